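"""Wave-detection pipeline: filters, masks, centerline, phase, fits, recovery."""

import numpy as np
import pytest

from hemowave import (
    AnalysisConfig,
    NoiseSpec,
    ReducedWaveParams,
    StimulusSpec,
    analytic_phase,
    coherence_map,
    estimate_fwhm,
    extract_phase_front,
    fit_centerline,
    fit_decay,
    fit_wave_speed,
    isoeccentric_average,
    lowpass_filter,
    make_flatmap_dataset,
    recover_parameters,
    response_power_map,
)
from hemowave.analysis import (
    NO_PROPAGATION,
    AveragedResponse,
    WaveFront,
    stimulus_reference,
)
from hemowave.grids import Field
from tests.conftest import NOISELESS


# ------------------------------------------------------------------ filter

def test_lowpass_dc_gain_and_linearity():
    rng = np.random.default_rng(0)
    const = np.full(600, 3.7)
    np.testing.assert_allclose(lowpass_filter(const, dt=0.25), const, rtol=1e-9)
    a, b = rng.standard_normal((2, 600))
    np.testing.assert_allclose(
        lowpass_filter(a + b, dt=0.25),
        lowpass_filter(a, dt=0.25) + lowpass_filter(b, dt=0.25), atol=1e-10)


def test_lowpass_two_pass_attenuation_at_twice_cutoff():
    """Two-pass 3rd-order Butterworth at 2x cutoff: |H|^2 = 1/(1+2^6) = 1/65."""
    dt, f = 0.25, 0.2  # cutoff 0.1 Hz
    t = np.arange(0, 2000, dt)
    x = np.sin(2 * np.pi * f * t)
    y = lowpass_filter(x, cutoff=0.1, dt=dt)
    ratio = np.abs(y[2000:-2000]).max() / 1.0
    # the bilinear-transform design warps slightly at f/fs = 0.05
    assert ratio == pytest.approx(1.0 / 65.0, rel=0.05)


def test_lowpass_cutoff_above_nyquist_errors():
    with pytest.raises(ValueError, match="Nyquist"):
        lowpass_filter(np.zeros(100), cutoff=3.0, dt=0.25)


# ----------------------------------------------------------------- masking

def test_power_map_pure_sinusoid():
    grid_dt = 0.25
    t = np.arange(0, 160, grid_dt)
    f0 = 0.05
    from hemowave.grids import SpatioTemporalGrid
    g = SpatioTemporalGrid(dx=0.75, dt=grid_dt, nx=4, nt=len(t))
    vals = np.broadcast_to(np.sin(2 * np.pi * f0 * t), (4, len(t))).copy()
    field = Field(vals, g, quantity="y")
    power, mask, f0_used = response_power_map(field, f0)
    assert np.all(power > 0.95)
    assert np.all(mask)
    assert f0_used == pytest.approx(f0, abs=1.0 / 160)


def test_power_map_white_noise_expectation():
    """White noise: expected normalized power ~ 1/(number of bins)."""
    rng = np.random.default_rng(7)
    nt = 512
    from hemowave.grids import SpatioTemporalGrid
    g = SpatioTemporalGrid(dx=0.75, dt=0.25, nx=400, nt=nt)
    vals = rng.standard_normal((400, nt))
    field = Field(vals, g, quantity="y")
    power, mask, _ = response_power_map(field, f0=0.05)
    nbins = nt // 2
    assert power.mean() == pytest.approx(1.0 / nbins, rel=0.15)
    assert not mask.any()


def test_power_mask_is_band_around_centerline(noiseless_dataset):
    ds = noiseless_dataset
    filt = lowpass_filter(ds.y.values, dt=ds.grid.dt)
    power, mask, f0 = response_power_map(Field(filt, ds.grid, quantity="y"))
    rows = np.where(mask.any(axis=1))[0]
    # a contiguous band of rows centered on the centerline (w = 0)
    assert ds.grid.ny // 2 in rows
    assert np.array_equal(rows, np.arange(rows.min(), rows.max() + 1))
    assert 0.04 < f0 < 0.06  # near the block fundamental


def test_coherence_scaled_reference_is_one():
    from hemowave.grids import SpatioTemporalGrid
    t = np.arange(0, 176, 0.25)
    ref = stimulus_reference(StimulusSpec(), t)
    g = SpatioTemporalGrid(dx=0.75, dt=0.25, nx=3, nt=len(t))
    vals = np.stack([2.0 * ref, -0.5 * ref, 0.0 * ref])
    coh, mask = coherence_map(Field(vals, g, quantity="y"), ref, f0=0.05)
    assert coh[0] == pytest.approx(1.0, abs=1e-9)
    assert coh[1] == pytest.approx(1.0, abs=1e-9)
    assert coh[2] == 0.0  # degenerate voxel


def test_coherence_independent_noise_below_threshold():
    """Independent noise stays below coherence 0.4 with probability > 0.95."""
    rng = np.random.default_rng(21)
    t = np.arange(0, 176, 0.25)
    ref = stimulus_reference(StimulusSpec(), t)
    from hemowave.grids import SpatioTemporalGrid
    n = 400
    g = SpatioTemporalGrid(dx=0.75, dt=0.25, nx=n, nt=len(t))
    vals = rng.standard_normal((n, len(t)))
    coh, mask = coherence_map(Field(vals, g, quantity="y"), ref, f0=0.05)
    assert (coh < 0.4).mean() > 0.95


def test_coherence_mask_traces_centerline():
    """With measurement noise, coherent voxels concentrate on the centerline."""
    ds = make_flatmap_dataset(ReducedWaveParams(3.0, 0.8), noise=NoiseSpec(seed=2))
    filt = lowpass_filter(ds.y.values, dt=ds.grid.dt)
    ref = stimulus_reference(StimulusSpec(), ds.grid.t)
    coh, mask = coherence_map(Field(filt, ds.grid, quantity="y"), ref, f0=0.0494)
    assert mask[ds.grid.ny // 2, :].mean() > 0.9
    assert coh[ds.grid.ny // 2].mean() > coh[0].mean()
    assert mask[ds.grid.ny // 2].mean() > mask[0].mean()


# -------------------------------------------------------------- centerline

def test_centerline_noisy_straight_line_selects_order_one():
    rng = np.random.default_rng(4)
    u = np.linspace(-10, 10, 150)
    w = 0.4 + 0.15 * u + rng.normal(0, 0.35, size=u.size)
    assert fit_centerline(np.column_stack([u, w])).order == 1


def test_centerline_exact_cubic_selected_with_zero_rss():
    u = np.linspace(-8, 8, 60)
    w = 0.5 - 0.2 * u + 0.01 * u ** 2 + 0.004 * u ** 3
    fit = fit_centerline(np.column_stack([u, w]))
    assert fit.order == 3
    np.testing.assert_allclose(fit(u), w, atol=1e-8)


def test_centerline_aic_tie_break_toward_lower_order():
    """The chosen order is the smallest whose AIC is within 2 of the minimum."""
    rng = np.random.default_rng(11)
    u = np.linspace(-10, 10, 100)
    w = 1.0 + 0.1 * u + rng.normal(0, 0.3, size=u.size)
    fit = fit_centerline(np.column_stack([u, w]))
    amin = min(fit.aic.values())
    eligible = [o for o, v in fit.aic.items() if v <= amin + 2.0]
    assert fit.order == min(eligible)


def test_centerline_order_recovery_rate():
    """AIC selection recovers the generating order in >= 90% of seeded trials."""
    hits = 0
    trials = 40
    for seed in range(trials):
        rng = np.random.default_rng(seed)
        u = rng.uniform(-10, 10, 150)
        order = 1 if seed % 2 == 0 else 3
        if order == 1:
            w = 0.5 + 0.2 * u
        else:
            w = 0.5 + 0.15 * u + 0.004 * u ** 3
        w = w + rng.normal(0, 0.35, size=u.size)
        if fit_centerline(np.column_stack([u, w])).order == order:
            hits += 1
    assert hits / trials >= 0.9


def test_centerline_vertical_geometry_swaps_axes():
    rng = np.random.default_rng(2)
    w = np.linspace(-8, 8, 80)
    u = 1.0 + 0.05 * w + rng.normal(0, 0.2, size=w.size)
    fit = fit_centerline(np.column_stack([u, w]))
    assert fit.swapped_axes


def test_centerline_too_few_points_errors():
    with pytest.raises(ValueError, match="points"):
        fit_centerline(np.zeros((4, 2)), max_order=5)


def test_centerline_recovery_from_curved_dataset(curved_dataset):
    """End-to-end: power+coherence mask -> AIC polynomial recovers the
    generating cubic within 0.5 voxel RMS across the map."""
    ds = curved_dataset
    filt = lowpass_filter(ds.y.values, dt=ds.grid.dt)
    field = Field(filt, ds.grid, quantity="y")
    power, pmask, f0 = response_power_map(field)
    ridge = np.max(np.abs(filt), axis=-1) >= 0.5 * np.abs(filt).max()
    mask = pmask & ridge
    uu, ww = np.meshgrid(ds.grid.x, ds.grid.y)
    fit = fit_centerline(np.column_stack([uu[mask], ww[mask]]))
    u = ds.grid.x
    w_true = np.polynomial.polynomial.polyval(u, ds.centerline)
    rms = np.sqrt(np.mean((fit(u) - w_true) ** 2))
    assert rms < 0.5 * ds.grid.dx


# ------------------------------------------------------------- averaging

def test_isoeccentric_average_translation_invariance(noiseless_dataset):
    ds = noiseless_dataset
    avg = isoeccentric_average(ds.y, [0.0], x_max=10.0)
    for i, xc in enumerate(avg.x):
        j = int(np.argmin(np.abs(ds.grid.y - xc)))
        np.testing.assert_allclose(avg.y[i], ds.y.values[j, 1, :], atol=1e-12)


def test_isoeccentric_average_missing_bins_flagged(noiseless_dataset):
    """Bins beyond the data margin are marked missing, not zero."""
    ds = noiseless_dataset
    avg = isoeccentric_average(ds.y, [8.25], x_max=10.0)  # offset centerline
    assert avg.missing.any()
    assert np.all(np.isnan(avg.y[avg.missing]))
    assert not np.isnan(avg.y[~avg.missing]).any()


def test_isoeccentric_average_curved_close_to_1d(curved_dataset):
    ds = curved_dataset
    from hemowave.analysis import CenterlineFit
    avg = isoeccentric_average(ds.y, np.asarray(ds.centerline), x_max=8.0)
    g1 = ds.grid
    # compare against the straight-centerline row profile of an equivalent
    # 1-D run: use max-over-t profiles
    prof = np.nanmax(np.abs(avg.y), axis=-1)
    assert np.nanargmax(prof) == avg.i_center
    # symmetric decay on both sides within 6% of peak
    half = (len(avg.x) - 1) // 2
    sym = np.abs(prof[half + 1:] - prof[half - 1::-1][: half])
    assert np.nanmax(sym) < 0.06 * np.nanmax(prof)


# ----------------------------------------------------------- phase & front

def _mk_avg(x, t, y):
    return AveragedResponse(x=x, t=t, y=y, counts=np.full(len(x), 5), dt=t[1] - t[0])


def test_analytic_phase_of_cosine():
    f0 = 0.05
    t = np.arange(0, 400, 0.25)
    x = np.arange(-5, 5.1, 0.75)
    y = np.broadcast_to(np.cos(2 * np.pi * f0 * t), (len(x), len(t))).copy()
    ph = analytic_phase(_mk_avg(x, t, y), f0)
    mid = slice(200, 1300)
    slope = np.polyfit(t[mid], ph.phi[0, mid], 1)[0]
    assert slope == pytest.approx(2 * np.pi * f0, rel=1e-3)


def test_analytic_phase_traveling_wave_gradient():
    """cos(2 pi f0 (t - x/v)) has d(phi)/dx = -2 pi f0 / v."""
    f0, v = 0.05, 2.5
    t = np.arange(0, 400, 0.25)
    x = np.arange(0, 8.1, 0.75)
    y = np.cos(2 * np.pi * f0 * (t[None, :] - x[:, None] / v))
    ph = analytic_phase(_mk_avg(x, t, y), f0)
    grad = np.gradient(ph.phi[:, 800], x)
    np.testing.assert_allclose(grad, -2 * np.pi * f0 / v, rtol=5e-3)


def test_hilbert_quadrature_of_cosine():
    from scipy.signal import hilbert
    t = np.arange(0, 2000, 0.25)
    c = np.cos(2 * np.pi * 0.05 * t)
    h = np.imag(hilbert(c))
    s = np.sin(2 * np.pi * 0.05 * t)
    assert np.max(np.abs(h[400:-400] - s[400:-400])) < 1e-3


def test_front_extraction_exact_plane_wave():
    """A damped traveling cosine yields the exact front t = t0 + |x|/v."""
    f0, v, K = 0.05, 2.0, 0.3
    t = np.arange(0, 400, 0.25)
    x = np.arange(-10, 10.1, 0.75)
    y = np.exp(-K * np.abs(x))[:, None] * \
        np.cos(2 * np.pi * f0 * (t[None, :] - np.abs(x)[:, None] / v))
    ph = analytic_phase(_mk_avg(x, t, y), f0)
    fF, fP = extract_phase_front(ph)
    for front in (fF, fP):
        assert front.flag is None
        sp = fit_wave_speed(front)
        assert sp.v == pytest.approx(v, rel=0.01)
        # and the front is the straight line through the central peak
        resid = front.t - (front.t[0] + (front.x_abs - front.x_abs[0]) / v)
        assert np.max(np.abs(resid)) < 0.05


def test_front_zero_decay_for_undamped_wave():
    """Pure traveling sinusoid: exact v and zero decay."""
    f0, v = 0.05, 2.0
    t = np.arange(0, 400, 0.25)
    x = np.arange(-10, 10.1, 0.75)
    y = np.cos(2 * np.pi * f0 * (t[None, :] - np.abs(x)[:, None] / v))
    ph = analytic_phase(_mk_avg(x, t, y), f0)
    fF, _ = extract_phase_front(ph)
    dc = fit_decay(fF)
    assert abs(dc.Gamma_t) < 1e-3
    assert abs(dc.K) < 1e-3


def test_extreme_damping_flagged_not_fit():
    ds = make_flatmap_dataset(ReducedWaveParams(0.8, 2.0), noise=NOISELESS)
    est, report = recover_parameters(ds)
    assert est.flags.get("F") == NO_PROPAGATION
    assert est.flags.get("P") == NO_PROPAGATION
    assert np.isnan(est.v_F) and np.isnan(est.v_P)


# ------------------------------------------------------------- regressions

def test_fit_wave_speed_exact_line():
    x = np.arange(1.5, 7.0, 0.75)
    front = WaveFront(side="F", x_abs=x, t=1.0 + x / 3.0,
                      amplitude=np.exp(-0.3 * x))
    sp = fit_wave_speed(front)
    assert sp.v == pytest.approx(3.0, rel=1e-9)
    assert sp.sd == pytest.approx(0.0, abs=1e-9)


def test_fit_wave_speed_unphysical_slope_flagged():
    x = np.arange(1.5, 7.0, 0.75)
    front = WaveFront(side="F", x_abs=x, t=5.0 - x / 3.0,
                      amplitude=np.ones_like(x))
    assert fit_wave_speed(front).flag == "unphysical slope"


def test_fit_wave_speed_too_few_points_flagged():
    front = WaveFront(side="F", x_abs=np.array([1.5, 2.25, 3.0]),
                      t=np.array([1.0, 1.3, 1.6]),
                      amplitude=np.ones(3))
    assert fit_wave_speed(front).flag == NO_PROPAGATION


def test_fit_wave_speed_interval_coverage():
    """~68% of 1-s.d. intervals cover the true speed over noisy replicates."""
    rng = np.random.default_rng(42)
    v_true = 3.0
    x = np.arange(1.5, 9.0, 0.75)
    cover = 0
    n_rep = 20
    for _ in range(n_rep):
        t = 1.0 + x / v_true + rng.normal(0, 0.15, size=x.size)
        front = WaveFront(side="F", x_abs=x, t=t, amplitude=np.ones_like(x))
        sp = fit_wave_speed(front)
        if abs(sp.v - v_true) <= sp.sd:
            cover += 1
    assert 0.4 <= cover / n_rep <= 0.9


def test_fit_decay_exact_exponential():
    x = np.arange(1.5, 7.0, 0.75)
    t = 1.0 + x / 3.0
    front = WaveFront(side="P", x_abs=x, t=t, amplitude=2.0 * np.exp(-0.5 * t))
    dc = fit_decay(front)
    assert dc.Gamma_t == pytest.approx(-0.5, rel=1e-9)
    assert dc.K == pytest.approx(0.5 / 3.0, rel=1e-9)


def test_fit_decay_drops_nonpositive_amplitudes():
    x = np.arange(1.5, 7.0, 0.75)
    amp = np.exp(-0.4 * x)
    amp[3] = -1e-3
    front = WaveFront(side="P", x_abs=x, t=1.0 + x / 2.0, amplitude=amp)
    dc = fit_decay(front)
    assert np.isfinite(dc.K)
    assert dc.n == len(x) - 1


# -------------------------------------------------------------------- FWHM

def test_fwhm_gaussian_envelope():
    """Gaussian envelope sigma = 2 mm -> FWHM = 2 sqrt(2 ln 2) * 2 = 4.71 mm."""
    f0 = 0.05
    t = np.arange(0, 400, 0.25)
    x = np.arange(-10, 10.1, 0.25)
    y = np.exp(-x[:, None] ** 2 / 8.0) * np.cos(2 * np.pi * f0 * t[None, :])
    fwhm, flag = estimate_fwhm(_mk_avg(x, t, y), f0)
    assert fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 2.0, rel=0.01)
    assert flag is None
    # scale invariance
    fwhm2, _ = estimate_fwhm(_mk_avg(x, t, 2 * y), f0)
    assert fwhm2 == pytest.approx(fwhm, rel=1e-9)


def test_fwhm_multi_peak_flagged():
    f0 = 0.05
    t = np.arange(0, 400, 0.25)
    x = np.arange(-10, 10.1, 0.25)
    env = np.exp(-(x - 4) ** 2 / 2.0) + 0.9 * np.exp(-(x + 4) ** 2 / 2.0)
    y = env[:, None] * np.cos(2 * np.pi * f0 * t[None, :])
    fwhm, flag = estimate_fwhm(_mk_avg(x, t, y), f0)
    assert flag == "multi-peaked profile"
    assert fwhm > 0


def test_fwhm_bounded_by_input_and_extent(subject_fits):
    """Detectable regime: FWHM lies between the neural input width and twice
    the propagation extent."""
    from hemowave import propagation_extent
    for name, (ds, est, rep) in subject_fits.items():
        input_fwhm = 2 * np.sqrt(2 * np.log(2)) * 1.0
        assert input_fwhm < est.fwhm_mm < 2 * 10.0


# ----------------------------------------------------------------- recovery

def test_recover_noiseless_within_ten_percent():
    for v, G in [(3.0, 0.8), (6.0, 0.4), (1.5, 0.4)]:
        ds = make_flatmap_dataset(ReducedWaveParams(v, G), noise=NOISELESS)
        est, rep = recover_parameters(ds)
        for side, d in rep["truth_deltas"].items():
            assert abs(d["v_rel_err"]) < 0.10
            assert abs(d["Gamma_rel_err"]) < 0.10
            assert abs(d["K_rel_err"]) < 0.10


def test_recover_deterministic_given_seed():
    red = ReducedWaveParams(3.0, 0.8)
    r1 = recover_parameters(make_flatmap_dataset(red, noise=NoiseSpec(seed=9)))
    r2 = recover_parameters(make_flatmap_dataset(red, noise=NoiseSpec(seed=9)))
    assert r1[0].to_dict() == r2[0].to_dict()


def test_recover_report_schema(noiseless_dataset):
    est, rep = recover_parameters(noiseless_dataset)
    for key in ("estimates", "consistency", "centerline", "config",
                "ground_truth", "truth_deltas"):
        assert key in rep
    for key in ("v_F", "v_P", "K_F", "K_P", "Gamma_F", "Gamma_P",
                "fwhm_mm", "f0", "flags", "diagnostics"):
        assert key in rep["estimates"]
    assert rep["centerline"]["order"] in range(0, 6)


def test_consistency_flagging_3sd(subject_fits):
    for name, (ds, est, rep) in subject_fits.items():
        for side, c in rep["consistency"].items():
            assert not c["violated"]
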