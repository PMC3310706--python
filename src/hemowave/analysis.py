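"""Empirical wave-detection pipeline: filtering, masking, centerline fitting,
isoeccentric averaging, Hilbert phase, front extraction, and regression.

The pipeline mirrors the surface-based analysis of line-stimulus responses:

1. low-pass filter every voxel time series (zero-phase Butterworth, 0.1 Hz);
2. select stimulus-driven voxels by normalized Fourier power (> 0.40) and
   coherence with the stimulus reference (> 0.4);
3. fit a polynomial centerline to the selected voxels (order chosen by AIC);
4. average the response over all voxels at equal signed perpendicular
   distance x from the centerline to obtain y(x, t);
5. band-pass around the response frequency, take the temporal Hilbert
   transform, and track the constant-phase front through the central peak;
6. straight-line fits of front time vs |x| give the wave speed, log-linear
   fits of amplitude along the front give temporal (Gamma_t) and spatial (K)
   decay constants, with 1-s.d. regression uncertainties.

Zero-phase (forward-backward) filtering is used throughout because one-pass
filtering would bias the phase-front timing that is the measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
import statsmodels.api as sm
from scipy import signal as ssig
from scipy import stats as sstats

from .grids import Field
from .synth import FlatMapDataset, StimulusSpec, signed_distance_to_curve

__all__ = [
    "AnalysisConfig",
    "lowpass_filter",
    "response_power_map",
    "coherence_map",
    "canonical_hrf",
    "stimulus_reference",
    "fit_centerline",
    "CenterlineFit",
    "isoeccentric_average",
    "AveragedResponse",
    "analytic_phase",
    "PhaseField",
    "extract_phase_front",
    "WaveFront",
    "fit_wave_speed",
    "fit_decay",
    "SpeedFit",
    "DecayFit",
    "estimate_fwhm",
    "recover_parameters",
    "WaveEstimates",
]

log = logging.getLogger(__name__)

NO_PROPAGATION = "no detectable propagation"


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable pipeline parameters (defaults follow the empirical procedure)."""

    f0: float | None = None          # analysis frequency, Hz; None -> peak-power bin
    lowpass_cutoff: float = 0.1      # Hz, 3rd-order zero-phase Butterworth
    lowpass_order: int = 3
    power_threshold: float = 0.40    # normalized Fourier power mask
    coherence_threshold: float = 0.4
    max_poly_order: int = 5          # centerline AIC candidates 0..max
    x_max: float = 10.0              # mm, perpendicular averaging extent
    exclusion_radius: float = 1.0    # mm, local (non-propagating) region
    amplitude_floor: float = 0.10    # fraction of central peak for phase masking
    k_fit_range: tuple | None = None  # mm window for the K regression;
                                      # None -> the whole propagating front
                                      # (same points as the temporal fit)
    band_halfwidth: float = 0.5      # band-pass half-width as a fraction of f0
    edge_guard_s: float = 30.0       # s discarded at both ends for Hilbert edges
    min_front_points: int = 4
    positive_side: int = +1          # which w side of the centerline is "F" (fovea)


# --------------------------------------------------------------------------
# filtering and voxel selection
# --------------------------------------------------------------------------

def lowpass_filter(ts: np.ndarray, cutoff: float = 0.1, fs: float | None = None,
                   order: int = 3, dt: float | None = None) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along the last axis.

    DC gain is exactly 1; the two-pass magnitude at frequency f is
    ``1 / (1 + (f/cutoff)**(2*order))``.
    """
    if fs is None:
        if dt is None:
            raise ValueError("provide fs or dt")
        fs = 1.0 / dt
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    b, a = ssig.butter(order, cutoff / (fs / 2))
    return ssig.filtfilt(b, a, np.asarray(ts, dtype=float), axis=-1)


def _series_and_dt(dataset) -> tuple[np.ndarray, float]:
    if isinstance(dataset, FlatMapDataset):
        return dataset.y.values, dataset.grid.dt
    if isinstance(dataset, Field):
        return dataset.values, dataset.grid.dt
    raise TypeError("expected FlatMapDataset or Field")


def response_power_map(dataset, f0: float | None = None,
                       threshold: float = 0.40):
    """Per-voxel normalized temporal Fourier power at f0, and its mask.

    Power in the f0 bin divided by total (non-DC) power; voxels above
    ``threshold`` form the stimulus-driven mask.  With ``f0=None`` the
    peak bin of the voxel-summed spectrum is used.  If f0 falls between
    bins the nearest bin is used and the offset logged.

    Returns
    -------
    power : ndarray, mask : ndarray of bool, f0_used : float
    """
    vals, dt = _series_and_dt(dataset)
    nt = vals.shape[-1]
    spec = np.abs(np.fft.rfft(vals - vals.mean(axis=-1, keepdims=True), axis=-1)) ** 2
    freqs = np.fft.rfftfreq(nt, dt)
    total = spec[..., 1:].sum(axis=-1)
    if f0 is None:
        summed = spec.reshape(-1, spec.shape[-1]).sum(axis=0)
        ibin = 1 + int(np.argmax(summed[1:]))
    else:
        ibin = int(np.argmin(np.abs(freqs - f0)))
        ibin = max(ibin, 1)
        if abs(freqs[ibin] - f0) > 1e-12:
            log.info("f0=%.4f Hz off the frequency grid; using bin %.4f Hz "
                     "(offset %.2e)", f0, freqs[ibin], freqs[ibin] - f0)
    with np.errstate(invalid="ignore", divide="ignore"):
        power = np.where(total > 0, spec[..., ibin] / total, 0.0)
    return power, power > threshold, float(freqs[ibin])


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma temporal HRF (peak ~6 s, undershoot ~16 s)."""
    h = sstats.gamma.pdf(t, 6) - sstats.gamma.pdf(t, 16) / 6.0
    s = np.trapezoid(h, t)
    return h / s if s != 0 else h


def stimulus_reference(spec: StimulusSpec, t: np.ndarray) -> np.ndarray:
    """Stimulus block time course convolved with the canonical temporal HRF."""
    dt = t[1] - t[0]
    env = spec.envelope(t)
    kern = canonical_hrf(np.arange(0, 32.0, dt))
    return np.convolve(env, kern)[: len(t)] * dt


def coherence_map(dataset, reference: np.ndarray, f0: float,
                  threshold: float = 0.4, nperseg: int = 64):
    """Magnitude coherence at f0 between each voxel and the reference.

    Welch magnitude-squared coherence (Hann segments) evaluated at the
    segment-grid bin nearest f0; the returned map is its square root.
    Degenerate (zero-variance) voxels get coherence 0.
    """
    vals, dt = _series_and_dt(dataset)
    fs = 1.0 / dt
    nperseg = min(nperseg, vals.shape[-1])
    flat = vals.reshape(-1, vals.shape[-1])
    live = flat.std(axis=-1) > 0
    coh = np.zeros(flat.shape[0])
    if np.any(live):
        freqs, cxy = ssig.coherence(flat[live], reference[None, :], fs=fs,
                                    nperseg=nperseg, axis=-1)
        ibin = int(np.argmin(np.abs(freqs - f0)))
        coh[live] = np.sqrt(np.clip(cxy[:, ibin], 0.0, 1.0))
    coh = coh.reshape(vals.shape[:-1])
    return coh, coh > threshold


# --------------------------------------------------------------------------
# centerline
# --------------------------------------------------------------------------

@dataclass
class CenterlineFit:
    """Polynomial centerline with AIC-based order selection."""

    coeffs: np.ndarray          # increasing order
    order: int
    aic: dict                   # order -> AIC value
    swapped_axes: bool = False  # fit performed as u = poly(w) (degenerate geometry)

    def __call__(self, u: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(u, self.coeffs)


def fit_centerline(mask_points: np.ndarray, max_order: int = 5) -> CenterlineFit:
    """Least-squares polynomial centerline through masked voxel coordinates.

    AIC = n*ln(RSS/n) + 2*(order + 2) per candidate order; among orders whose
    AIC is within 2 of the minimum, the smallest order wins (tie-break toward
    parsimony).  Near-vertical point clouds are fit with the axes swapped and
    flagged.
    """
    pts = np.asarray(mask_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("mask_points must be (n, 2) as (u, w)")
    n = len(pts)
    if n < max_order + 2:
        raise ValueError(f"need at least max_order+2={max_order + 2} points, got {n}")
    u, w = pts[:, 0], pts[:, 1]
    swapped = np.ptp(u) < 0.25 * np.ptp(w)
    if swapped:
        log.info("centerline geometry near-vertical; fitting with axes swapped")
        u, w = w, u
    aic = {}
    fits = {}
    # numerically-zero residuals are clamped to a common floor so that
    # exact fits of different orders tie (and the tie-break picks the lowest)
    rss_floor = n * (1e-9 * max(1.0, float(np.ptp(w)))) ** 2
    for order in range(0, max_order + 1):
        coeffs = np.polynomial.polynomial.polyfit(u, w, order)
        rss = float(np.sum((w - np.polynomial.polynomial.polyval(u, coeffs)) ** 2))
        rss = max(rss, rss_floor)
        aic[order] = n * np.log(rss / n) + 2.0 * (order + 2)
        fits[order] = coeffs
    amin = min(aic.values())
    chosen = min(o for o, v in aic.items() if v <= amin + 2.0)
    return CenterlineFit(coeffs=fits[chosen], order=chosen, aic=aic,
                         swapped_axes=swapped)


# --------------------------------------------------------------------------
# isoeccentric averaging
# --------------------------------------------------------------------------

@dataclass
class AveragedResponse:
    """Perpendicular-distance-binned average response y(x, t)."""

    x: np.ndarray        # signed perpendicular distance bin centers, mm
    t: np.ndarray        # s
    y: np.ndarray        # (n_x, nt); NaN rows are missing bins
    counts: np.ndarray   # voxels per bin
    dt: float

    @property
    def missing(self) -> np.ndarray:
        return self.counts == 0

    @property
    def i_center(self) -> int:
        return int(np.argmin(np.abs(self.x)))


def isoeccentric_average(dataset, centerline: CenterlineFit | np.ndarray,
                         x_max: float = 10.0,
                         positive_side: int = +1) -> AveragedResponse:
    """Average responses over all voxels at equal signed distance from the
    centerline.

    Signed perpendicular distance x is computed for every voxel (positive on
    the ``positive_side`` w side, the fovea analogue), binned at the voxel
    pitch, and averaged per (x, t).  Bins with no voxels are marked missing
    (NaN), not zero.  Voxels whose perpendicular foot falls at a curve
    endpoint are excluded.
    """
    vals, dt = _series_and_dt(dataset)
    if isinstance(dataset, FlatMapDataset):
        grid = dataset.grid
    else:
        grid = dataset.grid
    coeffs = centerline.coeffs if isinstance(centerline, CenterlineFit) else np.atleast_1d(centerline)
    uu, ww = np.meshgrid(grid.x, grid.y)
    pts = np.column_stack([uu.ravel(), ww.ravel()])
    dist, interior = signed_distance_to_curve(
        pts, coeffs, (grid.x.min(), grid.x.max()))
    dist = positive_side * dist
    nbins = int(np.floor(x_max / grid.dx))
    centers = np.arange(-nbins, nbins + 1) * grid.dx
    idx = np.round(dist / grid.dx).astype(int)
    ok = interior & (np.abs(dist) <= x_max + grid.dx / 2) & (np.abs(idx) <= nbins)
    flat = vals.reshape(-1, vals.shape[-1])
    ysum = np.zeros((len(centers), vals.shape[-1]))
    cnt = np.zeros(len(centers), dtype=int)
    np.add.at(ysum, idx[ok] + nbins, flat[ok])
    np.add.at(cnt, idx[ok] + nbins, 1)
    with np.errstate(invalid="ignore"):
        yavg = np.where(cnt[:, None] > 0, ysum / np.maximum(cnt[:, None], 1), np.nan)
    t = np.arange(vals.shape[-1]) * dt
    return AveragedResponse(x=centers, t=t, y=yavg, counts=cnt, dt=dt)


# --------------------------------------------------------------------------
# Hilbert phase and fronts
# --------------------------------------------------------------------------

@dataclass
class PhaseField:
    """Instantaneous phase and amplitude of the band-passed response."""

    x: np.ndarray
    t: np.ndarray
    phi: np.ndarray        # unwrapped phase, radians, (n_x, nt)
    amplitude: np.ndarray  # analytic-signal envelope, (n_x, nt)
    f0: float              # analysis frequency, Hz
    mask: np.ndarray       # (n_x,) True where amplitude exceeds the floor
    dt: float


def analytic_phase(avg: AveragedResponse, f0: float,
                   band_halfwidth: float = 0.5,
                   amplitude_floor: float = 0.10,
                   snr_min: float = 3.0) -> PhaseField:
    """Temporal Hilbert transform of the band-passed averaged response.

    A zero-phase 2nd-order Butterworth band-pass of half-width
    ``band_halfwidth * f0`` isolates the response component at f0; the
    analytic signal A = y + i*H[y] then gives phi = arg(A) (unwrapped along
    t per x) and the amplitude envelope |A|.  Rows are masked (phase is
    meaningless at noise level) when either the peak envelope falls below
    ``amplitude_floor`` of the central peak, or the f0 Fourier amplitude
    does not exceed ``snr_min`` times the noise floor estimated from
    off-response bins (1.2-1.8 f0) of the same row.
    """
    fs = 1.0 / avg.dt
    lo, hi = (1 - band_halfwidth) * f0, (1 + band_halfwidth) * f0
    if hi >= fs / 2:
        raise ValueError("band edge above Nyquist")
    b, a = ssig.butter(2, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    y = np.nan_to_num(avg.y, nan=0.0)
    yb = ssig.filtfilt(b, a, y, axis=-1)
    A = ssig.hilbert(yb, axis=-1)
    amp = np.abs(A)
    phi = np.unwrap(np.angle(A), axis=-1)
    peak = amp.max(axis=-1)
    central = peak[avg.i_center]
    # per-row SNR at f0: signal bin vs median of nearby off-response bins
    spec = np.abs(np.fft.rfft(y - y.mean(-1, keepdims=True), axis=-1))
    freqs = np.fft.rfftfreq(y.shape[-1], avg.dt)
    ibin = int(np.argmin(np.abs(freqs - f0)))
    nb = (freqs > 1.2 * f0) & (freqs < 1.8 * f0)
    noise_floor = np.median(spec[:, nb], axis=-1) if np.any(nb) else np.zeros(len(y))
    snr_ok = spec[:, ibin] > snr_min * noise_floor
    mask = (peak >= amplitude_floor * central) & snr_ok & ~avg.missing
    return PhaseField(x=avg.x, t=avg.t, phi=phi, amplitude=amp, f0=f0,
                      mask=mask, dt=avg.dt)


@dataclass
class WaveFront:
    """Constant-phase trajectory on one side of the centerline."""

    side: str                   # "F" (positive x) or "P" (negative x)
    x_abs: np.ndarray           # |x|, mm, increasing
    t: np.ndarray               # front crossing times, s
    amplitude: np.ndarray       # envelope sampled on the front
    flag: str | None = None     # NO_PROPAGATION or None

    @property
    def ok(self) -> bool:
        return self.flag is None

    @property
    def n(self) -> int:
        return len(self.x_abs)


def _cross_times(phi_row: np.ndarray, t: np.ndarray, target: float) -> np.ndarray:
    """All upward crossings of the unwrapped phase through ``target``."""
    d = phi_row - target
    idx = np.where((d[:-1] <= 0) & (d[1:] > 0))[0]
    if len(idx) == 0:
        return np.empty(0)
    frac = -d[idx] / (d[idx + 1] - d[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def extract_phase_front(phase: PhaseField, y: AveragedResponse | None = None, *,
                        exclusion_radius: float = 1.0,
                        edge_guard_s: float = 30.0,
                        min_points: int = 4,
                        monotone_tol: float | None = None) -> tuple[WaveFront, WaveFront]:
    """Track the phase front that intersects the central BOLD peak.

    The reference phase phi0 is read at the envelope peak of the central row
    (within an edge-guarded window).  Moving outward from |x| =
    ``exclusion_radius``, each row's front time is the unwrapped-phase
    crossing of phi0 (mod 2*pi) nearest the previous front time; tracking
    stops at masked rows.  Leading points still inside the non-propagating
    local region -- identified by a step time below half the median step
    (fronts are nearly stationary at the center) -- are trimmed so the fits
    act on the propagating region only.  A side whose front has fewer than
    ``min_points`` points or is non-monotone in |x| is flagged
    "no detectable propagation".
    """
    x, t, phi = phase.x, phase.t, phase.phi
    i0 = int(np.argmin(np.abs(x)))
    guard = (t >= edge_guard_s) & (t <= t[-1] - edge_guard_s)
    if not np.any(guard):
        raise ValueError("edge guard leaves no analysis window")
    tw = t[guard]
    # prefer a cycle near the middle of the window for steady-state phase
    weight = np.exp(-0.5 * ((tw - tw.mean()) / (0.25 * (tw[-1] - tw[0]))) ** 2)
    ic = int(np.argmax(phase.amplitude[i0, guard] * weight))
    t_peak = tw[ic]
    phi0 = float(np.interp(t_peak, t, phi[i0]))

    fronts = []
    for side, step in (("F", +1), ("P", -1)):
        pts = []
        t_prev = t_peak
        i = i0 + step
        while 0 <= i < len(x):
            xa = abs(x[i])
            if xa > exclusion_radius:
                if not phase.mask[i]:
                    break
                # choose the 2*pi branch of phi0 nearest the running front time
                m = np.round((np.interp(t_prev, t, phi[i]) - phi0) / (2 * np.pi))
                crossings = _cross_times(phi[i], t, phi0 + 2 * np.pi * m)
                crossings = np.concatenate([
                    crossings,
                    _cross_times(phi[i], t, phi0 + 2 * np.pi * (m + 1)),
                    _cross_times(phi[i], t, phi0 + 2 * np.pi * (m - 1)),
                ])
                crossings = crossings[(crossings >= tw[0]) & (crossings <= tw[-1])]
                if len(crossings) == 0:
                    break
                tc = float(crossings[np.argmin(np.abs(crossings - t_prev))])
                amp = float(np.interp(tc, t, phase.amplitude[i]))
                pts.append((xa, tc, amp))
                t_prev = tc
            i += step
        pts = np.asarray(pts) if pts else np.empty((0, 3))
        # trim leading points that still sit in the stationary local region
        while len(pts) >= 3:
            steps = np.diff(pts[:, 1])
            if steps[0] < 0.75 * np.median(steps):
                pts = pts[1:]
            else:
                break
        # robust screening: drop isolated crossing-time outliers (phase
        # jitter at low SNR maps to large time jitter at f0) against a
        # straight-line front; the absolute floor 2*dt leaves clean fronts
        # untouched
        for _ in range(2):
            if len(pts) < max(min_points, 4):
                break
            coef = np.polyfit(pts[:, 0], pts[:, 1], 1)
            resid = pts[:, 1] - np.polyval(coef, pts[:, 0])
            thresh = max(3.0 * 1.4826 * float(np.median(np.abs(resid))),
                         2.0 * phase.dt)
            keep = np.abs(resid) <= thresh
            if keep.all():
                break
            pts = pts[keep]
        flag = None
        if len(pts) < min_points:
            flag = NO_PROPAGATION
        else:
            steps = np.diff(pts[:, 1])
            # monotone in |x| up to the timing-jitter scale; a systematically
            # non-advancing front marks non-propagation
            tol = monotone_tol if monotone_tol is not None else \
                max(2.0 * float(np.median(np.abs(steps))), 2.0 * phase.dt)
            if np.any(steps < -tol) or np.median(steps) <= 0:
                flag = NO_PROPAGATION
        fronts.append(WaveFront(side=side, x_abs=pts[:, 0], t=pts[:, 1],
                                amplitude=pts[:, 2], flag=flag))
    return fronts[0], fronts[1]


# --------------------------------------------------------------------------
# regressions
# --------------------------------------------------------------------------

@dataclass
class SpeedFit:
    v: float
    sd: float
    r2: float
    n: int
    flag: str | None = None


@dataclass
class DecayFit:
    K: float
    sd_K: float
    Gamma_t: float
    sd_Gamma: float
    n: int                 # points in the temporal regression
    n_spatial: int = 0     # points in the spatial (K) regression
    flag: str | None = None


def _ols(x: np.ndarray, y: np.ndarray):
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.bse[1]), float(res.rsquared)


def fit_wave_speed(front: WaveFront) -> SpeedFit:
    """Wave speed from an ordinary least-squares line of t on |x|.

    ``v = 1/slope`` with the uncertainty propagated from the slope's 1-s.d.
    error (x is the controlled variable on the front, so t is regressed on
    |x|, not the reverse).  Fronts with fewer than 4 points or non-positive
    slope are flagged.
    """
    if not front.ok or front.n < 4:
        return SpeedFit(np.nan, np.nan, np.nan, front.n, flag=NO_PROPAGATION)
    slope, se, r2 = _ols(front.x_abs, front.t)
    if slope <= 0:
        return SpeedFit(np.nan, np.nan, r2, front.n, flag="unphysical slope")
    return SpeedFit(v=1.0 / slope, sd=se / slope ** 2, r2=r2, n=front.n)


def fit_decay(front: WaveFront, k_fit_range: tuple | None = None) -> DecayFit:
    """Exponential decay of BOLD amplitude along the front.

    Log-linear regression of amplitude along the front: vs time over the
    whole propagating front for the signed temporal decay constant Gamma_t
    (negative for decaying waves), and vs |x| for the spatial decay constant
    K (positive).  With ``k_fit_range=None`` (default) the spatial fit uses
    the same points as the temporal fit, which keeps the two estimates
    internally consistent (|Gamma_t| = K*v); a (lo, hi] window in mm
    restricts the spatial fit instead.  Non-positive amplitudes are dropped
    (logged).
    """
    if not front.ok or front.n < 3:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, front.n, flag=NO_PROPAGATION)
    pos = front.amplitude > 0
    if np.any(~pos):
        log.info("fit_decay: dropping %d non-positive amplitude points", int((~pos).sum()))
    xa, tt, aa = front.x_abs[pos], front.t[pos], front.amplitude[pos]
    if len(aa) < 3:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, len(aa), flag=NO_PROPAGATION)
    g, sg, _ = _ols(tt, np.log(aa))
    if k_fit_range is not None:
        inwin = (xa > k_fit_range[0]) & (xa <= k_fit_range[1])
        if inwin.sum() >= 3:
            xa, aa = xa[inwin], aa[inwin]
    k, sk, _ = _ols(xa, np.log(aa))
    return DecayFit(K=-k, sd_K=sk, Gamma_t=g, sd_Gamma=sg, n=int(pos.sum()),
                    n_spatial=len(aa))


def estimate_fwhm(avg: AveragedResponse, f0: float,
                  edge_guard_s: float = 30.0) -> tuple[float, str | None]:
    """FWHM (mm) of the spatial profile of the f0 amplitude envelope.

    The profile is the per-x Fourier amplitude at the bin nearest f0 over the
    edge-guarded window.  Half-maximum positions are linearly interpolated;
    a multi-peaked profile yields the widest contiguous half-max span and a
    flag.
    """
    guard = (avg.t >= edge_guard_s) & (avg.t <= avg.t[-1] - edge_guard_s)
    y = np.nan_to_num(avg.y[:, guard], nan=0.0)
    nt = y.shape[-1]
    freqs = np.fft.rfftfreq(nt, avg.dt)
    ibin = int(np.argmin(np.abs(freqs - f0)))
    prof = np.abs(np.fft.rfft(y - y.mean(-1, keepdims=True), axis=-1))[:, ibin]
    ipk = int(np.argmax(prof))
    half = prof[ipk] / 2.0
    above = prof >= half
    # contiguous run containing the peak
    runs = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    flag = "multi-peaked profile" if len(runs) > 1 else None
    lo_i, hi_i = max(runs, key=lambda r: r[1] - r[0])
    x = avg.x

    def interp_edge(i_edge, direction):
        j = i_edge + direction
        if 0 <= j < len(prof) and prof[j] < half:
            frac = (prof[i_edge] - half) / (prof[i_edge] - prof[j])
            return x[i_edge] + frac * (x[j] - x[i_edge])
        return x[i_edge]

    x_lo = interp_edge(lo_i, -1)
    x_hi = interp_edge(hi_i, +1)
    return float(x_hi - x_lo), flag


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

@dataclass
class WaveEstimates:
    """Fitted wave parameters with regression uncertainties and diagnostics."""

    v_F: float = np.nan
    v_P: float = np.nan
    sd_v_F: float = np.nan
    sd_v_P: float = np.nan
    K_F: float = np.nan
    K_P: float = np.nan
    sd_K_F: float = np.nan
    sd_K_P: float = np.nan
    Gamma_F: float = np.nan      # signed temporal decay, 1/s (negative)
    Gamma_P: float = np.nan
    sd_Gamma_F: float = np.nan
    sd_Gamma_P: float = np.nan
    fwhm_mm: float = np.nan
    f0: float = np.nan
    flags: dict = dc_field(default_factory=dict)
    diagnostics: dict = dc_field(default_factory=dict)

    def consistency(self, side: str) -> dict:
        """|Gamma_t| vs K*v agreement for one side, with a 3-s.d. violation flag."""
        g = abs(getattr(self, f"Gamma_{side}"))
        sg = getattr(self, f"sd_Gamma_{side}")
        kv = getattr(self, f"K_{side}") * getattr(self, f"v_{side}")
        skv = np.hypot(getattr(self, f"sd_K_{side}") * getattr(self, f"v_{side}"),
                       getattr(self, f"K_{side}") * getattr(self, f"sd_v_{side}"))
        sd = np.hypot(sg, skv)
        diff = g - kv
        return {"abs_Gamma_t": g, "K_times_v": kv,
                "violated": bool(sd > 0 and abs(diff) > 3 * sd)}

    def to_dict(self) -> dict:
        return asdict(self)


def recover_parameters(dataset: FlatMapDataset,
                       config: AnalysisConfig | None = None) -> tuple[WaveEstimates, dict]:
    """Run the full pipeline on a dataset and compare against ground truth.

    filter -> mask (power & coherence) -> centerline -> isoeccentric average
    -> Hilbert phase -> phase fronts -> speed/decay regressions -> FWHM.

    Returns the estimates and a structured report; when the dataset embeds
    ground truth the report includes truth-vs-estimate deltas.  Stage flags
    propagate into ``estimates.flags`` and the report.
    """
    cfg = config or AnalysisConfig()
    grid = dataset.grid
    filt = lowpass_filter(dataset.y.values, cutoff=cfg.lowpass_cutoff,
                          dt=grid.dt, order=cfg.lowpass_order)
    filt_field = Field(filt, grid, quantity="y", units="percent")

    power, pmask, f0 = response_power_map(filt_field, cfg.f0, cfg.power_threshold)
    spec = dataset.ground_truth.get("stimulus") if dataset.ground_truth else None
    stim = StimulusSpec(**spec) if spec else StimulusSpec()
    ref = stimulus_reference(stim, grid.t)
    coh, cmask = coherence_map(filt_field, ref, f0, cfg.coherence_threshold)
    # spatial prior analogue: the experiment restricted candidate voxels to
    # the stimulus locus via retinotopy; on the synthetic flat map the
    # response ridge (voxels within half maximum amplitude) plays that role
    peak_amp = np.max(np.abs(filt), axis=-1)
    ridge = peak_amp >= 0.5 * peak_amp.max()
    mask = pmask & cmask & ridge
    if mask.sum() < cfg.max_poly_order + 2:
        mask = pmask & ridge  # coherence too strict on short/noisy data
    if mask.sum() < cfg.max_poly_order + 2:
        mask = ridge
    uu, ww = np.meshgrid(grid.x, grid.y)
    cl = fit_centerline(np.column_stack([uu[mask], ww[mask]]), cfg.max_poly_order)

    avg = isoeccentric_average(filt_field, cl, x_max=cfg.x_max,
                               positive_side=cfg.positive_side)
    phase = analytic_phase(avg, f0, cfg.band_halfwidth, cfg.amplitude_floor)
    front_F, front_P = extract_phase_front(
        phase, avg, exclusion_radius=cfg.exclusion_radius,
        edge_guard_s=cfg.edge_guard_s, min_points=cfg.min_front_points)

    est = WaveEstimates(f0=f0)
    for side, front in (("F", front_F), ("P", front_P)):
        sp = fit_wave_speed(front)
        dc = fit_decay(front, cfg.k_fit_range)
        setattr(est, f"v_{side}", sp.v)
        setattr(est, f"sd_v_{side}", sp.sd)
        setattr(est, f"K_{side}", dc.K)
        setattr(est, f"sd_K_{side}", dc.sd_K)
        setattr(est, f"Gamma_{side}", dc.Gamma_t)
        setattr(est, f"sd_Gamma_{side}", dc.sd_Gamma)
        flags = [f for f in (front.flag, sp.flag, dc.flag) if f]
        if flags:
            est.flags[side] = flags[0]
        est.diagnostics[side] = {"n_front": front.n, "r2_speed": sp.r2,
                                 "n_k_fit": dc.n_spatial}
    est.fwhm_mm, fwhm_flag = estimate_fwhm(avg, f0, cfg.edge_guard_s)
    if fwhm_flag:
        est.flags["fwhm"] = fwhm_flag
    est.diagnostics.update({
        "centerline_order": cl.order,
        "n_mask_voxels": int(mask.sum()),
        "f0_hz": f0,
    })

    report = {
        "estimates": est.to_dict(),
        "consistency": {s: est.consistency(s) for s in ("F", "P")
                        if np.isfinite(getattr(est, f"v_{s}"))},
        "centerline": {"order": cl.order, "coeffs": cl.coeffs.tolist(),
                       "aic": {str(k): float(v) for k, v in cl.aic.items()}},
        "config": asdict(cfg),
    }
    gt = dataset.ground_truth or {}
    if "v_beta" in gt:
        truth = {"v_beta": gt["v_beta"], "Gamma": gt["Gamma"], "K": gt["K"]}
        deltas = {}
        for side in ("F", "P"):
            v = getattr(est, f"v_{side}")
            if np.isfinite(v):
                deltas[side] = {
                    "v_rel_err": v / gt["v_beta"] - 1.0,
                    "Gamma_rel_err": abs(getattr(est, f"Gamma_{side}")) / gt["Gamma"] - 1.0,
                    "K_rel_err": getattr(est, f"K_{side}") / gt["K"] - 1.0,
                }
        report["ground_truth"] = truth
        report["truth_deltas"] = deltas
    return est, report
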