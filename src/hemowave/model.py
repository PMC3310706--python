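"""Model/Results interface for wave-parameter estimation.

:class:`BoldWaveModel` wraps a flat-map BOLD dataset the way statistical
modelling packages wrap data: construct from a dataset (or NIfTI file),
``fit()`` runs the wave-detection pipeline and returns a
:class:`BoldWaveResults` carrying the estimates, their 1-s.d. regression
uncertainties, diagnostics, and a ``summary()`` table.  Forward simulation
hangs off the model via :meth:`BoldWaveModel.simulate`.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .analysis import AnalysisConfig, WaveEstimates, recover_parameters
from .params import HemoParams, ReducedWaveParams
from .synth import FlatMapDataset, NoiseSpec, StimulusSpec, make_flatmap_dataset

__all__ = ["BoldWaveModel", "BoldWaveResults"]


class BoldWaveModel:
    """Traveling-wave model of a flat-map BOLD response.

    Parameters
    ----------
    dataset : FlatMapDataset
        2-D + time BOLD field (percent signal change) with optional embedded
        ground truth.
    config : AnalysisConfig, optional
        Pipeline settings; defaults follow the empirical procedure.
    """

    def __init__(self, dataset: FlatMapDataset, config: AnalysisConfig | None = None):
        self.dataset = dataset
        self.config = config or AnalysisConfig()

    @classmethod
    def from_nifti(cls, path, config: AnalysisConfig | None = None) -> "BoldWaveModel":
        return cls(FlatMapDataset.from_nifti(path), config=config)

    @classmethod
    def simulate(cls, p: HemoParams | ReducedWaveParams,
                 stimulus: StimulusSpec | None = None,
                 centerline=(0.0,),
                 noise: NoiseSpec | None = None,
                 config: AnalysisConfig | None = None) -> "BoldWaveModel":
        """Build a model around a freshly simulated synthetic dataset."""
        ds = make_flatmap_dataset(p, stimulus, centerline, noise)
        return cls(ds, config=config)

    def fit(self) -> "BoldWaveResults":
        est, report = recover_parameters(self.dataset, self.config)
        return BoldWaveResults(self, est, report)


class BoldWaveResults:
    """Fitted wave parameters with uncertainties and diagnostics."""

    _param_names = ["v_F", "v_P", "K_F", "K_P", "Gamma_F", "Gamma_P", "fwhm_mm"]

    def __init__(self, model: BoldWaveModel, estimates: WaveEstimates, report: dict):
        self.model = model
        self.estimates = estimates
        self.report = report

    @property
    def params(self) -> pd.Series:
        e = self.estimates
        return pd.Series({n: getattr(e, n) for n in self._param_names})

    @property
    def bse(self) -> pd.Series:
        e = self.estimates
        return pd.Series({
            "v_F": e.sd_v_F, "v_P": e.sd_v_P,
            "K_F": e.sd_K_F, "K_P": e.sd_K_P,
            "Gamma_F": e.sd_Gamma_F, "Gamma_P": e.sd_Gamma_P,
            "fwhm_mm": np.nan,
        })

    @property
    def flags(self) -> dict:
        return self.estimates.flags

    @property
    def truth_deltas(self) -> dict | None:
        return self.report.get("truth_deltas")

    def summary(self) -> str:
        e = self.estimates
        units = {"v": "mm/s", "K": "1/mm", "Gamma": "1/s"}
        lines = [
            "BOLD traveling-wave estimates",
            "=" * 46,
            f"analysis frequency f0: {e.f0:.4f} Hz",
            f"centerline polynomial order: "
            f"{self.report['centerline']['order']}",
            "",
            f"{'parameter':<12}{'estimate':>10}{'1 s.d.':>10}  unit",
            "-" * 46,
        ]
        for side in ("F", "P"):
            lines.append(f"{'v_' + side:<12}{getattr(e, 'v_' + side):>10.3f}"
                         f"{getattr(e, 'sd_v_' + side):>10.3f}  mm/s")
            lines.append(f"{'Gamma_' + side:<12}{getattr(e, 'Gamma_' + side):>10.3f}"
                         f"{getattr(e, 'sd_Gamma_' + side):>10.3f}  1/s")
            lines.append(f"{'K_' + side:<12}{getattr(e, 'K_' + side):>10.3f}"
                         f"{getattr(e, 'sd_K_' + side):>10.3f}  1/mm")
        lines.append(f"{'FWHM':<12}{e.fwhm_mm:>10.2f}{'':>10}  mm")
        for side, c in self.report.get("consistency", {}).items():
            lines.append(
                f"consistency {side}: |Gamma_t| = {c['abs_Gamma_t']:.3f} vs "
                f"K*v = {c['K_times_v']:.3f}"
                + ("  [VIOLATED >3 s.d.]" if c["violated"] else "")
            )
        if e.flags:
            lines.append(f"flags: {e.flags}")
        deltas = self.truth_deltas
        if deltas:
            lines.append("")
            lines.append("ground-truth comparison (relative errors)")
            for side, d in deltas.items():
                lines.append(f"  {side}: v {d['v_rel_err']:+.1%}, "
                             f"Gamma {d['Gamma_rel_err']:+.1%}, K {d['K_rel_err']:+.1%}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "sd": self.bse})

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.report, indent=1, default=_jsonify)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def __repr__(self):
        return (f"<BoldWaveResults v_F={self.estimates.v_F:.3g} "
                f"v_P={self.estimates.v_P:.3g} flags={self.estimates.flags}>")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float):
        return obj
    return str(obj)
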