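"""Physiological parameterization of the poroelastic hemodynamic model.

The model couples five linearized stages on the cortical sheet:

1. arterial inflow F driven by neural activity z (damped harmonic oscillator,
   rates ``kappa`` and ``gamma_f``);
2. blood-mass density xi obeying mass conservation with inflow source and
   pressure-driven venous outflow;
3. blood momentum with viscous damping ``D`` and pressure-gradient coupling
   ``c1``;
4. the constitutive law P = c2 * xi**beta, with 1/beta the Grubb exponent;
5. deoxyhemoglobin (dHb) concentration Q with oxygen-conversion source
   (psi*xi - Q)*eta and outflow sink,

closed by the semi-empirical BOLD observation equation with coefficients
k1, k2, k3 and resting volume fraction V0.

Eliminating pressure and velocity from stages 2-4 yields a damped wave
equation for xi.  With the shorthand rates ``a = D/rho_f`` (viscous) and
``b = beta/tau`` (outflow; tau = xi0/F0 is the mean transit time) the operator
factorizes as::

    (d/dt + a)(d/dt + b) xi - v_beta**2 * laplacian(xi) = (d/dt + a) F

so the damping rate and propagation speed are::

    2*Gamma   = a + b = beta/tau + D/rho_f
    v_beta**2 = c1 * c2 * beta * xi0**(beta - 1)

These two reduced parameters are the observables of the traveling-wave part
of the BOLD response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import yaml

__all__ = [
    "HemoParams",
    "ReducedWaveParams",
    "derive_reduced_params",
    "InvalidParameterError",
]

_MM_PER_M = 1e3


class InvalidParameterError(ValueError):
    """A physiological parameter set violates its invariants."""


#: units of every HemoParams field, written alongside serialized configs
_UNITS = {
    "kappa": "1/s", "gamma_f": "1/s^2", "F0": "kg m^-3 s^-1",
    "rho_f": "kg m^-3", "xi0": "kg m^-3", "cP": "kg m^-3 s^-1 Pa^-1",
    "c1": "dimensionless", "c2": "Pa (kg m^-3)^-beta",
    "D": "kg m^-3 s^-1", "beta": "dimensionless", "tau": "s",
    "psi": "mmol kg^-1", "eta": "1/s", "V0": "fraction",
    "Q0": "mmol m^-3", "k1": "dimensionless", "k2": "dimensionless",
    "k3": "dimensionless", "a_F": "dimensionless",
}


@dataclass(frozen=True)
class ReducedWaveParams:
    """Reduced parameters of the hemodynamic wave equation.

    Parameters
    ----------
    v_beta : float
        Wave propagation speed (mm/s).
    Gamma : float
        Damping rate (1/s); ``2*Gamma = beta/tau + D/rho_f``.
    a_F : float
        Drive gain coupling the (unit-DC-gain) flow stage into the wave
        equation.  Dimensionless calibration constant; it sets the response
        amplitude and nothing else.
    """

    v_beta: float
    Gamma: float
    a_F: float = 1.0

    def __post_init__(self):
        if not (self.v_beta > 0 and math.isfinite(self.v_beta)):
            raise InvalidParameterError(f"v_beta must be positive, got {self.v_beta}")
        if not (self.Gamma > 0 and math.isfinite(self.Gamma)):
            raise InvalidParameterError(f"Gamma must be positive, got {self.Gamma}")

    @property
    def wave_range_mm(self) -> float:
        """Characteristic e-folding range v_beta/Gamma of the damped wave (mm)."""
        return self.v_beta / self.Gamma


@dataclass(frozen=True)
class HemoParams:
    """Full physiological parameter set.

    Defaults are standard balloon-model literature values where the quantity
    is temporal (kappa, gamma_f, tau, V0, k1-k3, Grubb exponent 0.38) and
    poroelastic constants chosen so the derived reduced parameters sit at
    v_beta = 3 mm/s, Gamma = 0.8 1/s -- the middle of the empirically
    observed range.  All fields are overridable via config.

    Notes
    -----
    ``gamma_f`` is the flow-elimination constant of the inflow oscillator and
    carries units of 1/s**2 (dimensional requirement of the second-order
    stage).  ``Q0`` may be given as ``None``, in which case it is derived
    from the resting steady state of the dHb balance,
    ``Q0 = psi*xi0*eta*tau / (1 + eta*tau)``.
    """

    # flow (inflow oscillator)
    kappa: float = 0.65        # signal decay rate, 1/s
    gamma_f: float = 0.41      # flow elimination constant, 1/s^2
    F0: float = field(default=12.6)  # resting inflow, kg m^-3 s^-1 (= xi0/tau)
    # poroelastic medium
    rho_f: float = 1050.0      # blood density, kg m^-3
    xi0: float = 31.5          # resting blood mass density in tissue, kg m^-3
    cP: float = 8.4e-3         # outflow proportionality constant
    c1: float = 7.182e-8       # pressure-gradient coupling (dimensionless)
    c2: float = 0.1710679886245809  # constitutive proportionality, Pa (kg m^-3)^-beta
    D: float = 574.7368421052631    # viscous damping, kg m^-3 s^-1
    beta: float = 1.0 / 0.38   # reciprocal Grubb exponent, dimensionless
    tau: float = 2.5           # mean transit time, s
    # oxygen / dHb
    psi: float = 2.2           # hemoglobin per unit blood mass, mmol kg^-1
    eta: float = 0.15          # oxygen transfer rate, 1/s
    # BOLD observation
    V0: float = 0.03           # resting blood volume fraction
    Q0: float | None = None    # resting dHb measure; None -> steady state value
    k1: float = 2.8
    k2: float = 2.0
    k3: float = 0.6
    # wave drive gain (calibration constant, see ReducedWaveParams.a_F)
    a_F: float = 1.0

    def __post_init__(self):
        positive = [
            "kappa", "gamma_f", "F0", "rho_f", "xi0", "cP", "c1", "c2",
            "D", "tau", "psi", "eta", "k1", "k2", "k3", "a_F",
        ]
        for name in positive:
            val = getattr(self, name)
            if not (val > 0 and math.isfinite(val)):
                raise InvalidParameterError(f"{name} must be strictly positive, got {val}")
        if self.beta < 1:
            raise InvalidParameterError(f"beta must be >= 1, got {self.beta}")
        if not (0 < self.V0 < 1):
            raise InvalidParameterError(f"V0 must lie in (0, 1), got {self.V0}")
        if self.Q0 is not None and self.Q0 <= 0:
            raise InvalidParameterError(f"Q0 must be positive or None, got {self.Q0}")

    # ---- derived rates used throughout the linear stages -----------------
    @property
    def viscous_rate(self) -> float:
        """a = D/rho_f (1/s): damping via blood viscosity."""
        return self.D / self.rho_f

    @property
    def outflow_rate(self) -> float:
        """b = beta/tau (1/s): damping via venous outflow at boundaries."""
        return self.beta / self.tau

    @property
    def P0(self) -> float:
        """Resting pore pressure from the constitutive law, Pa."""
        return self.c2 * self.xi0 ** self.beta

    @property
    def Q0_effective(self) -> float:
        """Resting dHb consistent with the steady state of the Q balance."""
        if self.Q0 is not None:
            return self.Q0
        return self.psi * self.xi0 * self.eta * self.tau / (1.0 + self.eta * self.tau)

    def with_(self, **kwargs) -> "HemoParams":
        return replace(self, **kwargs)

    # ---- constructors ----------------------------------------------------
    @classmethod
    def from_reduced(cls, reduced: ReducedWaveParams, base: "HemoParams" | None = None) -> "HemoParams":
        """Realize reduced wave parameters as a full physiological set.

        The two damping channels (viscous a = D/rho_f and outflow b = beta/tau)
        are not separately identified by (v_beta, Gamma); the symmetric split
        a = b = Gamma is used.  That split makes the wave operator
        (d/dt + Gamma)**2 - v_beta**2 * laplacian: a nondispersive damped wave
        whose phase speed is exactly v_beta and whose spatial decay is exactly
        Gamma/v_beta at every frequency -- the structure most consistent with
        the empirical finding Gamma = K*v.
        """
        base = base if base is not None else cls()
        tau = base.beta / reduced.Gamma
        D = base.rho_f * reduced.Gamma
        v_si = reduced.v_beta / _MM_PER_M
        c1 = v_si ** 2 * base.xi0 / (base.beta * base.P0)
        # keep the resting balance cP*P0 = F0 = xi0/tau (outflow equals inflow)
        cP = base.xi0 / (tau * base.P0)
        return base.with_(tau=tau, D=D, c1=c1, a_F=reduced.a_F,
                          F0=base.xi0 / tau, cP=cP, Q0=None)

    # ---- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"model": self.to_dict(), "units": dict(_UNITS)},
                           fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "HemoParams":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise KeyError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "HemoParams":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg.get("model", cfg))


def derive_reduced_params(p: HemoParams) -> ReducedWaveParams:
    """Derive (v_beta, Gamma) from the full physiological set.

    ``2*Gamma = beta/tau + D/rho_f`` holds exactly by construction, and
    ``v_beta = sqrt(c1 * c2 * beta * xi0**(beta-1))`` is the closed form of
    the symbolic linearization of the mass/momentum/constitutive stages about
    the resting state (converted from m/s to mm/s).
    """
    Gamma = 0.5 * (p.beta / p.tau + p.D / p.rho_f)
    v2_si = p.c1 * p.c2 * p.beta * p.xi0 ** (p.beta - 1.0)
    if not (Gamma > 0) or not (v2_si > 0):
        raise InvalidParameterError(
            f"derived wave parameters must be positive (Gamma={Gamma}, v_beta^2={v2_si})"
        )
    return ReducedWaveParams(v_beta=math.sqrt(v2_si) * _MM_PER_M, Gamma=Gamma, a_F=p.a_F)
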