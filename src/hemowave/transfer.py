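"""Linearized model stages as Fourier-domain transfer functions.

All stages are rational functions of ``i*omega`` and ``k**2`` with real
coefficients, so Hermitian symmetry ``T(-k, -omega) = conj(T(k, omega))``
holds by construction and every response is real valued.

Convention
----------
Fields are reconstructed as ``exp(+i*(k*x + omega*t))`` modes, i.e. the
forward transform kernel is ``exp(-i*(k*x + omega*t))`` (numpy FFT applied to
both axes), so ``d/dt -> i*omega`` and ``laplacian -> -k**2``.  With damping
Gamma > 0 all poles lie strictly off the real frequency axis.  The companion
:func:`dispersion` helper quotes the ideal damped-wave roots in the physics
``exp(-i*omega*t)`` convention used for the closed form
``omega = -i*Gamma +/- sqrt(v_beta**2 k**2 - Gamma**2)``.

Spatial frequency k is in rad/mm and temporal angular frequency omega in
rad/s; speeds are mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Field, GridMismatchError, SpatioTemporalGrid
from .params import HemoParams, InvalidParameterError, ReducedWaveParams, derive_reduced_params

__all__ = [
    "flow_transfer",
    "dispersion",
    "wave_stage",
    "dhb_transfer",
    "bold_signal",
    "assemble_transfer_functions",
    "TransferFunctionSet",
    "as_full_params",
]


def as_full_params(p: HemoParams | ReducedWaveParams) -> HemoParams:
    """Accept either parameterization; realize reduced sets via the symmetric split."""
    if isinstance(p, ReducedWaveParams):
        return HemoParams.from_reduced(p)
    return p


# --------------------------------------------------------------------------
# individual stages
# --------------------------------------------------------------------------

def flow_transfer(omega, p: HemoParams) -> np.ndarray:
    """Inflow response to neural drive: damped harmonic oscillator.

    Second-order low-pass in (kappa, gamma_f), normalized to unit DC gain so
    that the wave drive gain a_F alone sets response amplitude:
    ``T_Fz = gamma_f / (gamma_f - omega**2 + i*kappa*omega)``.
    """
    omega = np.asarray(omega, dtype=float)
    return p.gamma_f / (p.gamma_f - omega ** 2 + 1j * p.kappa * omega)


def dispersion(k, r: ReducedWaveParams) -> tuple[np.ndarray, np.ndarray]:
    """Both temporal roots of the ideal damped wave equation.

    Roots of ``omega**2 + 2i*Gamma*omega - v_beta**2 k**2 = 0``::

        omega = -i*Gamma +/- sqrt(v_beta**2 k**2 - Gamma**2)

    Both roots have ``Im(omega) <= 0`` (damped modes in the
    ``exp(-i*omega*t)`` convention).  At k = 0 the roots are {0, -2i*Gamma};
    for ``v_beta*k >> Gamma`` the phase speed ``|Re omega|/k -> v_beta``.
    """
    k = np.asarray(k, dtype=float)
    disc = np.lib.scimath.sqrt((r.v_beta * k) ** 2 - r.Gamma ** 2)
    root_plus = -1j * r.Gamma + disc
    root_minus = -1j * r.Gamma - disc
    return root_plus, root_minus


def wave_stage(k, omega, p: HemoParams | ReducedWaveParams) -> np.ndarray:
    """Blood-mass wave response to (normalized) inflow, T_xiF.

    Transfer function of the factorized damped wave operator::

        (i*omega + a)(i*omega + b) + v_beta**2 k**2

    driven by ``a_F * (i*omega + a)``, with a = D/rho_f, b = beta/tau.  The
    product term a*b keeps the response finite at (k, omega) = (0, 0) and
    reduces the k = 0 limit to the balloon-model volume relaxation
    ``(d/dt + beta/tau) xi = a_F * F``.
    """
    p = as_full_params(p)
    red = derive_reduced_params(p)
    if not red.Gamma > 0:
        raise InvalidParameterError("wave stage requires Gamma > 0 (undamped pole)")
    a = p.viscous_rate
    b = p.outflow_rate
    iw = 1j * np.asarray(omega, dtype=float)
    k2 = np.asarray(k, dtype=float) ** 2
    return p.a_F * (iw + a) / ((iw + a) * (iw + b) + red.v_beta ** 2 * k2)


def _dhb_coeffs(omega, p: HemoParams) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients (c_xi, c_F) of the linearized dHb balance.

    In fractional variables q = Q1/Q0, v = xi1/xi0, f = F1/F0 the linearized
    conservation law for dHb reads::

        (d/dt + eta + 1/tau) q = [eta + 1/tau - (beta-1)/tau] v
                                 + V0 (d/dt + beta/tau) v - (V0/tau) f

    The sink carries the washout term (beta-1)/tau * v (volume raises
    pressure-driven outflow faster than it dilutes dHb) and the source is the
    oxygen conversion (psi*xi - Q)*eta, whose resting balance fixes
    psi*xi0/Q0 = 1 + 1/(eta*tau).  The small V0 terms are the advective
    divergence of blood velocity inherited from mass conservation.

    The direct-inflow coefficient carries the drive gain a_F: a_F is the
    calibrated amplitude of the flow perturbation per unit neural drive, so
    it scales f identically in the wave drive and in the dHb dilution term.
    This keeps the whole response proportional to a_F (amplitude calibration
    never changes the stHRF shape).
    """
    iw = 1j * np.asarray(omega, dtype=float)
    r = p.eta + 1.0 / p.tau
    den = iw + r
    c_xi = (r - (p.beta - 1.0) / p.tau + p.V0 * (iw + p.beta / p.tau)) / den
    c_F = -p.a_F * (p.V0 / p.tau) / den
    return c_xi, c_F


def dhb_transfer(k, omega, p: HemoParams) -> np.ndarray:
    """Fractional dHb response to neural drive, T_Qz (Q1/Q0 per unit z).

    First-order relaxation at rate ``eta + 1/tau`` driven by the blood-mass
    wave (through oxygen conversion and outflow washout) and directly by
    inflow (dilution by fully oxygenated arterial blood, the early dHb dip).
    All poles are damped for valid parameters.
    """
    p = as_full_params(p)
    c_xi, c_F = _dhb_coeffs(omega, p)
    T_Fz = flow_transfer(omega, p)
    T_xiz = wave_stage(k, omega, p) * T_Fz
    return c_xi * T_xiz + c_F * T_Fz


def bold_coefficients(p: HemoParams) -> tuple[float, float]:
    """(coefficient of xi1/xi0, coefficient of Q1/Q0) in percent signal change.

    Linearization of y = V0*[k1(1-q) + k2(1-q/v) + k3(1-v)] about rest:
    ``y = 100*V0*[(k2-k3) * xi1/xi0 - (k1+k2) * Q1/Q0]``.
    """
    return 100.0 * p.V0 * (p.k2 - p.k3), -100.0 * p.V0 * (p.k1 + p.k2)


def bold_signal(xi_pert: Field, q_pert: Field, p: HemoParams) -> Field:
    """Linearized BOLD observation from fractional perturbation fields.

    Parameters
    ----------
    xi_pert, q_pert : Field
        Fractional perturbations xi1/xi0 (quantity tag ``xi``) and Q1/Q0
        (tag ``Q``) on the same grid.

    Returns
    -------
    Field
        BOLD signal y in percent signal change.  Zero perturbations map to
        zero signal and the output is linear in both inputs; an isolated
        decrease in Q at fixed xi increases y.
    """
    if not xi_pert.same_grid(q_pert):
        raise GridMismatchError("xi and Q perturbations must share a grid")
    c_xi, c_q = bold_coefficients(p)
    y = c_xi * xi_pert.values + c_q * q_pert.values
    return Field(values=y, grid=xi_pert.grid, quantity="y", units="percent")


def bold_transfer(k, omega, p: HemoParams | ReducedWaveParams) -> np.ndarray:
    """Composed spatiotemporal filter T_yz (percent BOLD per unit neural drive).

    Flow stage x wave stage x dHb stage x observation stage, evaluated at
    arbitrary (k, omega); k and omega must broadcast against each other.
    """
    p = as_full_params(p)
    T_Fz = flow_transfer(omega, p)
    T_xiz = wave_stage(k, omega, p) * T_Fz
    c_xi, c_F = _dhb_coeffs(omega, p)
    T_Qz = c_xi * T_xiz + c_F * T_Fz
    cy_xi, cy_q = bold_coefficients(p)
    return cy_xi * T_xiz + cy_q * T_Qz


# --------------------------------------------------------------------------
# assembled spatiotemporal filters
# --------------------------------------------------------------------------

@dataclass
class TransferFunctionSet:
    """Complex spatiotemporal filters T_Lz for L in {F, xi, Q, y}.

    ``omega`` has shape (nt,); ``k`` holds the radial spatial frequency
    magnitude with shape (nx,) in 1-D or (ny, nx) in 2-D.  T_Fz is purely
    temporal with shape (nt,); the spatial filters have shape k.shape + (nt,).
    """

    omega: np.ndarray
    k: np.ndarray
    T_Fz: np.ndarray
    T_xiz: np.ndarray
    T_Qz: np.ndarray
    T_yz: np.ndarray

    def hermitian_defect(self) -> float:
        """max |T(-k,-omega) - conj(T(k,omega))| over the y filter.

        On the FFT grid, negating a frequency maps index j -> -j (mod n), so
        the reversed-and-rolled array is compared against the conjugate.  On
        even-sized axes the Nyquist bin is its own image only modulo the
        sampling period and is excluded from the comparison.
        """
        defect = 0.0
        for T in (self.T_xiz, self.T_Qz, self.T_yz):
            rev = T
            mask = np.ones(T.shape, dtype=bool)
            for ax in range(T.ndim):  # negate every frequency axis: flip + roll
                rev = np.roll(np.flip(rev, axis=ax), 1, axis=ax)
                n = T.shape[ax]
                if n % 2 == 0:
                    idx = [slice(None)] * T.ndim
                    idx[ax] = n // 2
                    mask[tuple(idx)] = False
            defect = max(defect, float(np.max(np.abs(rev - np.conj(T))[mask])))
        return defect


def _fft_freqs(grid: SpatioTemporalGrid) -> tuple[np.ndarray, np.ndarray]:
    """(k magnitude grid, omega grid) in rad/mm and rad/s on the full FFT lattice."""
    omega = 2.0 * np.pi * np.fft.fftfreq(grid.nt, d=grid.dt)
    kx = 2.0 * np.pi * np.fft.fftfreq(grid.nx, d=grid.dx)
    if grid.is_1d:
        k = np.abs(kx)
    else:
        ky = 2.0 * np.pi * np.fft.fftfreq(grid.ny, d=grid.dx)
        k = np.sqrt(kx[None, :] ** 2 + ky[:, None] ** 2)
    return k, omega


def assemble_transfer_functions(p: HemoParams | ReducedWaveParams,
                                grid: SpatioTemporalGrid) -> TransferFunctionSet:
    """Assemble T_Fz, T_xiz, T_Qz, T_yz on the grid's FFT frequency lattice.

    T_yz is the composition flow-stage x wave-stage x dHb-stage x
    observation-stage of the Fourier-transformed linearized model.  All
    entries are finite for Gamma > 0 and the set is Hermitian symmetric.
    """
    p = as_full_params(p)
    red = derive_reduced_params(p)  # validates Gamma > 0, v_beta > 0
    if red.Gamma <= 0:
        raise InvalidParameterError("Gamma must be positive (undamped pole)")
    k, omega = _fft_freqs(grid)
    kb = k[..., None]  # broadcast against omega on the last axis
    T_Fz = flow_transfer(omega, p)
    T_xiz = wave_stage(kb, omega, p) * T_Fz
    c_xi, c_F = _dhb_coeffs(omega, p)
    T_Qz = c_xi * T_xiz + c_F * T_Fz
    cy_xi, cy_q = bold_coefficients(p)
    T_yz = cy_xi * T_xiz + cy_q * T_Qz
    for name, T in (("T_Fz", T_Fz), ("T_xiz", T_xiz), ("T_Qz", T_Qz), ("T_yz", T_yz)):
        if not np.all(np.isfinite(T)):
            raise InvalidParameterError(f"{name} has non-finite entries (pole on grid)")
    return TransferFunctionSet(omega=omega, k=k, T_Fz=T_Fz, T_xiz=T_xiz,
                               T_Qz=T_Qz, T_yz=T_yz)
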