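"""Governing equations, boundary conditions and residual functionals.

The steady 1-D cleft model, after one integration of the convection-diffusion
equation using the zero-inlet-flux condition, is the first-order system

    -D dc/dy + v c = 2 j y / b          (axial ion flux balance)
    dv/dy = (2 f_aq / b) (c - c3)       (volume conservation, aquaporin influx)

on y in [0, L], with boundary conditions

    c(L) = c4                           (open end at interstitial osmolarity)
    v(0) = k_TJ RT (c(0) - c1)          (osmotically driven TJ water velocity)

The sign convention is v > 0 from the tight junction (y = 0) toward the
interstitium (y = L).  The ion pump flux j is uniform along the cleft, and
hydrostatic pressure is neglected against the osmotic driving terms.

This module knows nothing about solution strategies; it only evaluates the
right-hand side, the TJ velocity, the nondimensional groups and the discrete
residuals of a candidate profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Parameters, derived_scales

__all__ = [
    "StateDerivative",
    "ResidualReport",
    "NondimensionalGroups",
    "rhs",
    "tj_velocity",
    "residuals",
    "nondimensional_groups",
    "pressure_neglect_ratio",
]


@dataclass(frozen=True)
class StateDerivative:
    dc_dy: float  # concentration gradient [mol cm^-4]
    dv_dy: float  # velocity gradient [s^-1]


@dataclass(frozen=True)
class ResidualReport:
    """Defect of a profile against the governing equations (all >= 0).

    ``ion_flux_residual`` and ``volume_residual`` are dimensionless (scaled by
    the total pumped flux 2jL/b and the outlet velocity scale respectively);
    the boundary entries are absolute, in mol/cm^3 and cm/s.
    """

    bc_outlet: float            # |c(L) - c4|
    bc_inlet_velocity: float    # |v(0) - k_TJ RT (c(0) - c1)|
    ion_flux_residual: float    # max_y |-D c' + v c - 2 j y / b| / (2 j L / b)
    volume_residual: float      # |v(L) - v(0) - (2 f_aq/b) int (c - c3) dy| / vel scale

    def max_dimensionless(self) -> float:
        return max(self.ion_flux_residual, self.volume_residual)


@dataclass(frozen=True)
class NondimensionalGroups:
    """Dimensionless groups of the scaled system.

    With Y = y/L, C = c/c3, V = v L / D the system reads

        C' = V C - alpha Y,   V' = beta (C - 1),
        C(1) = c4/c3,         V(0) = gamma (C(0) - c1/c3),

    alpha = 2 j L^2 / (b D c3)      (pumping vs diffusion),
    beta  = 2 f_aq c3 L^2 / (b D)   (aquaporin influx vs diffusion),
    gamma = k_TJ RT c3 L / D        (TJ conductance vs diffusion).
    """

    alpha: float
    beta: float
    gamma: float
    c1r: float  # c1/c3
    c4r: float  # c4/c3


def nondimensional_groups(params: Parameters) -> NondimensionalGroups:
    L, b, D, c3 = params.L, params.b, params.D, params.c3
    return NondimensionalGroups(
        alpha=2.0 * params.j * L * L / (b * D * c3),
        beta=2.0 * params.f_aq * c3 * L * L / (b * D),
        gamma=params.k_TJ * params.RT * c3 * L / D,
        c1r=params.c1 / c3,
        c4r=params.c4 / c3,
    )


def rhs(y: float, c: float, v: float, params: Parameters) -> StateDerivative:
    """Derivatives (dc/dy, dv/dy) of the reduced first-order system.

    dc/dy = (v c - 2 j y / b) / D, dv/dy = (2 f_aq / b)(c - c3).  Note the
    lateral aquaporin flow vanishes (and reverses) where c crosses c3.
    """
    if c <= 0:
        raise ValueError(f"nonphysical state: concentration c = {c:g} <= 0 at y = {y:g}")
    dc_dy = (v * c - 2.0 * params.j * y / params.b) / params.D
    dv_dy = 2.0 * params.f_aq / params.b * (c - params.c3)
    return StateDerivative(dc_dy=dc_dy, dv_dy=dv_dy)


def tj_velocity(c0: float, params: Parameters) -> float:
    """Water velocity through the tight junction, k_TJ RT (c(0) - c1) [cm/s].

    Positive (absorption, into the cleft) when the inlet cleft osmolarity
    exceeds the lumen's; negative (secretion into the lumen) otherwise.
    """
    if c0 <= 0:
        raise ValueError(f"nonphysical inlet concentration c0 = {c0:g}")
    return params.k_TJ * params.RT * (c0 - params.c1)


def pressure_neglect_ratio(params: Parameters, delta_c: float = 100e-6,
                           delta_p: float = 1e5) -> float:
    """Ratio RT*dc / dp justifying the neglect of hydrostatic pressure.

    At a typical osmotic difference of 100 mM (1e-4 mol/cm^3), RT*dc is
    ~2.58e6 CGS while a generous 0.1 atm pressure difference is 1e5 CGS —
    a factor ~26.  ``mu`` is therefore carried but unused.
    """
    return params.RT * delta_c / delta_p


def residuals(y: np.ndarray, c: np.ndarray, v: np.ndarray,
              params: Parameters) -> ResidualReport:
    """Discrete residuals of a candidate profile on its own mesh.

    The ion-flux defect is evaluated at cell midpoints with the same
    second-order midpoint (box) operators the relaxation solver uses; the
    volume integral uses the trapezoid rule (exactly the box scheme's
    quadrature).  The mesh must be strictly increasing and cover [0, L].
    """
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    v = np.asarray(v, dtype=float)
    if y.ndim != 1 or y.shape != c.shape or y.shape != v.shape:
        raise ValueError("y, c, v must be 1-D arrays of equal length")
    if y.size < 2 or np.any(np.diff(y) <= 0):
        raise ValueError("mesh must be strictly increasing")
    if abs(y[0]) > 1e-12 * params.L or abs(y[-1] - params.L) > 1e-9 * params.L:
        raise ValueError(
            f"mesh must cover [0, L]: got [{y[0]:g}, {y[-1]:g}], L = {params.L:g}"
        )

    h = np.diff(y)
    cm = 0.5 * (c[1:] + c[:-1])
    vm = 0.5 * (v[1:] + v[:-1])
    ym = 0.5 * (y[1:] + y[:-1])
    flux_defect = -params.D * np.diff(c) / h + vm * cm - 2.0 * params.j * ym / params.b
    # normalization: total pumped flux, with a diffusive floor for j = 0
    flux_scale = max(2.0 * params.j * params.L / params.b,
                     params.D * float(np.max(c)) / params.L)
    ion_flux_residual = float(np.max(np.abs(flux_defect))) / flux_scale

    lateral = 2.0 * params.f_aq / params.b * np.trapezoid(c - params.c3, y)
    vol_defect = abs((v[-1] - v[0]) - lateral)
    scales = derived_scales(params)
    AL = 0.0 if not np.isfinite(scales.y_inh) else scales.v_hom_L
    vel_scale = max(abs(v[-1]), AL, params.D / params.L)
    volume_residual = vol_defect / vel_scale

    return ResidualReport(
        bc_outlet=float(abs(c[-1] - params.c4)),
        bc_inlet_velocity=float(abs(v[0] - tj_velocity(float(c[0]), params))),
        ion_flux_residual=ion_flux_residual,
        volume_residual=volume_residual,
    )
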