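"""Closed-form and non-perturbative approximate solutions of the cleft model.

Three families, each anchored to the homogeneous state (c_hom, v = A*y):

* homogeneous — the exact interior solution with constant concentration; it
  satisfies the governing equations identically but ignores the outlet
  boundary condition.
* long cleft (L >= y_inh) — homogeneous plus an outlet boundary-layer
  correction: the disturbance (c4 - c_hom) decays into the cleft as
  ``exp((y^2 - L^2)/y_inh^2) * (y/L)**p`` with ``p = f_aq c_hom^2 / j``.
* short cleft (L well below the modified scale) — parabolic profiles from the
  global conservation laws.  Variant 2 is fully explicit; variant 1 carries a
  free dimensionless inlet offset C0 = (c(0) - c_hom)/c_hom, obtained here by
  least squares against the relaxation solution (a closed form exists but is
  unwieldy; the fitted route is the default and is labelled as such).

All approximations satisfy c(L) = c4 exactly by construction.  Velocities are
reconstructed from volume conservation (integrating dv/dy = (2 f_aq/b)(c-c3)
with the concentration ansatz), plus the TJ inlet velocity, so the volume
budget is consistent with the concentration formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import tj_velocity
from .params import Parameters, ParameterError, derived_scales

__all__ = [
    "ApproxProfile",
    "ShortCleftCoeffs",
    "homogeneous_profile",
    "long_cleft_profile",
    "short_cleft_profile",
    "fit_C0",
    "inlet_shift",
]


@dataclass(eq=False)
class ApproxProfile:
    """Analytical profile on a mesh (CGS), tagged with its validity claim."""

    y: np.ndarray
    c: np.ndarray
    v: np.ndarray
    approx_kind: str  # homogeneous | long_cleft | short_cleft_v1 | short_cleft_v2
    validity: str


@dataclass(frozen=True)
class ShortCleftCoeffs:
    """Dimensionless inlet offset C0 of the variant-1 parabolic ansatz."""

    C0: float
    source: str  # "fitted" | "supplementary_closed_form"


def _as_mesh(params: Parameters, mesh) -> np.ndarray:
    if mesh is None:
        return np.linspace(0.0, params.L, 513)
    if isinstance(mesh, int):
        return np.linspace(0.0, params.L, mesh)
    y = np.asarray(mesh, dtype=float)
    if y.ndim != 1 or y.size < 2 or np.any(np.diff(y) <= 0):
        raise ValueError("mesh must be a strictly increasing 1-D array")
    return y


def homogeneous_profile(params: Parameters, mesh=None) -> ApproxProfile:
    """The interior solution c = c_hom, v = A*y (exact away from boundaries)."""
    if params.f_aq <= 0 and params.j > 0:
        raise ParameterError("homogeneous profile undefined for f_aq = 0 with j > 0")
    y = _as_mesh(params, mesh)
    s = derived_scales(params)
    c = np.full_like(y, s.c_hom)
    v = s.A * y
    return ApproxProfile(
        y=y, c=c, v=v, approx_kind="homogeneous",
        validity="exact solution of the interior equations; ignores c(L) = c4",
    )


def _validity_note(params: Parameters, expected: str) -> str:
    s = derived_scales(params)
    if s.regime == expected:
        return f"valid: regime is {expected}"
    return (
        f"warning: formula derived for {expected} clefts but regime is "
        f"{s.regime} (L = {params.L:g} cm, y_inh = {s.y_inh:g} cm)"
    )


def long_cleft_profile(params: Parameters, mesh=None) -> ApproxProfile:
    """Homogeneous state plus the outlet boundary-layer correction.

    c = c_hom + (c4 - c_hom) E(y),
    E(y) = exp((y^2 - L^2)/y_inh^2) * (y/L)^p,  p = f_aq c_hom^2 / j,
    so E(L) = 1 (outlet condition exact) and E decays toward the interior
    over the scale y_inh.  The matching velocity correction is
    dv = D f_aq c_hom (c4 - c_hom) / (j y) * E(y).
    """
    if params.j <= 0:
        raise ParameterError("long-cleft formula requires j > 0")
    y = _as_mesh(params, mesh)
    s = derived_scales(params)
    L, y_inh = params.L, s.y_inh
    p = params.f_aq * s.c_hom**2 / params.j
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.exp((y**2 - L**2) / y_inh**2) * np.where(y > 0, (y / L) ** p, 0.0)
        dv = np.where(
            y > 0,
            params.D * params.f_aq * s.c_hom * (params.c4 - s.c_hom)
            / (params.j * np.where(y > 0, y, 1.0)) * E,
            0.0,
        )
    c = s.c_hom + (params.c4 - s.c_hom) * E
    v = tj_velocity(float(c[0]), params) + s.A * y + dv
    return ApproxProfile(
        y=y, c=c, v=v, approx_kind="long_cleft",
        validity=_validity_note(params, "long"),
    )


def short_cleft_profile(
    params: Parameters,
    mesh=None,
    variant: int = 2,
    coeffs: ShortCleftCoeffs | None = None,
) -> ApproxProfile:
    """Parabolic short-cleft approximations from the global conservation laws.

    Variant 2 (explicit): c = c_hom + (c4 - c_hom) [1 + kappa (y^2 - L^2)/y_inh^2]
    with kappa = 1 + f_aq c_hom c4 / j.  Variant 1 replaces the inlet value by
    the free offset C0: c = c_hom [1 + C0 + ((c4 - c_hom)/c_hom - C0) y^2/L^2];
    it needs :class:`ShortCleftCoeffs` (see :func:`fit_C0`) and is the more
    accurate of the two.  Both satisfy c(L) = c4 exactly.
    """
    if params.j <= 0:
        raise ParameterError("short-cleft formulas require j > 0")
    if variant not in (1, 2):
        raise ValueError("variant must be 1 or 2")
    y = _as_mesh(params, mesh)
    s = derived_scales(params)
    L = params.L
    dc4 = params.c4 - s.c_hom
    two_faq_b = 2.0 * params.f_aq / params.b

    if variant == 2:
        kappa = 1.0 + params.f_aq * s.c_hom * params.c4 / params.j
        delta_c = dc4 * (1.0 + kappa * (y**2 - L**2) / s.y_inh**2)
        # integral of delta_c from 0 to y, for the velocity correction
        int_dc = dc4 * (y + kappa * (y**3 / 3.0 - L**2 * y) / s.y_inh**2)
        kind = "short_cleft_v2"
    else:
        if coeffs is None:
            raise ValueError(
                "variant 1 requires ShortCleftCoeffs (use fit_C0 or supply a "
                "closed-form coefficient)"
            )
        C0 = coeffs.C0
        delta_c = s.c_hom * C0 + (dc4 - s.c_hom * C0) * y**2 / L**2
        int_dc = s.c_hom * C0 * y + (dc4 - s.c_hom * C0) * y**3 / (3.0 * L**2)
        kind = "short_cleft_v1"

    c = s.c_hom + delta_c
    if np.any(c <= 0):
        raise ParameterError(
            "short-cleft ansatz produced non-positive concentration; the "
            "parameters are outside the formula's validity region"
        )
    v = tj_velocity(float(c[0]), params) + s.A * y + two_faq_b * int_dc
    return ApproxProfile(
        y=y, c=c, v=v, approx_kind=kind, validity=_validity_note(params, "short"),
    )


def fit_C0(params: Parameters, options=None) -> ShortCleftCoeffs:
    """Fit the variant-1 inlet offset C0 to the relaxation solution.

    With the ansatz shape fixed, C0 is the single linear coefficient; it is
    estimated by continuous least squares (trapezoid inner products) of
    ``delta_c(y) - (c4 - c_hom) y^2/L^2`` against the basis function
    ``c_hom (1 - y^2/L^2)`` on the solver's own mesh.
    """
    from .solvers import solve_relaxation

    s = derived_scales(params)
    prof = solve_relaxation(params, options)
    y, c = prof.y, prof.c
    w = 1.0 - (y / params.L) ** 2
    r = (c - s.c_hom) - (params.c4 - s.c_hom) * (y / params.L) ** 2
    denom = np.trapezoid(w * w, y)
    C0 = float(np.trapezoid(w * r, y) / (s.c_hom * denom))
    return ShortCleftCoeffs(C0=C0, source="fitted")


def inlet_shift(params: Parameters) -> float:
    """Approximate inlet offset c(0) - c_hom for short clefts [mol/cm^3].

    The parabolic ansatz evaluated at y = 0:
    ``(c4 - c_hom) (1 - kappa L^2 / y_inh^2)``, kappa = 1 + f_aq c_hom c4 / j.
    As L -> 0 the shift tends to (c4 - c_hom), i.e. c(0) -> c4; the outlet
    disturbance is always reduced at the inlet, more strongly the longer the
    cleft.
    """
    if params.j <= 0:
        raise ParameterError("inlet_shift requires j > 0")
    s = derived_scales(params)
    kappa = 1.0 + params.f_aq * s.c_hom * params.c4 / params.j
    return (params.c4 - s.c_hom) * (1.0 - kappa * params.L**2 / s.y_inh**2)
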