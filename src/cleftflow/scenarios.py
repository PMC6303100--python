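"""Flux partitioning, parameter sweeps and daily-volume estimates.

These are the computational experiments the model exists for: how the water
flux splits between the tight junction, the lateral aquaporin membrane and
the open cleft end, how that split responds to cleft length, cleft width,
lumen and cytosol osmolarity, and what the fluxes amount to per unit
epithelial area and day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import MM_TO_CGS, NM_TO_CM, UM_TO_CM, Parameters
from .solvers import CleftProfile, SolverOptions, solve

__all__ = [
    "FluxSummary",
    "SweepResult",
    "flux_summary",
    "sweep",
    "volume_per_area",
    "linked_c3",
    "DEFAULT_CLEFT_LINE_DENSITY",
]

#: cleft line density [cm of cleft per cm^2 of epithelium] for square cells of
#: side 10 um (perimeter shared between neighbours: 2 sides per cell).  A
#: geometry convention of this package, not a measured constant.
DEFAULT_CLEFT_LINE_DENSITY = 2.0 / (10 * UM_TO_CM)


@dataclass(frozen=True)
class FluxSummary:
    """Per-unit-depth volumetric flux partition of one converged profile (CGS).

    ``Q_tj + Q_lateral = Q_out`` to solver tolerance (volume conservation).
    ``c_e`` (efflux osmolarity 2jL/(b v(L))) is only defined when water
    actually leaves through the open end (v(L) > 0).
    """

    v0: float                      # TJ velocity [cm/s]
    vL: float                      # outlet velocity [cm/s]
    Q_tj: float                    # v0*b [cm^2/s]
    Q_lateral: float               # 2 f_aq int (c - c3) dy [cm^2/s]
    Q_out: float                   # vL*b [cm^2/s]
    c_e: float | None              # efflux concentration [mol/cm^3], None if vL <= 0
    tj_fraction: float             # v0 / vL
    lateral_sign_switch_y: float | None  # first y with c(y) = c3, if interior

    @property
    def c_e_mM(self) -> float | None:
        return None if self.c_e is None else self.c_e / MM_TO_CGS


def flux_summary(profile: CleftProfile, params: Parameters) -> FluxSummary:
    """Summarize the flux partition of a converged profile."""
    y, c, v = profile.y, profile.c, profile.v
    v0, vL = float(v[0]), float(v[-1])
    Q_tj = v0 * params.b
    Q_lateral = 2.0 * params.f_aq * float(np.trapezoid(c - params.c3, y))
    Q_out = vL * params.b
    c_e = 2.0 * params.j * params.L / (params.b * vL) if vL > 0 else None
    tj_fraction = v0 / vL if vL != 0 else float("nan")

    switch = None
    s = c - params.c3
    signs = np.sign(s)
    for i in range(len(y) - 1):
        if signs[i] != 0 and signs[i + 1] != 0 and signs[i] != signs[i + 1]:
            # linear interpolation of the crossing
            t = s[i] / (s[i] - s[i + 1])
            switch = float(y[i] + t * (y[i + 1] - y[i]))
            break
        if signs[i + 1] == 0 and 0 < i + 1 < len(y) - 1:
            switch = float(y[i + 1])
            break
    return FluxSummary(
        v0=v0, vL=vL, Q_tj=Q_tj, Q_lateral=Q_lateral, Q_out=Q_out,
        c_e=c_e, tj_fraction=tj_fraction, lateral_sign_switch_y=switch,
    )


_SWEEPABLE = ("L", "b", "c1", "c3")
_USER_SCALE = {"L": UM_TO_CM, "b": NM_TO_CM, "c1": MM_TO_CGS, "c3": MM_TO_CGS}
_USER_UNIT = {"L": "um", "b": "nm", "c1": "mM", "c3": "mM"}


@dataclass(eq=False)
class SweepResult:
    """Tidy result of a 1-D parameter sweep."""

    varied: str
    values: list                     # swept values in CGS
    summaries: list                  # FluxSummary or None per point
    converged: list                  # bool per point
    errors: list                     # str or None per point
    profiles: list | None = None     # retained CleftProfiles if requested

    def to_dataframe(self) -> pd.DataFrame:
        unit = _USER_UNIT[self.varied]
        scale = _USER_SCALE[self.varied]
        rows = []
        for val, summ, conv, err in zip(
            self.values, self.summaries, self.converged, self.errors
        ):
            row = {
                f"{self.varied}_{unit}": val / scale,
                "v0_cm_per_s": None, "vL_cm_per_s": None,
                "Q_tj_cm2_per_s": None, "Q_lateral_cm2_per_s": None,
                "Q_out_cm2_per_s": None, "c_e_mM": None,
                "tj_fraction": None, "converged": conv, "error": err,
            }
            if summ is not None:
                row.update(
                    v0_cm_per_s=summ.v0, vL_cm_per_s=summ.vL,
                    Q_tj_cm2_per_s=summ.Q_tj, Q_lateral_cm2_per_s=summ.Q_lateral,
                    Q_out_cm2_per_s=summ.Q_out, c_e_mM=summ.c_e_mM,
                    tj_fraction=summ.tj_fraction,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def sweep(
    params: Parameters,
    vary: str,
    values,
    options: SolverOptions | None = None,
    keep_profiles: bool = False,
) -> SweepResult:
    """Solve the BVP along a 1-D sweep of ``vary`` in {L, b, c1, c3}.

    Values are CGS floats.  Each point is warm-started from the previous
    converged profile; individual failures are recorded and the sweep
    continues.
    """
    if vary not in _SWEEPABLE:
        raise ValueError(f"vary must be one of {_SWEEPABLE}, got {vary!r}")
    values = [float(v) for v in values]
    summaries, converged, errors, profiles = [], [], [], []
    prev = None
    for val in values:
        try:
            pk = params.replace(**{vary: val})
            initial = (prev.y, prev.c, prev.v) if prev is not None else None
            prof = solve(pk, options, initial=initial)
            summaries.append(flux_summary(prof, pk))
            converged.append(bool(prof.solver_meta.converged))
            errors.append(None)
            prev = prof
            profiles.append(prof if keep_profiles else None)
        except Exception as exc:  # record and continue
            summaries.append(None)
            converged.append(False)
            errors.append(str(exc))
            profiles.append(None)
    return SweepResult(
        varied=vary, values=values, summaries=summaries, converged=converged,
        errors=errors, profiles=profiles if keep_profiles else None,
    )


def volume_per_area(
    summary: FluxSummary,
    geometry: float = DEFAULT_CLEFT_LINE_DENSITY,
    duration: float = 86400.0,
    pathway: str = "tj",
) -> float:
    """Volume flux per unit epithelial area [cm^3 per cm^2 per ``duration``].

    ``geometry`` is the cleft line density (cm of cleft edge per cm^2 of
    epithelium; default corresponds to square 10 um cells).  Pathway "tj"
    uses |v0|*b (water crossing the tight junctions), "open_end" uses v(L)*b
    (total efflux at the cleft mouth).
    """
    if geometry <= 0:
        raise ValueError("geometry (cleft line density) must be positive")
    if pathway == "tj":
        q = abs(summary.Q_tj)
    elif pathway == "open_end":
        q = summary.Q_out
    else:
        raise ValueError("pathway must be 'tj' or 'open_end'")
    return q * geometry * duration


def linked_c3(c1: float, slope: float = 0.5, c1_ref: float = 300 * MM_TO_CGS,
              c3_ref: float = 300 * MM_TO_CGS) -> float:
    """Cytosolic osmolarity linearly coupled to the lumen's (CGS).

    A documented convenience for scenarios where the cell osmolarity rises
    with lumen osmolarity: c3 = c3_ref + slope * (c1 - c1_ref).  The coupling
    is phenomenological; the slope is a free choice.
    """
    return c3_ref + slope * (c1 - c1_ref)
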