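"""Physiological parameters, unit handling, and the derived scales of the cleft model.

All internal arithmetic is done in CGS units with concentrations in mol/cm^3.
User-facing I/O uses the physiological units the field quotes (mM, nm, um,
aquaporins per um^2); every config value must carry its unit explicitly, so a
bare number is rejected rather than silently misread.

Two derived quantities organize everything downstream:

* ``c_hom`` — the intrinsic homogeneous cleft osmolarity, the positive root of
  ``c_hom^2 - c3*c_hom - j/f_aq = 0``.  It depends only on the cytosolic
  osmolarity ``c3``, the lateral ion pump flux ``j`` and the aggregate
  aquaporin coefficient ``f_aq``; it always exceeds ``c3``.
* ``y_inh`` — the inhomogeneity length ``sqrt(D*b*c_hom/j)``, the distance over
  which the outlet boundary disturbance relaxes back to ``c_hom``.  Clefts much
  longer than ``y_inh`` develop the homogeneous regime; shorter ones do not.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "ParameterError",
    "Parameters",
    "DerivedScales",
    "load_parameters",
    "compute_faq",
    "compute_ktj",
    "compute_chom",
    "compute_yinh",
    "classify_regime",
    "derived_scales",
    "MM_TO_CGS",
    "NM_TO_CM",
    "UM_TO_CM",
]

# unit conversion factors into CGS
MM_TO_CGS = 1e-6          # 1 mM = 1e-6 mol/cm^3
NM_TO_CM = 1e-7
UM_TO_CM = 1e-4
PER_UM2_TO_PER_CM2 = 1e8

_RT_DEFAULT = 310.15 * 8.314e7  # g cm^2 s^-2 mol^-1 at 37 C


class ParameterError(ValueError):
    """Raised for invalid or inconsistent physiological parameters."""


@dataclass(frozen=True)
class Parameters:
    """Full physiological parameter set in CGS units.

    Defaults are the tabulated constants for a moderately leaky absorbing
    epithelium (mammalian small intestine); for the range-valued geometry and
    lumen entries the wide-cleft, long-cleft, hypertonic-lumen baseline is
    used (b = 400 nm, L = 100 um, c1 = 600 mM).

    ``mu`` (viscosity) is carried for completeness but never used: hydrostatic
    pressure contributions are neglected, being ~26x smaller than the osmotic
    ones at the typical 100 mM concentration differences (see
    :func:`cleftflow.model.pressure_neglect_ratio`).
    """

    k_aq: float = 5e-14        # single-aquaporin water permeability [cm^3/s]
    D: float = 1e-5            # ion diffusion coefficient [cm^2/s]
    n_aq: float = 1e11         # aquaporin areal density [cm^-2] (= 1e3 um^-2)
    j: float = 18.5e-9         # ion flux through lateral membrane [mol cm^-2 s^-1]
    b: float = 400 * NM_TO_CM  # cleft width [cm]
    L: float = 100 * UM_TO_CM  # cleft length [cm]
    mu: float = 0.7e-2         # viscosity [g cm^-1 s^-1], reserved (pressure neglected)
    RT: float = _RT_DEFAULT    # thermal energy per mole [g cm^2 s^-2 mol^-1]
    V_wat: float = 18.0        # molar volume of water [cm^3/mol]
    w_TJ: float = 2e-7         # TJ pore width [cm] (2 nm, moderately leaky)
    P_f: float = 13.1e-3       # TJ hydraulic permeability [cm/s]
    c1: float = 600 * MM_TO_CGS  # lumen osmolarity [mol/cm^3]
    c3: float = 300 * MM_TO_CGS  # cytosol osmolarity [mol/cm^3]
    c4: float = 300 * MM_TO_CGS  # interstitium osmolarity [mol/cm^3]

    def __post_init__(self) -> None:
        # mu is merely carried; j, n_aq, k_aq, P_f may vanish (no pumping, no
        # aquaporins, sealed TJ) to represent degenerate limits.
        nonneg = {"mu", "j", "n_aq", "k_aq", "P_f"}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                raise ParameterError(f"parameter {f.name!r} is not finite: {value}")
            if f.name in nonneg:
                if value < 0:
                    raise ParameterError(f"parameter {f.name!r} must be >= 0, got {value}")
            elif value <= 0:
                raise ParameterError(
                    f"parameter {f.name!r} must be strictly positive, got {value}"
                )
        if not self.b < self.L:
            raise ParameterError(
                f"cleft width b={self.b:g} cm must be smaller than length "
                f"L={self.L:g} cm (narrow-channel geometry)"
            )
        for name in ("c1", "c3", "c4"):
            mm = getattr(self, name) / MM_TO_CGS
            if not 0 < mm < 10_000:
                raise ParameterError(
                    f"osmolarity {name} = {mm:g} mM outside (0, 10000) mM; "
                    "this usually indicates a unit-conversion error"
                )

    def replace(self, **changes: float) -> "Parameters":
        """Return a copy with the given CGS fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    @property
    def f_aq(self) -> float:
        """Aggregate aquaporin transport coefficient [cm^4 mol^-1 s^-1]."""
        return compute_faq(self.k_aq, self.V_wat, self.n_aq)

    @property
    def k_TJ(self) -> float:
        """Tight-junction osmotic conductance [cm^2 s g^-1]."""
        return compute_ktj(self.P_f, self.V_wat, self.w_TJ, self.RT, self.b)

    def to_user_units(self) -> dict:
        """Parameters expressed in the user-facing units (mM, nm, um, ...)."""
        return {
            "k_aq": f"{self.k_aq:g} cm3/s",
            "D": f"{self.D:g} cm2/s",
            "n_aq": f"{self.n_aq / PER_UM2_TO_PER_CM2:g} um^-2",
            "j": f"{self.j:g} mol/cm2/s",
            "b": f"{self.b / NM_TO_CM:g} nm",
            "L": f"{self.L / UM_TO_CM:g} um",
            "mu": f"{self.mu:g} g/cm/s",
            "RT": f"{self.RT:g} erg/mol",
            "V_wat": f"{self.V_wat:g} cm3/mol",
            "w_TJ": f"{self.w_TJ / NM_TO_CM:g} nm",
            "P_f": f"{self.P_f:g} cm/s",
            "c1": f"{self.c1 / MM_TO_CGS:g} mM",
            "c3": f"{self.c3 / MM_TO_CGS:g} mM",
            "c4": f"{self.c4 / MM_TO_CGS:g} mM",
        }

    def to_cgs_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


# accepted unit spellings per field -> factor into CGS
_FIELD_UNITS: dict[str, dict[str, float]] = {
    "k_aq": {"cm3/s": 1.0, "cm^3/s": 1.0, "cm3·s-1": 1.0},
    "D": {"cm2/s": 1.0, "cm^2/s": 1.0},
    "n_aq": {"um^-2": PER_UM2_TO_PER_CM2, "um-2": PER_UM2_TO_PER_CM2,
             "per_um2": PER_UM2_TO_PER_CM2, "cm^-2": 1.0, "cm-2": 1.0},
    "j": {"mol/cm2/s": 1.0, "mol/cm^2/s": 1.0},
    "b": {"nm": NM_TO_CM, "um": 1e-4, "cm": 1.0},
    "L": {"um": UM_TO_CM, "nm": NM_TO_CM, "cm": 1.0},
    "mu": {"g/cm/s": 1.0, "poise": 1.0, "p": 1.0},
    "RT": {"erg/mol": 1.0, "g·cm2/s2/mol": 1.0, "cgs": 1.0},
    "V_wat": {"cm3/mol": 1.0, "cm^3/mol": 1.0},
    "w_TJ": {"nm": NM_TO_CM, "cm": 1.0},
    "P_f": {"cm/s": 1.0},
    "c1": {"mm": MM_TO_CGS, "mol/cm3": 1.0, "mol/cm^3": 1.0},
    "c3": {"mm": MM_TO_CGS, "mol/cm3": 1.0, "mol/cm^3": 1.0},
    "c4": {"mm": MM_TO_CGS, "mol/cm3": 1.0, "mol/cm^3": 1.0},
}


def _parse_quantity(field: str, raw) -> float:
    """Parse a "value unit" string (or a (value, unit) pair) into CGS."""
    if isinstance(raw, (tuple, list)) and len(raw) == 2:
        value, unit = raw
    elif isinstance(raw, str):
        parts = raw.split()
        if len(parts) != 2:
            raise ParameterError(
                f"field {field!r}: expected 'value unit' (e.g. '600 mM'), got {raw!r}"
            )
        value, unit = parts
    else:
        raise ParameterError(
            f"field {field!r}: bare number {raw!r} rejected; "
            "give the unit explicitly, e.g. '600 mM'"
        )
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise ParameterError(f"field {field!r}: cannot parse number in {raw!r}") from exc
    units = _FIELD_UNITS[field]
    key = str(unit).strip().lower().replace("µ", "u")
    lookup = {k.lower(): v for k, v in units.items()}
    if key not in lookup:
        raise ParameterError(
            f"field {field!r}: unknown unit {unit!r}; accepted: {sorted(units)}"
        )
    return value * lookup[key]


def load_parameters(
    config: Mapping[str, object] | None = None,
    overrides: Mapping[str, object] | None = None,
) -> Parameters:
    """Build a validated :class:`Parameters` from a config mapping.

    ``config`` maps field names to "value unit" strings (as read from a YAML
    file); ``overrides`` (e.g. CLI flags) take precedence over ``config``.
    Unknown keys are rejected.  Missing keys fall back to the tabulated
    defaults.
    """
    merged: dict[str, object] = {}
    for source in (config or {}), (overrides or {}):
        for key, raw in source.items():
            if key not in _FIELD_UNITS:
                raise ParameterError(
                    f"unknown parameter {key!r}; known: {sorted(_FIELD_UNITS)}"
                )
            merged[key] = raw
    values = {field: _parse_quantity(field, raw) for field, raw in merged.items()}
    return Parameters(**values)


def compute_faq(k_aq: float, V_wat: float, n_aq: float) -> float:
    """Aggregate aquaporin coefficient f_aq = k_aq * V_wat * n_aq.

    The lateral water velocity entering the cleft is ``f_aq * (c - c3)``, so
    f_aq carries cm^4 mol^-1 s^-1.  Zero density (no aquaporins) gives zero.
    """
    if k_aq < 0 or V_wat < 0 or n_aq < 0:
        raise ParameterError("compute_faq: inputs must be non-negative")
    return k_aq * V_wat * n_aq


def compute_ktj(P_f: float, V_wat: float, w_TJ: float, RT: float, b: float) -> float:
    """TJ osmotic conductance k_TJ = P_f * V_wat * w_TJ / (RT * b).

    ``k_TJ * RT * (c(0) - c1)`` is the water velocity through the tight
    junction; note k_TJ itself scales as 1/b while k_TJ*b is geometry-free.
    """
    if b <= 0:
        raise ParameterError("compute_ktj: cleft width b must be positive")
    if P_f < 0 or min(V_wat, w_TJ, RT) <= 0:
        raise ParameterError("compute_ktj: inputs out of range")
    return P_f * V_wat * w_TJ / (RT * b)


def compute_chom(c3: float, j: float, f_aq: float) -> float:
    """Homogeneous cleft concentration, positive root of c^2 - c3*c - j/f_aq = 0.

    c_hom = (c3/2) * (1 + sqrt(1 + 4 j / (f_aq c3^2))) >= c3, with equality
    iff j = 0.  All arguments in CGS (mol/cm^3 etc.).
    """
    if c3 <= 0:
        raise ParameterError("compute_chom: c3 must be positive")
    if j < 0:
        raise ParameterError("compute_chom: j must be non-negative")
    if j == 0:
        return c3
    if f_aq <= 0:
        raise ParameterError(
            "compute_chom: f_aq = 0 with j > 0 leaves no water pathway to dilute "
            "pumped ions; c_hom is undefined (infinite)"
        )
    return 0.5 * c3 * (1.0 + math.sqrt(1.0 + 4.0 * j / (f_aq * c3 * c3)))


def compute_yinh(D: float, b: float, c_hom: float, j: float) -> float:
    """Inhomogeneity length y_inh = sqrt(D * b * c_hom / j) [cm].

    Scales exactly as sqrt(b): narrow clefts reach the homogeneous regime over
    a shorter distance.  Undefined (infinite) for j = 0.
    """
    if j <= 0:
        raise ParameterError(
            "compute_yinh: j = 0 makes y_inh infinite; classify the regime as "
            "'short' upstream instead"
        )
    if min(D, b, c_hom) < 0:
        raise ParameterError("compute_yinh: inputs must be non-negative")
    return math.sqrt(D * b * c_hom / j)


def classify_regime(
    L: float,
    y_inh: float,
    y_inh_short: float,
    r_long: float = 1.0,
    r_short: float = 0.5,
) -> str:
    """Classify the cleft as 'long', 'short' or 'intermediate'.

    'long' if L >= r_long * y_inh (boundary assigned to long); otherwise
    'short' if L <= r_short * y_inh_short, where ``y_inh_short`` is the
    modified scale governing the validity of the parabolic short-cleft
    approximation; otherwise 'intermediate'.  An infinite ``y_inh`` (no ion
    pumping) always classifies as short.
    """
    if math.isinf(y_inh):
        return "short"
    if L >= r_long * y_inh:
        return "long"
    if L <= r_short * y_inh_short:
        return "short"
    return "intermediate"


@dataclass(frozen=True)
class DerivedScales:
    """The scale quantities that organize the model's behavior (CGS units)."""

    f_aq: float      # aquaporin transport coefficient [cm^4 mol^-1 s^-1]
    k_TJ: float      # TJ osmotic conductance [cm^2 s g^-1]
    c_hom: float     # homogeneous concentration [mol/cm^3]
    A: float         # homogeneous velocity slope, v_hom(y) = A*y [s^-1]
    v_hom_L: float   # homogeneous outlet velocity A*L [cm/s]
    y_inh: float     # inhomogeneity length [cm]
    y_inh_short: float  # modified scale for the short-cleft condition [cm]
    regime: str      # 'long' | 'short' | 'intermediate'

    def to_user_dict(self) -> dict:
        return {
            "f_aq_cm4_per_mol_s": self.f_aq,
            "k_TJ_cm2_s_per_g": self.k_TJ,
            "c_hom_mM": self.c_hom / MM_TO_CGS,
            "A_per_s": self.A,
            "v_hom_L_cm_per_s": self.v_hom_L,
            "y_inh_um": self.y_inh / UM_TO_CM,
            "y_inh_short_um": self.y_inh_short / UM_TO_CM,
            "regime": self.regime,
        }


def derived_scales(
    params: Parameters, r_long: float = 1.0, r_short: float = 0.5
) -> DerivedScales:
    """Compute all derived scales for a parameter set.

    The modified short-cleft scale is
    ``y_inh * sqrt(2 * (1 + f_aq * c_hom^2 / (2 j)))``: the parabolic
    approximation stays within the outlet disturbance for lengths well below
    it.  With j = 0 both scales are infinite and the regime is 'short'.
    """
    f_aq = params.f_aq
    k_TJ = params.k_TJ
    c_hom = compute_chom(params.c3, params.j, f_aq)
    if params.j > 0:
        A = 2.0 * params.j / (params.b * c_hom)
        y_inh = compute_yinh(params.D, params.b, c_hom, params.j)
        y_inh_short = y_inh * math.sqrt(
            2.0 * (1.0 + f_aq * c_hom * c_hom / (2.0 * params.j))
        )
    else:  # no pumping: no intrinsic velocity scale, disturbance never relaxes
        A, y_inh, y_inh_short = 0.0, math.inf, math.inf
    regime = classify_regime(params.L, y_inh, y_inh_short, r_long, r_short)
    return DerivedScales(
        f_aq=f_aq,
        k_TJ=k_TJ,
        c_hom=c_hom,
        A=A,
        v_hom_L=A * params.L,
        y_inh=y_inh,
        y_inh_short=y_inh_short,
        regime=regime,
    )
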