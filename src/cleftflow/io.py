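"""Serialization: profile CSVs, scale JSONs and run records."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .params import MM_TO_CGS, UM_TO_CM, Parameters, DerivedScales

__all__ = [
    "write_profile_csv",
    "read_profile_csv",
    "write_run_record",
]

_HEADER = "y_um,c_mM,v_cm_per_s"


def write_profile_csv(profile, path) -> Path:
    """Write a profile as CSV with columns y_um, c_mM, v_cm_per_s.

    Values are printed with 17 significant digits so a round-trip through the
    file reproduces the binary doubles exactly.
    """
    path = Path(path)
    data = np.column_stack(
        [profile.y / UM_TO_CM, profile.c / MM_TO_CGS, profile.v]
    )
    np.savetxt(path, data, delimiter=",", fmt="%.17g", header=_HEADER, comments="")
    return path


def read_profile_csv(path):
    """Read a profile CSV back into CGS arrays (y, c, v)."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 3:
        raise ValueError(f"expected 3 columns ({_HEADER}), got {data.shape[1]}")
    return data[:, 0] * UM_TO_CM, data[:, 1] * MM_TO_CGS, data[:, 2]


def write_run_record(
    path,
    params: Parameters,
    scales: DerivedScales,
    command: str,
    outputs: list[str],
) -> Path:
    """Emit the JSON run record that accompanies every CLI invocation."""
    from . import __version__

    record = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "package": "cleftflow",
        "version": __version__,
        "python": platform.python_version(),
        "command": command,
        "parameters_cgs": params.to_cgs_dict(),
        "parameters_user": params.to_user_units(),
        "derived_scales": scales.to_user_dict(),
        "outputs": outputs,
    }
    path = Path(path)
    path.write_text(json.dumps(record, indent=2) + "\n")
    return path
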