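"""Delimited-text and TOML I/O for the pipeline's artefacts.

Concentration data travel as tidy CSV with columns ``time_h, conc_ug_ml,
tissue, species, conjugate, dose_mg_kg`` (header mandatory, decimal point,
concentrations always in µg/mL).  Release curves use ``time_h,
fraction_released`` (or ``percent_released``) plus ``conjugate``.  Parameter
sets are flat TOML files keyed by the conventional symbols.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .params import DispositionParams, ReleasedDrugPK
from .release import ReleaseCurve
from .series import ConcentrationSeries, concat_frames

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "read_release_csv",
    "write_release_csv",
    "read_params_toml",
    "write_params_toml",
]

SERIES_COLUMNS = ("time_h", "conc_ug_ml", "tissue", "species", "conjugate", "dose_mg_kg")

_PARAM_KEYS = ("k_res", "k_ext", "k_tu", "CL", "V_c",
               "k12", "k21", "k13", "k31", "V_pl", "V_tu", "body_mass")


# shortest-round-trip float formatting so read-back reproduces values exactly
_FLOAT_FMT = "%.17g"


def write_series_csv(series: Iterable[ConcentrationSeries], path) -> None:
    concat_frames(series).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_series_csv(path) -> List[ConcentrationSeries]:
    """Read a tidy concentration CSV back into one series per profile."""
    frame = pd.read_csv(path, float_precision="round_trip")
    required = ("time_h", "conc_ug_ml", "tissue", "species")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InvalidParameterError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    if "conjugate" not in frame.columns:
        frame["conjugate"] = ""
    out = []
    for _, group in frame.groupby(["conjugate", "tissue", "species"], sort=True):
        out.append(ConcentrationSeries.from_frame(group.reset_index(drop=True)))
    return out


def write_release_csv(curves: Iterable[ReleaseCurve], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_h": c.times,
                "fraction_released": c.fraction_released,
                "conjugate": c.conjugate_label,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_release_csv(path) -> List[ReleaseCurve]:
    """Read cumulative release curves; percent columns are rescaled to fractions.

    Accepts either a ``fraction_released`` or a ``percent_released`` column;
    a fraction column whose values exceed 1.5 is heuristically treated as
    percent and divided by 100.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if "time_h" not in frame.columns:
        raise InvalidParameterError(f"{path}: missing required column time_h")
    if "fraction_released" in frame.columns:
        values = frame["fraction_released"].to_numpy(dtype=float)
        if np.nanmax(values) > 1.5:
            values = values / 100.0
    elif "percent_released" in frame.columns:
        values = frame["percent_released"].to_numpy(dtype=float) / 100.0
    else:
        raise InvalidParameterError(
            f"{path}: need a fraction_released or percent_released column"
        )
    frame = frame.assign(_fraction=values)
    if "conjugate" not in frame.columns:
        frame["conjugate"] = ""
    curves = []
    for label, group in frame.groupby("conjugate", sort=True):
        group = group.sort_values("time_h")
        curves.append(
            ReleaseCurve(
                times=group["time_h"].to_numpy(dtype=float),
                fraction_released=group["_fraction"].to_numpy(dtype=float),
                conjugate_label=str(label),
            )
        )
    return curves


def read_params_toml(path) -> Tuple[DispositionParams, ReleasedDrugPK, Dict[str, float]]:
    """Read a flat TOML parameter file.

    Returns the disposition and released-drug parameter sets plus an optional
    ``half_lives`` mapping (conjugate label -> release half-life in h) if the
    file carries one.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    missing = [k for k in _PARAM_KEYS if k != "body_mass" and k not in raw]
    if missing:
        raise InvalidParameterError(f"{path}: missing parameter key(s) {', '.join(missing)}")
    disp = DispositionParams(
        k_res=float(raw["k_res"]),
        k_ext=float(raw["k_ext"]),
        V_pl=float(raw["V_pl"]),
        V_tu=float(raw["V_tu"]),
        body_mass=float(raw.get("body_mass", 0.025)),
    )
    rel = ReleasedDrugPK(
        k_tu=float(raw["k_tu"]),
        CL=float(raw["CL"]),
        V_c=float(raw["V_c"]),
        k12=float(raw["k12"]),
        k21=float(raw["k21"]),
        k13=float(raw["k13"]),
        k31=float(raw["k31"]),
    )
    half_lives = {str(k): float(v) for k, v in raw.get("half_lives", {}).items()}
    return disp, rel, half_lives


def write_params_toml(
    disp: DispositionParams,
    rel: ReleasedDrugPK,
    path,
    half_lives: Optional[Dict[str, float]] = None,
) -> None:
    values = {
        "k_res": disp.k_res, "k_ext": disp.k_ext, "k_tu": rel.k_tu,
        "CL": rel.CL, "V_c": rel.V_c,
        "k12": rel.k12, "k21": rel.k21, "k13": rel.k13, "k31": rel.k31,
        "V_pl": disp.V_pl, "V_tu": disp.V_tu, "body_mass": disp.body_mass,
    }
    lines = [f"{key} = {value!r}" for key, value in values.items()]
    if half_lives:
        lines.append("")
        lines.append("[half_lives]")
        lines.extend(f'"{label}" = {t_half!r}' for label, t_half in half_lives.items())
    Path(path).write_text("\n".join(lines) + "\n")
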