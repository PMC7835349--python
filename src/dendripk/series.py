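"""Concentration-time series container and its tidy-frame round trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = ["ConcentrationSeries", "TISSUES", "SPECIES"]

TISSUES = ("plasma", "tumour")
SPECIES = ("conjugated", "released", "total")


@dataclass(frozen=True)
class ConcentrationSeries:
    """A tissue/species concentration profile in µg/mL versus time in hours.

    Model-evaluated series have strictly increasing times; observed datasets
    from terminal sampling may carry replicate animals at the same timepoint,
    so only non-decreasing order is enforced.
    """

    times: np.ndarray
    values: np.ndarray
    tissue: str
    species: str
    conjugate_label: str = ""
    dose_mg_kg: float = float("nan")

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise InvalidParameterError("times and values must be 1-D arrays of equal length")
        if t.size and (not np.all(np.isfinite(t)) or np.any(t < 0)):
            raise InvalidParameterError("times must be finite and non-negative")
        if t.size and np.any(np.diff(t) < 0):
            raise InvalidParameterError("times must be non-decreasing")
        if v.size and (not np.all(np.isfinite(v)) or np.any(v < 0)):
            raise InvalidParameterError("concentrations must be finite and non-negative")
        if self.tissue not in TISSUES:
            raise InvalidParameterError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.species not in SPECIES:
            raise InvalidParameterError(f"species must be one of {SPECIES}, got {self.species!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "conc_ug_ml": self.values,
                "tissue": self.tissue,
                "species": self.species,
                "conjugate": self.conjugate_label,
                "dose_mg_kg": self.dose_mg_kg,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConcentrationSeries":
        """Build a series from a tidy frame holding exactly one profile."""
        for col in ("time_h", "conc_ug_ml", "tissue", "species"):
            if col not in frame.columns:
                raise InvalidParameterError(f"missing required column {col!r}")
        tissue = frame["tissue"].unique()
        species = frame["species"].unique()
        if len(tissue) != 1 or len(species) != 1:
            raise InvalidParameterError("frame holds more than one tissue/species profile")
        conj = str(frame["conjugate"].iloc[0]) if "conjugate" in frame.columns else ""
        dose = float(frame["dose_mg_kg"].iloc[0]) if "dose_mg_kg" in frame.columns else float("nan")
        order = np.argsort(frame["time_h"].to_numpy(), kind="stable")
        return cls(
            times=frame["time_h"].to_numpy(dtype=float)[order],
            values=frame["conc_ug_ml"].to_numpy(dtype=float)[order],
            tissue=str(tissue[0]),
            species=str(species[0]),
            conjugate_label=conj,
            dose_mg_kg=dose,
        )


def concat_frames(series: Iterable[ConcentrationSeries]) -> pd.DataFrame:
    """Stack several series into one tidy frame (helper for CSV export)."""
    frames = [s.to_frame() for s in series]
    if not frames:
        return pd.DataFrame(
            columns=["time_h", "conc_ug_ml", "tissue", "species", "conjugate", "dose_mg_kg"]
        )
    return pd.concat(frames, ignore_index=True)
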