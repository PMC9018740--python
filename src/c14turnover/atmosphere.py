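"""Atmospheric Δ¹⁴C records.

The atmospheric record is the clock of retrospective birth dating: the
above-ground nuclear tests of the 1950s/60s nearly doubled atmospheric
¹⁴C (the "bomb pulse", peaking around 1963), and genomic DNA of a cell
carries the atmospheric Δ¹⁴C of the year its DNA was synthesised.  This
module holds the record as a piecewise-linear interpolant over decimal
calendar years and applies the food-chain lag: carbon fixed by plants
takes about a year to reach human DNA, so every atmospheric lookup used
by the forward models is shifted back by ``lag`` years.

Values are decay-corrected Δ¹⁴C in per mil (‰).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AtmosphericRecord", "CoverageError", "read_record_csv", "write_record_csv"]


class CoverageError(ValueError):
    """A lookup outside the calendar span covered by the record."""


@dataclass(frozen=True)
class AtmosphericRecord:
    """Piecewise-linear atmospheric Δ¹⁴C curve with a food-chain lag.

    Parameters
    ----------
    years
        Strictly increasing decimal calendar years, length >= 2.
    values
        Decay-corrected Δ¹⁴C in ‰ at each knot.
    lag
        Food-chain delay in years (default 1.0).  ``lagged_lookup(y)``
        returns the atmospheric value at ``y - lag``.
    """

    years: np.ndarray
    values: np.ndarray
    lag: float = 1.0

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if years.ndim != 1 or years.size < 2:
            raise ValueError("record needs at least two (year, value) knots")
        if values.shape != years.shape:
            raise ValueError("years and values must have equal length")
        if not np.all(np.diff(years) > 0):
            raise ValueError("years must be strictly increasing")
        if not (np.isfinite(years).all() and np.isfinite(values).all()):
            raise ValueError("years and values must be finite")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    @property
    def start(self) -> float:
        return float(self.years[0])

    @property
    def end(self) -> float:
        return float(self.years[-1])

    def _check_range(self, year: np.ndarray) -> None:
        if np.any(year < self.years[0]) or np.any(year > self.years[-1]):
            raise CoverageError(
                f"year outside atmospheric record "
                f"[{self.years[0]:g}, {self.years[-1]:g}]"
            )

    def lookup(self, year):
        """Δ¹⁴C (‰) at a decimal calendar year; exact at knots, linear between."""
        y = np.asarray(year, dtype=float)
        self._check_range(y)
        out = np.interp(y, self.years, self.values)
        return float(out) if np.isscalar(year) or y.ndim == 0 else out

    def lagged_lookup(self, year):
        """Δ¹⁴C (‰) at ``year - lag``: the value entering newly made DNA."""
        y = np.asarray(year, dtype=float) - self.lag
        self._check_range(y)
        out = np.interp(y, self.years, self.values)
        return float(out) if np.isscalar(year) or y.ndim == 0 else out

    def covers(self, lo: float, hi: float) -> bool:
        return self.years[0] <= lo and hi <= self.years[-1]


def read_record_csv(path) -> AtmosphericRecord:
    """Read a two-column ``year,delta14c_permil`` CSV (header required)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"year", "delta14c_permil"} - set(df.columns)
    if missing:
        raise ValueError(f"atmosphere CSV missing columns: {sorted(missing)}")
    return AtmosphericRecord(
        years=df["year"].to_numpy(float), values=df["delta14c_permil"].to_numpy(float)
    )


def write_record_csv(record: AtmosphericRecord, path) -> None:
    """Write the record as ``year,delta14c_permil``; round-trips bit-exactly."""
    pd.DataFrame(
        {"year": record.years, "delta14c_permil": record.values}
    ).to_csv(path, index=False, float_format="%.17g")
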