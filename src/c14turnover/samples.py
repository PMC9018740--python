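"""Subject-level Δ¹⁴C measurements.

One :class:`SubjectSample` is one accelerator-mass-spectrometry (AMS)
measurement of decay-corrected genomic Δ¹⁴C for one sorted cell
population (neuronal or non-neuronal) of one subject, together with the
subject's birth and sample-collection dates as decimal calendar years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "SubjectSample",
    "POPULATIONS",
    "HEMISPHERES",
    "read_samples_csv",
    "write_samples_csv",
    "validate_table",
    "samples_to_frame",
]

POPULATIONS = ("neuronal", "non-neuronal")
HEMISPHERES = ("left", "right")

_COLUMNS = [
    "subject_id",
    "birth_year",
    "collection_year",
    "population",
    "hemisphere",
    "delta14c_permil",
    "meas_sd_permil",
]


@dataclass(frozen=True)
class SubjectSample:
    """One genomic Δ¹⁴C measurement.

    ``meas_sd_permil`` is the AMS measurement uncertainty; it is carried
    for reporting but the likelihood uses a single common noise SD.
    """

    subject_id: str
    birth_year: float
    collection_year: float
    population: str
    delta14c_permil: float
    meas_sd_permil: float = 0.0
    hemisphere: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.collection_year > self.birth_year:
            raise ValueError(
                f"{self.subject_id}: collection_year must exceed birth_year"
            )
        if self.population not in POPULATIONS:
            raise ValueError(
                f"{self.subject_id}: population must be one of {POPULATIONS}"
            )
        if self.hemisphere is not None and self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"{self.subject_id}: hemisphere must be one of {HEMISPHERES} or empty"
            )
        if self.meas_sd_permil < 0:
            raise ValueError(f"{self.subject_id}: meas_sd_permil must be >= 0")

    @property
    def age_at_collection(self) -> float:
        """Subject age in years at sample collection."""
        return self.collection_year - self.birth_year


def samples_to_frame(samples: Iterable[SubjectSample]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "birth_year": s.birth_year,
            "collection_year": s.collection_year,
            "population": s.population,
            "hemisphere": s.hemisphere or "",
            "delta14c_permil": s.delta14c_permil,
            "meas_sd_permil": s.meas_sd_permil,
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_samples_csv(samples: Iterable[SubjectSample], path) -> None:
    samples_to_frame(samples).to_csv(path, index=False, float_format="%.17g")


def validate_table(path) -> tuple[list[SubjectSample], list[str]]:
    """Parse a measurement table, returning samples and a complete error list.

    Either every row parses (second element empty) or no samples are
    returned and every row-level violation is named — rows are never
    silently dropped.
    """
    df = pd.read_csv(
        path, dtype={"subject_id": str, "hemisphere": str}, float_precision="round_trip"
    )
    errors: list[str] = []
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        return [], [f"missing columns: {missing}"]

    samples: list[SubjectSample] = []
    for idx, row in df.iterrows():
        hemi = row["hemisphere"]
        hemi = None if (pd.isna(hemi) or str(hemi).strip() == "") else str(hemi).strip()
        try:
            samples.append(
                SubjectSample(
                    subject_id=str(row["subject_id"]),
                    birth_year=float(row["birth_year"]),
                    collection_year=float(row["collection_year"]),
                    population=str(row["population"]),
                    delta14c_permil=float(row["delta14c_permil"]),
                    meas_sd_permil=float(row["meas_sd_permil"]),
                    hemisphere=hemi,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {idx}: {exc}")

    keys = [(s.subject_id, s.population, s.hemisphere) for s in samples]
    dupes = {k for k in keys if keys.count(k) > 1}
    for k in sorted(dupes, key=str):
        errors.append(f"duplicate (subject, population, hemisphere) key: {k}")

    if errors:
        return [], errors
    return samples, []


def read_samples_csv(path) -> list[SubjectSample]:
    """Parse a measurement table or raise with the full list of violations."""
    samples, errors = validate_table(path)
    if errors:
        raise ValueError("invalid measurement table:\n  " + "\n  ".join(errors))
    return samples
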