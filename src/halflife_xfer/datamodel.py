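"""Core data types, tabular I/O, and the feature transform.

A dataset is one row per protein. "Common" proteins have a measured
half-life in both the tissue and the cell culture; "uncommon" proteins
were quantified only in cell culture and are the ones whose tissue
half-life the downstream model predicts.

Canonical feature order (used everywhere a 7-vector appears)::

    cell_halflife, length (PL), abundance (PA), disorder_count (ID),
    mrna_level (MR), transcription_rate (TR), translation_rate (TL)

By default the auxiliary properties are natural-log transformed and
rounded to 4 decimals, while the two half-lives stay in raw hours so
that regression intercepts remain interpretable as hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical feature names, in the order used by every weight vector
FEATURE_NAMES: tuple[str, ...] = (
    "cell_halflife",
    "length",
    "abundance",
    "disorder_count",
    "mrna_level",
    "transcription_rate",
    "translation_rate",
)

#: canonical file columns (TSV/CSV header names)
CANONICAL_COLUMNS: tuple[str, ...] = (
    "protein_id",
    "cell_halflife_h",
    "tissue_halflife_h",
    "length_aa",
    "abundance",
    "disorder_count",
    "mrna_level",
    "transcription_rate",
    "translation_rate",
)

_FIELD_FOR_COLUMN = {
    "cell_halflife_h": "cell_halflife",
    "tissue_halflife_h": "tissue_halflife",
    "length_aa": "length",
    "abundance": "abundance",
    "disorder_count": "disorder_count",
    "mrna_level": "mrna_level",
    "transcription_rate": "transcription_rate",
    "translation_rate": "translation_rate",
}


class FormatError(ValueError):
    """A structural problem with an input table (e.g. missing column)."""


class DomainError(ValueError):
    """A value outside the domain an operation requires."""


class InsufficientDataError(ValueError):
    """Too few records/points for the requested fit."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein's identifiers, half-lives (hours) and cellular properties."""

    protein_id: str
    cell_halflife: float
    tissue_halflife: float | None
    length: int
    abundance: float
    disorder_count: int
    mrna_level: float
    transcription_rate: float
    translation_rate: float

    @property
    def is_common(self) -> bool:
        """True when the tissue half-life was measured."""
        return self.tissue_halflife is not None

    def validate(self) -> list[str]:
        problems = []
        for name in ("cell_halflife", "length", "abundance", "mrna_level",
                     "transcription_rate", "translation_rate"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v <= 0:
                problems.append(f"{name} must be strictly positive, got {v!r}")
        if self.tissue_halflife is not None and self.tissue_halflife <= 0:
            problems.append(
                f"tissue_halflife must be strictly positive when present, "
                f"got {self.tissue_halflife!r}")
        if self.disorder_count < 0:
            problems.append(
                f"disorder_count must be nonnegative, got {self.disorder_count!r}")
        return problems


@dataclass(frozen=True)
class TransformConfig:
    """Which features to log-transform and how to round.

    log_features: features replaced by log_e(value); disorder_count uses
    log_e(count + 1) so a count of zero stays representable.
    round_decimals: decimals kept after the transform (raw values are
    never rounded).
    log_halflives: also log the two half-lives (off by default; keeps
    intercepts in hours).
    """

    log_features: tuple[str, ...] = (
        "length", "abundance", "disorder_count",
        "mrna_level", "transcription_rate", "translation_rate",
    )
    round_decimals: int = 4
    log_halflives: bool = False

    def effective_log_features(self) -> tuple[str, ...]:
        if self.log_halflives:
            return ("cell_halflife",) + tuple(
                f for f in self.log_features if f != "cell_halflife")
        return tuple(f for f in self.log_features if f != "cell_halflife")


@dataclass(frozen=True)
class FeatureVector:
    """Transformed 7-vector in canonical feature order."""

    values: tuple[float, ...]
    transform_flags: tuple[bool, ...]
    rounding: int

    def __post_init__(self):
        if len(self.values) != len(FEATURE_NAMES):
            raise DomainError(
                f"feature vector must have {len(FEATURE_NAMES)} entries, "
                f"got {len(self.values)}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class Dataset:
    """A collection of protein records with a provenance label."""

    records: list[ProteinRecord]
    provenance: str = ""
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def common(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.is_common]

    @property
    def uncommon(self) -> list[ProteinRecord]:
        return [r for r in self.records if not r.is_common]

    def subset(self, ids: set[str]) -> "Dataset":
        return Dataset([r for r in self.records if r.protein_id in ids],
                       provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "protein_id": r.protein_id,
                "cell_halflife_h": r.cell_halflife,
                "tissue_halflife_h": (np.nan if r.tissue_halflife is None
                                      else r.tissue_halflife),
                "length_aa": r.length,
                "abundance": r.abundance,
                "disorder_count": r.disorder_count,
                "mrna_level": r.mrna_level,
                "transcription_rate": r.transcription_rate,
                "translation_rate": r.translation_rate,
            })
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def transform_features(record: ProteinRecord,
                       config: TransformConfig = TransformConfig()) -> FeatureVector:
    """Map a record to its transformed feature 7-vector.

    Auxiliary properties are replaced by log_e(value) (disorder_count by
    log_e(count+1)) and rounded; half-lives stay in raw hours unless
    ``config.log_halflives``.
    """
    log_set = set(config.effective_log_features())
    raw = {
        "cell_halflife": record.cell_halflife,
        "length": float(record.length),
        "abundance": record.abundance,
        "disorder_count": float(record.disorder_count),
        "mrna_level": record.mrna_level,
        "transcription_rate": record.transcription_rate,
        "translation_rate": record.translation_rate,
    }
    values, flags = [], []
    for name in FEATURE_NAMES:
        v = raw[name]
        if name in log_set:
            arg = v + 1.0 if name == "disorder_count" else v
            if arg <= 0:
                raise DomainError(
                    f"cannot log-transform non-positive {name}={v!r} "
                    f"for protein {record.protein_id}")
            v = round(math.log(arg), config.round_decimals)
            flags.append(True)
        else:
            flags.append(False)
        values.append(float(v))
    return FeatureVector(tuple(values), tuple(flags), config.round_decimals)


def feature_matrix(records: list[ProteinRecord],
                   config: TransformConfig = TransformConfig()) -> np.ndarray:
    """Stack transformed feature vectors into an (n, 7) array."""
    return np.array([transform_features(r, config).values for r in records])


def _parse_row(idx: int, row: pd.Series) -> ProteinRecord | tuple[int, str]:
    try:
        tissue = row["tissue_halflife_h"]
        tissue = None if pd.isna(tissue) else float(tissue)
        rec = ProteinRecord(
            protein_id=str(row["protein_id"]),
            cell_halflife=float(row["cell_halflife_h"]),
            tissue_halflife=tissue,
            length=int(row["length_aa"]),
            abundance=float(row["abundance"]),
            disorder_count=int(row["disorder_count"]),
            mrna_level=float(row["mrna_level"]),
            transcription_rate=float(row["transcription_rate"]),
            translation_rate=float(row["translation_rate"]),
        )
    except (TypeError, ValueError) as exc:
        return (idx, f"unparseable value: {exc}")
    problems = rec.validate()
    if problems:
        return (idx, "; ".join(problems))
    return rec


def read_dataset(path, fmt: str = "tsv",
                 column_map: dict[str, str] | None = None) -> Dataset:
    """Read a canonical TSV/CSV protein table.

    Rows violating the record invariants are rejected (reported in
    ``Dataset.rejected`` as (row index, reason)); a missing
    tissue_halflife_h value marks the record uncommon, not invalid.
    ``column_map`` maps file column names to canonical ones.
    """
    sep = {"tsv": "\t", "csv": ","}.get(fmt)
    if sep is None:
        raise FormatError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'")
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    ds = Dataset([], provenance=str(path))
    seen: set[str] = set()
    for idx, row in df.iterrows():
        parsed = _parse_row(int(idx), row)
        if isinstance(parsed, tuple):
            ds.rejected.append(parsed)
            continue
        if parsed.protein_id in seen:
            ds.rejected.append((int(idx),
                                f"duplicate protein_id {parsed.protein_id!r}"))
            continue
        seen.add(parsed.protein_id)
        ds.records.append(parsed)
    return ds


def write_dataset(dataset: Dataset, path, fmt: str = "tsv"):
    """Write the canonical table; uncommon records get an empty tissue field."""
    sep = {"tsv": "\t", "csv": ","}.get(fmt)
    if sep is None:
        raise FormatError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'")
    df = dataset.to_frame()
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")
    return path


__all__ = [
    "FEATURE_NAMES", "CANONICAL_COLUMNS", "ProteinRecord", "FeatureVector",
    "Dataset", "TransformConfig", "transform_features", "feature_matrix",
    "read_dataset", "write_dataset", "FormatError", "DomainError",
    "InsufficientDataError", "replace",
]
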