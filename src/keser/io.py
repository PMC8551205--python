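"""Ingestion and on-disk formats for longitudinal coded-event data.

The raw input is a table of (patient, code, date) records — one row per time a
code (diagnosis, medication, procedure, lab) was recorded for a patient.  Codes
carry a namespace prefix ("PheCode:714.1", "RXNORM:6851", "CCS:213",
"LAB:11039-5") from which the code type is derived; downstream screening and
evaluation are stratified by these types.

Dates are normalized to integer day offsets from the earliest date in the
file, so all window arithmetic is in whole days and calendar/timezone
ambiguity is removed.  Codes occurring multiple times for the same patient on
the same day are counted once per day.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "Vocabulary",
    "EventTable",
    "code_type",
    "read_events",
    "apply_rollup",
    "read_rollup",
    "filter_phecode_levels",
    "frequency_filter",
    "split_patients",
]

#: canonical code-type tags, derived from the namespace prefix of a code
_PREFIX_TYPES = {
    "phecode": "PheCode",
    "rxnorm": "RXNORM",
    "ccs": "CCS",
    "lab": "LAB",
    "loinc": "LAB",
}


class SchemaError(ValueError):
    """An input file does not have the required columns."""


def code_type(code: str) -> str:
    """Return the code-type tag (PheCode | RXNORM | CCS | LAB | other).

    The tag is derived from the namespace prefix before the first ":".
    Codes without a recognized prefix are tagged "other".
    """
    prefix, _, rest = code.partition(":")
    if not rest:
        return "other"
    return _PREFIX_TYPES.get(prefix.lower(), "other")


@dataclass(frozen=True)
class Vocabulary:
    """An ordered, unique set of code strings with derived type tags.

    The ordering is stable and is persisted alongside every matrix artifact
    that indexes rows/columns by code.
    """

    codes: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("vocabulary codes must be unique")
        object.__setattr__(self, "codes", tuple(self.codes))
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.codes)})

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def __iter__(self):
        return iter(self.codes)

    def index(self, code: str) -> int:
        return self._index[code]

    def type_of(self, code: str) -> str:
        return code_type(code)

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(code_type(c) for c in self.codes)

    def of_type(self, tag: str) -> tuple[str, ...]:
        return tuple(c for c in self.codes if code_type(c) == tag)

    def subset(self, codes: Iterable[str]) -> "Vocabulary":
        """Restrict to *codes*, preserving this vocabulary's order."""
        keep = set(codes)
        return Vocabulary(tuple(c for c in self.codes if c in keep))

    def content_hash(self) -> str:
        h = hashlib.blake2b(digest_size=8)
        for c in self.codes:
            h.update(c.encode())
            h.update(b"\n")
        return h.hexdigest()

    def save(self, path) -> None:
        Path(path).write_text("\n".join(self.codes) + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        return cls(tuple(ln for ln in lines if ln))


class EventTable:
    """Deduplicated (patient, code, day) records.

    Same-day repeats of a code for a patient collapse to one record at
    construction unless ``deduplicate=False`` is requested (useful when
    frequency control should count raw rows rather than patient-day records).
    """

    COLUMNS = ("patient", "code", "day")

    def __init__(self, df: pd.DataFrame, deduplicate: bool = True):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"event table missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["patient"] = df["patient"].astype(str)
        df["code"] = df["code"].astype(str)
        df["day"] = df["day"].astype(np.int64)
        if deduplicate:
            df = df.drop_duplicates()
        df = df.sort_values(list(self.COLUMNS), kind="mergesort").reset_index(drop=True)
        self.df = df
        self.deduplicated = deduplicate

    @classmethod
    def from_records(cls, records: Iterable[tuple], deduplicate: bool = True) -> "EventTable":
        df = pd.DataFrame(list(records), columns=list(cls.COLUMNS))
        return cls(df, deduplicate=deduplicate)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def patients(self) -> tuple[str, ...]:
        return tuple(self.df["patient"].unique())

    def vocabulary(self) -> Vocabulary:
        return Vocabulary(tuple(sorted(self.df["code"].unique())))

    def records(self) -> list[tuple[str, str, int]]:
        return list(self.df.itertuples(index=False, name=None))

    def restrict(self, vocab: Vocabulary) -> "EventTable":
        keep = self.df["code"].isin(set(vocab.codes))
        return EventTable(self.df.loc[keep], deduplicate=self.deduplicated)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".parquet":
            self.df.rename(columns={"day": "date"}).to_parquet(path, index=False)
        else:
            sep = "," if path.suffix == ".csv" else "\t"
            self.df.rename(columns={"day": "date"}).to_csv(path, sep=sep, index=False)


def _normalize_dates(raw: pd.Series, path) -> pd.Series:
    """Convert a date column to integer day offsets from the earliest date."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return numeric.astype(np.int64)
    parsed = pd.to_datetime(raw, errors="coerce", format="mixed")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        # +2: one for the header line, one for 0- vs 1-based numbering
        line = int(bad.idxmax()) + 2
        raise ValueError(
            f"{path}: unparseable date {raw[bad.idxmax()]!r} at line {line}"
        )
    if parsed.isna().any():
        line = int(parsed.isna().idxmax()) + 2
        raise ValueError(f"{path}: missing date at line {line}")
    days = (parsed - parsed.min()).dt.days
    return days.astype(np.int64)


def read_events(path, fmt: str | None = None, deduplicate: bool = True) -> EventTable:
    """Read a longitudinal event file into an :class:`EventTable`.

    Supported formats: delimited text (TSV/CSV, header ``patient,code,date``)
    and Parquet with the same schema.  Dates may be ISO dates or already
    integer day indices; either way they are normalized to integer day
    offsets from the earliest date in the file.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".parquet": "parquet", ".csv": "csv"}.get(path.suffix, "tsv")
    if fmt == "parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", dtype=str)
    for col in ("patient", "code", "date"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    df = df.reset_index(drop=True)
    day = _normalize_dates(df["date"], path)
    out = pd.DataFrame({"patient": df["patient"], "code": df["code"], "day": day})
    return EventTable(out, deduplicate=deduplicate)


def read_rollup(path) -> dict[str, str]:
    """Read a two-column TSV mapping raw code -> grouped code."""
    df = pd.read_csv(path, sep="\t", header=None, names=["raw", "grouped"], dtype=str)
    dup = df["raw"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: raw code {df['raw'][dup.idxmax()]!r} maps to more than one grouped code")
    return dict(zip(df["raw"], df["grouped"]))


def apply_rollup(events: EventTable, mapping: Mapping[str, str], keep_unmapped: bool = True) -> EventTable:
    """Replace raw codes by their grouped concept (e.g. ICD -> PheCode).

    Rows sharing (patient, grouped code, day) collapse to one record.
    Unmapped codes are passed through (``keep_unmapped=True``) or dropped.
    """
    df = events.df.copy()
    mapped = df["code"].map(mapping)
    if keep_unmapped:
        df["code"] = mapped.fillna(df["code"])
    else:
        df = df.loc[mapped.notna()].copy()
        df["code"] = mapped.loc[df.index]
    return EventTable(df, deduplicate=True)


def _phecode_level(code: str) -> int | None:
    """Number of decimal digits of a PheCode, or None if malformed."""
    body = code.partition(":")[2]
    head, dot, frac = body.partition(".")
    if not head.isdigit() or (dot and not frac.isdigit()):
        return None
    return len(frac)


_LEVEL_DIGITS = {"integer": 0, "one-digit": 1, "two-digit": 2}


def filter_phecode_levels(vocab: Vocabulary, level: str = "one-digit") -> Vocabulary:
    """Retain a single PheCode granularity level per integer family.

    PheCodes form a dotted-decimal hierarchy (714, 714.1, 714.12).  For
    families in which the requested level is present, only codes at that
    level are kept; families without any code at the requested level, and
    all non-PheCode codes, pass through unchanged.  Collapsing to one level
    reduces collinearity among regression candidates.
    """
    if level not in _LEVEL_DIGITS:
        raise ValueError(f"unknown PheCode level {level!r}")
    want = _LEVEL_DIGITS[level]

    families: dict[str, set[int]] = {}
    for c in vocab.codes:
        if code_type(c) != "PheCode":
            continue
        lv = _phecode_level(c)
        if lv is None:
            warnings.warn(f"malformed PheCode {c!r}; retained as-is")
            continue
        fam = c.partition(":")[2].partition(".")[0]
        families.setdefault(fam, set()).add(lv)

    keep = []
    for c in vocab.codes:
        if code_type(c) != "PheCode":
            keep.append(c)
            continue
        lv = _phecode_level(c)
        if lv is None:
            keep.append(c)
            continue
        fam = c.partition(":")[2].partition(".")[0]
        if want in families[fam]:
            if lv == want:
                keep.append(c)
        else:
            keep.append(c)
    return Vocabulary(tuple(keep))


def frequency_filter(events: EventTable, min_count: int, strict: bool = True) -> Vocabulary:
    """Vocabulary of codes whose record count passes a frequency threshold.

    Counts are over the table's records — deduplicated patient-day records
    for a table ingested with the default settings.  ``strict=True`` keeps
    codes with count > ``min_count`` (mirroring thresholds quoted as
    ">1000"); ``strict=False`` keeps count >= ``min_count``.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = events.df["code"].value_counts()
    passed = counts[counts > min_count] if strict else counts[counts >= min_count]
    return Vocabulary(tuple(sorted(passed.index)))


def _patient_hash(patient: str, seed: int) -> int:
    key = hashlib.blake2b(
        patient.encode(), key=int(seed).to_bytes(8, "little", signed=False), digest_size=8
    )
    return int.from_bytes(key.digest(), "little")


def split_patients(events: EventTable, fraction: float, seed: int) -> tuple[EventTable, EventTable]:
    """Split into two tables with disjoint, exhaustive patient sets.

    The first table receives ``round(fraction * n_patients)`` patients.
    Assignment ranks patients by a keyed hash of their id, so the split is a
    deterministic function of (patient set, fraction, seed) and independent
    of input row order.  The canonical use is building training and
    validation co-occurrence matrices from non-overlapping patients.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    patients = sorted(set(events.df["patient"]))
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    ranked = sorted(patients, key=lambda p: (_patient_hash(p, seed), p))
    n_first = int(np.floor(fraction * len(patients) + 0.5))
    n_first = min(max(n_first, 1), len(patients) - 1)
    first = set(ranked[:n_first])
    in_first = events.df["patient"].isin(first)
    return (
        EventTable(events.df.loc[in_first], deduplicate=events.deduplicated),
        EventTable(events.df.loc[~in_first], deduplicate=events.deduplicated),
    )
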