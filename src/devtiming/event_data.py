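"""Loading, validation, coverage filtering and summaries of event-timing tables.

The central input is a sparse long-format table of neurodevelopmental
events: one row per (species, event) pair whose timing — the
post-conceptional day (PC day) on which the event occurs — is known from
the literature. Each species carries a primate / non-primate flag and each
event a coarse anatomical class (cortical, limbic or other); both are
needed downstream to build interaction terms and to decompose prediction
errors by group.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EVENT_CLASSES = ("cortical", "limbic", "other")

REQUIRED_COLUMNS = ("species", "event", "pc_day", "is_primate", "event_class")

_TRUE_STRINGS = {"1", "true", "t", "yes"}
_FALSE_STRINGS = {"0", "false", "f", "no"}


class SchemaError(ValueError):
    """The input table is missing required columns or uses unknown labels."""


@dataclass(frozen=True)
class SpeciesMeta:
    species: str
    is_primate: bool


@dataclass(frozen=True)
class EventMeta:
    event: str
    event_class: str  # one of EVENT_CLASSES


@dataclass(frozen=True)
class DistributionSummary:
    """Moment summary of a vector of PC days (raw or log scale)."""

    skewness: float
    kurtosis: float  # excess kurtosis (normal -> 0)
    n: int
    min: float
    max: float


@dataclass
class EventTimingTable:
    """Validated sparse species x event timing table.

    ``data`` has one row per known observation with columns
    ``species, event, pc_day, is_primate, event_class``. Metadata
    (primate flag, event class) is constant within a species / event.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["species"] = df["species"].astype(str).str.strip()
        df["event"] = df["event"].astype(str).str.strip()
        df["is_primate"] = _coerce_bool(df["is_primate"])
        df["event_class"] = df["event_class"].astype(str).str.strip().str.lower()

        bad_class = sorted(set(df["event_class"]) - set(EVENT_CLASSES))
        if bad_class:
            raise SchemaError(
                f"unknown event_class values {bad_class}; expected one of {EVENT_CLASSES}"
            )

        pc = pd.to_numeric(df["pc_day"], errors="coerce")
        bad = df.index[pc.isna() | (pc <= 0)]
        if len(bad):
            row = bad[0]
            raise ValueError(
                f"pc_day must be a positive number; offending row index {row}: "
                f"{df.loc[row].to_dict()}"
            )
        df["pc_day"] = pc.astype(float)

        dup = df.duplicated(subset=["species", "event"])
        if dup.any():
            pairs = df.loc[dup, ["species", "event"]].to_records(index=False).tolist()
            raise ValueError(f"duplicate (species, event) observations: {pairs}")

        for key, col in (("species", "is_primate"), ("event", "event_class")):
            nuniq = df.groupby(key)[col].nunique()
            inconsistent = nuniq.index[nuniq > 1].tolist()
            if inconsistent:
                raise ValueError(
                    f"inconsistent {col} metadata within {key}(s): {inconsistent}"
                )

        self.data = df.reset_index(drop=True)

    # -- accessors -----------------------------------------------------

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def events(self) -> list[str]:
        return sorted(self.data["event"].unique())

    @property
    def n_species(self) -> int:
        return self.data["species"].nunique()

    @property
    def n_events(self) -> int:
        return self.data["event"].nunique()

    @property
    def n_observations(self) -> int:
        return len(self.data)

    def species_meta(self) -> list[SpeciesMeta]:
        sub = self.data.drop_duplicates("species").sort_values("species")
        return [SpeciesMeta(r.species, bool(r.is_primate)) for r in sub.itertuples()]

    def event_meta(self) -> list[EventMeta]:
        sub = self.data.drop_duplicates("event").sort_values("event")
        return [EventMeta(r.event, r.event_class) for r in sub.itertuples()]

    def is_primate(self, species: str) -> bool:
        sub = self.data.loc[self.data["species"] == species, "is_primate"]
        if sub.empty:
            raise KeyError(f"unknown species {species!r}")
        return bool(sub.iloc[0])

    def event_class(self, event: str) -> str:
        sub = self.data.loc[self.data["event"] == event, "event_class"]
        if sub.empty:
            raise KeyError(f"unknown event {event!r}")
        return str(sub.iloc[0])

    def drop_observation(self, species: str, event: str) -> "EventTimingTable":
        """Return a copy without the (species, event) row (for LOO folds)."""
        mask = (self.data["species"] == species) & (self.data["event"] == event)
        if not mask.any():
            raise KeyError(f"no observation ({species!r}, {event!r})")
        return EventTimingTable(self.data.loc[~mask])

    def to_frame(self) -> pd.DataFrame:
        return self.data.copy()


def _coerce_bool(col: pd.Series) -> pd.Series:
    def one(v: object) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUE_STRINGS:
            return True
        if s in _FALSE_STRINGS:
            return False
        raise SchemaError(f"cannot interpret is_primate value {v!r}")

    return col.map(one)


def read_event_table(path, fmt: str | None = None) -> EventTimingTable:
    """Read a long-format event-timing table from TSV or CSV.

    Parameters
    ----------
    path : str, pathlib.Path or file-like
        Source with header ``species,event,pc_day,is_primate,event_class``.
    fmt : {"tsv", "csv"}, optional
        Field separator; inferred from the file extension when omitted
        (``.csv`` -> comma, anything else -> tab).
    """
    if fmt is None:
        fmt = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"fmt must be 'tsv' or 'csv', got {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    return EventTimingTable(df)


def write_event_table(table_or_frame, path, fmt: str = "tsv", header_lines=()) -> None:
    """Write a table (or completed-matrix frame) back to TSV/CSV.

    ``header_lines`` are emitted as ``#``-prefixed comment lines before the
    header, used by the CLI for provenance stamps.
    """
    df = table_or_frame.to_frame() if hasattr(table_or_frame, "to_frame") else table_or_frame
    sep = "\t" if fmt == "tsv" else ","
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep=sep, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def filter_min_coverage(
    table: EventTimingTable,
    min_species_per_event: int = 2,
    min_events_per_species: int = 2,
) -> EventTimingTable:
    """Restrict the table to well-covered species and events.

    Keeps only events documented in at least ``min_species_per_event``
    species and species with at least ``min_events_per_species`` events.
    Removing an event can push a species below its threshold and vice
    versa, so the two criteria are applied alternately until a fixed point
    where both hold simultaneously.
    """
    df = table.data
    while True:
        ev_counts = df.groupby("event")["species"].nunique()
        keep_events = ev_counts.index[ev_counts >= min_species_per_event]
        sp_counts = df.groupby("species")["event"].nunique()
        keep_species = sp_counts.index[sp_counts >= min_events_per_species]
        new = df[df["event"].isin(keep_events) & df["species"].isin(keep_species)]
        if len(new) == len(df):
            break
        df = new
    if df.empty:
        raise ValueError("no events survive coverage filter")
    return EventTimingTable(df)


def log_transform(values) -> np.ndarray:
    """Element-wise natural log of positive PC-day values.

    The log is applied to reduce the dynamic range of the strongly
    right-skewed raw timings; it is the response scale for both models.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise ValueError("log_transform requires strictly positive finite values")
    return np.log(v)


def distribution_summary(values) -> DistributionSummary:
    """Fisher-Pearson sample skewness and excess kurtosis of a vector.

    Uses biased moment-based estimators (``scipy.stats.skew`` /
    ``kurtosis`` with their defaults); needs at least 3 values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values for skewness/kurtosis")
    return DistributionSummary(
        skewness=float(stats.skew(v)),
        kurtosis=float(stats.kurtosis(v)),  # excess, Fisher definition
        n=int(v.size),
        min=float(v.min()),
        max=float(v.max()),
    )
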