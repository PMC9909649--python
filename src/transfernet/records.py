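"""Patient-level transfer records: ingestion, cleaning, and descriptive summary.

One row per interhospital emergency-department (ED) transfer. Records arrive as
delimited text with a header; a schema config maps source columns onto the
canonical fields below. Cleaning follows the registry-curation convention that
invalid field values are set to missing (and counted) while rows that cannot
identify a transfer at all — no valid sender/receiver pair or no departure
time — are dropped (and counted).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

# --------------------------------------------------------------------------
# Canonical schema
# --------------------------------------------------------------------------

#: Canonical column order of a records frame.
RECORD_COLUMNS = (
    "record_id",
    "sender_id",
    "receiver_id",
    "depart_datetime",
    "arrive_datetime",
    "age",
    "sex",
    "reason",
    "condition_category",
    "surgery_at_receiver",
    "disposition",
)

#: Columns that must be present (directly or via schema mapping) in the input.
MANDATORY_COLUMNS = ("record_id", "sender_id", "receiver_id", "depart_datetime")

SEX_LEVELS = ("female", "male", "unknown")
REASON_LEVELS = (
    "patient_request",
    "specialist_unavailable",
    "capability_problem",
    "other",
)
DISPOSITION_LEVELS = (
    "ward_admission",
    "ed_observation",
    "icu_admission",
    "discharged_outpatient",
    "transferred_again",
    "transferred_back",
)

AGE_MIN, AGE_MAX = 0, 130

#: Departure time-of-day bands: hour h maps to 7<=h<15, 15<=h<23, else night.
TIME_BANDS = ("7a-3p", "3p-11p", "11p-7a")

SEASONS = ("spring", "summer", "fall", "winter")
_SEASON_BY_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
    12: "winter", 1: "winter", 2: "winter",
}

_BOOL_CODES = {
    "1": True, "0": False, "true": True, "false": False,
    "yes": True, "no": False, "y": True, "n": False, "t": True, "f": False,
}


@dataclass(frozen=True)
class TransferRecord:
    """A single patient transfer event between two hospital EDs."""

    record_id: str
    sender_id: str
    receiver_id: str
    depart_datetime: pd.Timestamp
    arrive_datetime: pd.Timestamp | None = None
    age: int | None = None
    sex: str = "unknown"
    reason: str | None = None
    condition_category: str | None = None
    surgery_at_receiver: bool | None = None
    disposition: str | None = None


@dataclass
class CleaningReport:
    """Accounting of what cleaning did to an input file."""

    rows_read: int = 0
    rows_retained: int = 0
    fields_nullified: dict[str, int] = field(default_factory=dict)
    duplicate_ids_dropped: int = 0
    rows_dropped: dict[str, int] = field(default_factory=dict)

    def nullify(self, field_name: str, n: int) -> None:
        if n:
            self.fields_nullified[field_name] = (
                self.fields_nullified.get(field_name, 0) + int(n)
            )

    def drop(self, why: str, n: int) -> None:
        if n:
            self.rows_dropped[why] = self.rows_dropped.get(why, 0) + int(n)


@dataclass
class DescriptiveSummary:
    """Descriptive statistics of a transfer cohort (the Table-1 layer)."""

    n_transfers: int
    age_mean: float
    age_sd: float
    categorical_tables: dict[str, list[tuple[str, int, float]]]
    reason_denominator: int


# --------------------------------------------------------------------------
# Reading and cleaning
# --------------------------------------------------------------------------

def load_schema_config(source: str | Path | Mapping[str, str] | None) -> dict[str, str]:
    """Resolve a schema config (canonical field -> source column name).

    Accepts a mapping, a YAML file path, or None (identity mapping).
    """
    if source is None:
        return {c: c for c in RECORD_COLUMNS}
    if isinstance(source, Mapping):
        mapping = dict(source)
    else:
        with open(source) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise ValueError(f"schema config {source!r} is not a mapping")
    unknown = set(mapping) - set(RECORD_COLUMNS)
    if unknown:
        raise ValueError(f"schema config maps unknown fields: {sorted(unknown)}")
    full = {c: c for c in RECORD_COLUMNS}
    full.update(mapping)
    return full


def _clean_enum(series: pd.Series, levels: tuple[str, ...]) -> tuple[pd.Series, int]:
    """Lower-case/strip codes; unknown codes become missing. Returns (clean, n_bad)."""
    raw = series.astype("string").str.strip().str.lower()
    raw = raw.replace({"": pd.NA, "nan": pd.NA, "none": pd.NA, "na": pd.NA})
    bad = raw.notna() & ~raw.isin(levels)
    return raw.where(~bad), int(bad.sum())


def read_transfers(
    path: str | Path | io.TextIOBase,
    schema_config: str | Path | Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Read, validate and clean a delimited transfer-record file.

    Row-level rules (violating rows are dropped and counted):

    * sender and receiver must both be present and distinct (no self-transfers);
    * the departure timestamp must parse;
    * duplicated ``record_id`` keeps the first occurrence.

    Field-level rules (violating values are set to missing and counted in
    ``fields_nullified``): age outside [0, 130], arrival before departure,
    unknown enum codes, unparseable booleans.

    Returns the canonical records frame and a :class:`CleaningReport`.
    """
    schema = load_schema_config(schema_config)
    try:
        raw = pd.read_csv(path, sep=delimiter, engine="python", dtype="string")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"cannot read transfer file {path!r}: {exc}") from exc

    missing_cols = [
        f for f in MANDATORY_COLUMNS if schema[f] not in raw.columns
    ]
    if missing_cols:
        raise ValueError(
            "mandatory column(s) missing from input: "
            + ", ".join(f"{f} (source {schema[f]!r})" for f in missing_cols)
        )

    report = CleaningReport(rows_read=len(raw))
    df = pd.DataFrame(index=raw.index)
    for canon in RECORD_COLUMNS:
        src = schema[canon]
        df[canon] = raw[src] if src in raw.columns else pd.Series(
            pd.NA, index=raw.index, dtype="string"
        )

    # -- row-level validity -------------------------------------------------
    for col in ("record_id", "sender_id", "receiver_id"):
        df[col] = df[col].astype("string").str.strip().replace({"": pd.NA})
    df["depart_datetime"] = pd.to_datetime(df["depart_datetime"], errors="coerce")

    bad_endpoint = df["sender_id"].isna() | df["receiver_id"].isna() | df["record_id"].isna()
    report.drop("missing_id_or_endpoint", bad_endpoint.sum())
    df = df[~bad_endpoint]

    self_tx = df["sender_id"] == df["receiver_id"]
    report.drop("self_transfer", self_tx.sum())
    df = df[~self_tx]

    bad_depart = df["depart_datetime"].isna()
    report.drop("missing_depart", bad_depart.sum())
    df = df[~bad_depart]

    dup = df["record_id"].duplicated(keep="first")
    report.duplicate_ids_dropped = int(dup.sum())
    df = df[~dup].copy()

    # -- field-level cleaning ----------------------------------------------
    arrive = pd.to_datetime(df["arrive_datetime"], errors="coerce")
    unparseable = df["arrive_datetime"].notna() & arrive.isna()
    early = arrive.notna() & (arrive < df["depart_datetime"])
    report.nullify("arrive_datetime", int(unparseable.sum() + early.sum()))
    df["arrive_datetime"] = arrive.where(~early)

    age = pd.to_numeric(df["age"], errors="coerce")
    bad_age = (df["age"].notna() & age.isna()) | age.lt(AGE_MIN) | age.gt(AGE_MAX)
    report.nullify("age", int(bad_age.sum()))
    df["age"] = age.where(~bad_age).round().astype("Int64")

    sex, n_bad = _clean_enum(df["sex"], SEX_LEVELS)
    report.nullify("sex", n_bad)
    df["sex"] = sex.fillna("unknown")

    for col, levels in (("reason", REASON_LEVELS), ("disposition", DISPOSITION_LEVELS)):
        clean, n_bad = _clean_enum(df[col], levels)
        report.nullify(col, n_bad)
        df[col] = clean

    df["condition_category"] = (
        df["condition_category"].astype("string").str.strip().replace({"": pd.NA})
    )

    surg_raw = df["surgery_at_receiver"].astype("string").str.strip().str.lower()
    surg = surg_raw.map(_BOOL_CODES)
    report.nullify("surgery_at_receiver", int((surg_raw.notna() & surg.isna()).sum()))
    df["surgery_at_receiver"] = surg.astype("boolean")

    report.rows_retained = len(df)
    return df.reset_index(drop=True), report


def write_transfers(df: pd.DataFrame, path: str | Path) -> None:
    """Write a records frame in the canonical CSV dialect (round-trip safe)."""
    out = df.loc[:, list(RECORD_COLUMNS)].copy()
    for col in ("depart_datetime", "arrive_datetime"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out["surgery_at_receiver"] = out["surgery_at_receiver"].map(
        {True: "1", False: "0"}
    )
    out.to_csv(path, index=False)


def frame_to_records(df: pd.DataFrame) -> list[TransferRecord]:
    """Materialize a records frame as typed :class:`TransferRecord` objects."""
    def _opt(v):
        return None if pd.isna(v) else v

    return [
        TransferRecord(
            record_id=row.record_id,
            sender_id=row.sender_id,
            receiver_id=row.receiver_id,
            depart_datetime=row.depart_datetime,
            arrive_datetime=_opt(row.arrive_datetime),
            age=_opt(row.age),
            sex=row.sex,
            reason=_opt(row.reason),
            condition_category=_opt(row.condition_category),
            surgery_at_receiver=_opt(row.surgery_at_receiver),
            disposition=_opt(row.disposition),
        )
        for row in df.itertuples(index=False)
    ]


def records_to_frame(records: Iterable[TransferRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records], columns=list(RECORD_COLUMNS))
    df["depart_datetime"] = pd.to_datetime(df["depart_datetime"])
    df["arrive_datetime"] = pd.to_datetime(df["arrive_datetime"])
    df["age"] = df["age"].astype("Int64")
    df["surgery_at_receiver"] = df["surgery_at_receiver"].astype("boolean")
    return df


# --------------------------------------------------------------------------
# Descriptive summary
# --------------------------------------------------------------------------

def time_band(hours: pd.Series) -> pd.Series:
    """Map departure hour to its time-of-day band (boundary at the later band)."""
    return pd.Series(
        np.select(
            [(hours >= 7) & (hours < 15), (hours >= 15) & (hours < 23)],
            [TIME_BANDS[0], TIME_BANDS[1]],
            default=TIME_BANDS[2],
        ),
        index=hours.index,
    )


def season_of(dates: pd.Series) -> pd.Series:
    """Meteorological season of the departure date (Dec–Feb winter, etc.)."""
    return dates.dt.month.map(_SEASON_BY_MONTH)


def _level_table(
    series: pd.Series, levels: Iterable[str] | None = None
) -> tuple[list[tuple[str, int, float]], int]:
    """Per-level (level, count, percent) with percents over the non-missing n."""
    nonmiss = series.dropna()
    denom = len(nonmiss)
    counts = nonmiss.value_counts()
    if levels is None:
        levels = list(counts.index)
    rows = []
    for lev in levels:
        c = int(counts.get(lev, 0))
        pct = round(100.0 * c / denom, 1) if denom else float("nan")
        rows.append((str(lev), c, pct))
    return rows, denom


def summarize_transfers(df: pd.DataFrame) -> DescriptiveSummary:
    """Descriptive summary of a transfer cohort.

    Reports n, mean/SD of age over non-missing ages, and per-level counts with
    one-decimal percents for sex, departure time-of-day band, weekend flag,
    season, transfer reason (percent over the non-missing reason denominator),
    condition category, surgery at the receiver, and disposition.
    """
    if df.empty:
        raise ValueError("cannot summarize an empty record set")

    depart = pd.to_datetime(df["depart_datetime"])
    ages = pd.to_numeric(df["age"], errors="coerce").dropna()

    tables: dict[str, list[tuple[str, int, float]]] = {}
    tables["sex"], _ = _level_table(df["sex"], SEX_LEVELS)
    tables["time_band"], _ = _level_table(time_band(depart.dt.hour), TIME_BANDS)
    weekend = depart.dt.dayofweek.isin((5, 6)).map({True: "weekend", False: "weekday"})
    tables["weekend"], _ = _level_table(weekend, ("weekend", "weekday"))
    tables["season"], _ = _level_table(season_of(depart), SEASONS)
    tables["reason"], reason_denom = _level_table(df["reason"], REASON_LEVELS)
    cond_levels = df["condition_category"].dropna().value_counts().index
    tables["condition_category"], _ = _level_table(df["condition_category"], cond_levels)
    surg = df["surgery_at_receiver"].map({True: "yes", False: "no"})
    tables["surgery_at_receiver"], _ = _level_table(surg, ("yes", "no"))
    tables["disposition"], _ = _level_table(df["disposition"], DISPOSITION_LEVELS)

    return DescriptiveSummary(
        n_transfers=len(df),
        age_mean=float(ages.mean()) if len(ages) else float("nan"),
        age_sd=float(ages.std(ddof=1)) if len(ages) > 1 else float("nan"),
        categorical_tables=tables,
        reason_denominator=reason_denom,
    )


def transfer_rate(n_transfers: int, n_ed_visits: int) -> float:
    """Transfers as a percentage of all ED visits over the same period."""
    if n_ed_visits <= 0:
        raise ValueError("n_ed_visits must be positive")
    return 100.0 * n_transfers / n_ed_visits


def summary_to_frame(summary: DescriptiveSummary) -> pd.DataFrame:
    """Flatten a summary to one row per variable level (CSV-exportable)."""
    rows = [("n_transfers", "", summary.n_transfers, float("nan")),
            ("age", "mean", summary.age_mean, float("nan")),
            ("age", "sd", summary.age_sd, float("nan"))]
    for var, table in summary.categorical_tables.items():
        for level, count, pct in table:
            rows.append((var, level, count, pct))
    return pd.DataFrame(rows, columns=["variable", "level", "value", "percent"])


def format_summary(summary: DescriptiveSummary) -> str:
    """Human-readable text report of a descriptive summary."""
    lines = [
        f"Transfers: {summary.n_transfers:,}",
        f"Age, mean (SD): {summary.age_mean:.1f} ({summary.age_sd:.1f})",
    ]
    for var, table in summary.categorical_tables.items():
        lines.append(f"{var}:")
        for level, count, pct in table:
            lines.append(f"  {level:<24s} {count:>9,} ({pct:.1f}%)")
    lines.append(f"Reason available for {summary.reason_denominator:,} transfers")
    return "\n".join(lines)
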