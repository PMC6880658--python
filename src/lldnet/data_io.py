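"""Cohort data model, CSV readers/writers, and eligibility/split rules.

A cohort is a per-subject table of the 10 clinician-rated depression items
(MADRS, each 0-6), the anxiety inventory sum (BAI, 0-63) and optionally its
21 items (each 0-3), demographic covariates, diagnosis-history exclusion
flags, and an optional anxiety-group label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MADRS_COLS = [f"m{i}" for i in range(1, 11)]
BAI_COLS = [f"b{i}" for i in range(1, 22)]

MADRS_ITEM_NAMES = [
    "apparent_sadness",
    "reported_sadness",
    "inner_tension",
    "reduced_sleep",
    "reduced_appetite",
    "concentration_difficulties",
    "lassitude",
    "inability_to_feel",
    "pessimistic_thought",
    "suicidal_thought",
]

# Three-factor grouping of the MADRS items used as node metadata:
# dysphoric apathy/retardation, psychic anxiety, vegetative.
CLUSTER_TAGS = {
    "m1": "dysphoric_apathy_retardation",
    "m2": "dysphoric_apathy_retardation",
    "m3": "psychic_anxiety",
    "m4": "vegetative",
    "m5": "vegetative",
    "m6": "dysphoric_apathy_retardation",
    "m7": "dysphoric_apathy_retardation",
    "m8": "dysphoric_apathy_retardation",
    "m9": "psychic_anxiety",
    "m10": "psychic_anxiety",
}

KNOWN_FLAGS = {"bipolar", "schizophrenia", "other_mental_disorder", "dementia"}

REQUIRED_COLS = ["subject_id", *MADRS_COLS, "age", "sex", "education_years"]


class CohortSchemaError(ValueError):
    """A required column is missing or mis-typed."""


class CohortValidationError(ValueError):
    """Row-level invariant violations; message names subjects/rows."""


@dataclass
class CohortConfig:
    """Eligibility and anxiety-split cutoffs.

    madrs_cutoff: minimum MADRS sum for inclusion (inclusive; default 10).
    bai_cutoff: BAI sum at or above which a subject is high-anxiety
        (inclusive; default 16, the moderate-anxiety boundary).
    exclusion_set: diagnosis-history flags that remove a subject.
    """

    madrs_cutoff: int = 10
    bai_cutoff: int = 16
    exclusion_set: frozenset = frozenset({"bipolar", "schizophrenia", "other_mental_disorder", "dementia"})

    def __post_init__(self):
        if self.madrs_cutoff <= 0 or self.bai_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        self.exclusion_set = frozenset(self.exclusion_set)


@dataclass
class CohortTable:
    """Validated per-subject table. `df` is the canonical storage.

    Columns: subject_id, m1..m10, bai_sum (nullable), optional b1..b21,
    age, sex ('F'/'M'), education_years, flags (semicolon-joined string,
    '' for none), group (optional, 'low_anxiety'/'high_anxiety' or '').
    """

    df: pd.DataFrame
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        _validate(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def madrs_sum(self) -> pd.Series:
        return self.df[MADRS_COLS].sum(axis=1)

    @property
    def has_bai_items(self) -> bool:
        return all(c in self.df.columns for c in BAI_COLS)

    def madrs_matrix(self) -> np.ndarray:
        """(n, 10) integer array of item scores."""
        return self.df[MADRS_COLS].to_numpy(dtype=int)

    def flags_of(self, row) -> frozenset:
        raw = row.get("flags", "") if isinstance(row, dict) else row
        if not raw or (isinstance(raw, float) and np.isnan(raw)):
            return frozenset()
        return frozenset(p for p in str(raw).split(";") if p)

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.df.loc[mask].copy())


def _flags_series(df: pd.DataFrame) -> pd.Series:
    if "flags" not in df.columns:
        return pd.Series([""] * len(df), index=df.index)
    return df["flags"].fillna("").astype(str).replace("nan", "")


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required columns: {missing}")

    problems: list[str] = []
    ids = df["subject_id"].astype(str)
    dup = ids[ids.duplicated()].tolist()
    if dup:
        problems.append(f"duplicate subject_id values: {sorted(set(dup))}")

    for col in MADRS_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (vals > 6) | (vals != vals.round())]
        for i in bad:
            problems.append(f"row {i} (subject {ids.iloc[i]}): {col}={df[col].iloc[i]!r} not an integer in 0..6")

    if "bai_sum" in df.columns:
        bs = pd.to_numeric(df["bai_sum"], errors="coerce")
        bad = df.index[bs.notna() & ((bs < 0) | (bs > 63))]
        for i in bad:
            problems.append(f"row {i} (subject {ids.iloc[i]}): bai_sum={df['bai_sum'].iloc[i]!r} outside 0..63")

    has_items = all(c in df.columns for c in BAI_COLS)
    if has_items:
        for col in BAI_COLS:
            v = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[v.isna() | (v < 0) | (v > 3)]
            for i in bad:
                problems.append(f"row {i} (subject {ids.iloc[i]}): {col}={df[col].iloc[i]!r} not in 0..3")
        if not problems and "bai_sum" in df.columns:
            isum = df[BAI_COLS].astype(float).sum(axis=1)
            bs = pd.to_numeric(df["bai_sum"], errors="coerce")
            bad = df.index[bs.notna() & (isum != bs)]
            for i in bad:
                problems.append(
                    f"row {i} (subject {ids.iloc[i]}): bai items sum to {isum.iloc[i]:.0f} "
                    f"but bai_sum={bs.iloc[i]:.0f}"
                )

    if "age" in df.columns:
        age = pd.to_numeric(df["age"], errors="coerce")
        for i in df.index[age.isna() | (age <= 0)]:
            problems.append(f"row {i} (subject {ids.iloc[i]}): age={df['age'].iloc[i]!r} not positive")
    edu = pd.to_numeric(df["education_years"], errors="coerce")
    for i in df.index[edu.isna() | (edu < 0)]:
        problems.append(f"row {i} (subject {ids.iloc[i]}): education_years={df['education_years'].iloc[i]!r} negative or missing")

    flags = _flags_series(df)
    for i, raw in flags.items():
        unknown = {p for p in raw.split(";") if p} - KNOWN_FLAGS
        if unknown:
            problems.append(f"row {i} (subject {ids.iloc[i]}): unknown flags {sorted(unknown)}")

    if problems:
        raise CohortValidationError("; ".join(problems))


def read_cohort(path, dialect: dict | None = None) -> CohortTable:
    """Read a cohort CSV (comma-separated, header, UTF-8 by default).

    Raises CohortSchemaError for missing columns and CohortValidationError
    (naming rows and subjects) for out-of-range or inconsistent values.
    """
    opts = {"sep": ",", "encoding": "utf-8"}
    if dialect:
        opts.update(dialect)
    df = pd.read_csv(path, dtype={"subject_id": str}, **opts)
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    if "group" in df.columns:
        df["group"] = df["group"].fillna("")
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort to CSV; read_cohort(write_cohort(t)) is the identity."""
    cohort.df.to_csv(path, index=False)


def apply_eligibility(cohort: CohortTable, config: CohortConfig | None = None) -> CohortTable:
    """Retain subjects with MADRS sum >= cutoff and no excluded diagnosis flag.

    Idempotent. Counts removed per reason land in the result's filter_log
    and the module logger; an empty result is a warning, not an error.
    """
    config = config or CohortConfig()
    df = cohort.df
    msum = cohort.madrs_sum
    below = msum < config.madrs_cutoff

    flags = _flags_series(df)
    flagged_reason = {}
    excluded_by_flag = pd.Series(False, index=df.index)
    for fl in sorted(config.exclusion_set):
        hit = flags.apply(lambda raw: fl in raw.split(";")) & ~below & ~excluded_by_flag
        flagged_reason[fl] = int(hit.sum())
        excluded_by_flag |= hit

    keep = ~below & ~excluded_by_flag
    log = {"input": len(df), "below_madrs_cutoff": int(below.sum()), **flagged_reason, "retained": int(keep.sum())}
    for reason, cnt in log.items():
        logger.info("eligibility: %s = %d", reason, cnt)
    if keep.sum() == 0:
        logger.warning("eligibility filter removed every subject")
    out = CohortTable(df.loc[keep].copy())
    out.filter_log = log
    return out


def split_by_anxiety(cohort: CohortTable, config: CohortConfig | None = None):
    """Split into (low, high) anxiety groups at the BAI cutoff (high inclusive).

    Every subject must have a BAI sum; the two parts partition the input.
    Group labels are stamped into the returned tables.
    """
    config = config or CohortConfig()
    if "bai_sum" not in cohort.df.columns:
        raise CohortValidationError("bai_sum column absent; cannot split by anxiety")
    bs = pd.to_numeric(cohort.df["bai_sum"], errors="coerce")
    missing = cohort.df["subject_id"][bs.isna()].tolist()
    if missing:
        raise CohortValidationError(f"missing bai_sum for subjects: {missing}")
    high_mask = bs >= config.bai_cutoff
    low = cohort.df.loc[~high_mask].copy()
    high = cohort.df.loc[high_mask].copy()
    low["group"] = "low_anxiety"
    high["group"] = "high_anxiety"
    return CohortTable(low), CohortTable(high)
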