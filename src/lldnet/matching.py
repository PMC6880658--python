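"""Propensity-score matching of high-anxiety to low-anxiety subjects.

A multivariable logistic regression of high-anxiety membership on severity
and demographic covariates yields each subject's propensity score.  Greedy
1:1 nearest-neighbor matching without replacement runs on the logit of the
propensity, treated (high-anxiety) subjects processed in decreasing
propensity order, with a caliper expressed in SD units of the logit
propensity (the Rosenbaum-Rubin convention); unmatched subjects are
discarded.  Balance is summarized by standardized mean differences
before/after matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import CohortTable, MADRS_COLS


class MatchingError(RuntimeError):
    pass


@dataclass
class MatchConfig:
    """covariates: column names used in the propensity model ('madrs_sum'
    and 'sex' are expanded internally); caliper in SD units of the logit
    propensity unless caliper_scale='raw' (raw logit units)."""

    covariates: tuple = ("madrs_sum", "age", "sex", "education_years")
    caliper: float = 0.25
    caliper_scale: str = "sd"
    ratio: int = 1

    def __post_init__(self):
        if self.caliper <= 0:
            raise ValueError("caliper must be positive")
        if not self.covariates:
            raise ValueError("covariates must be non-empty")
        if self.caliper_scale not in ("sd", "raw"):
            raise ValueError("caliper_scale must be 'sd' or 'raw'")
        if self.ratio != 1:
            raise ValueError("only 1:1 matching is supported")


@dataclass
class MatchResult:
    pairs: list                      # (treated_id, control_id)
    propensity: pd.Series            # indexed by subject_id
    caliper_logit: float             # the realized caliper on the logit scale
    balance: pd.DataFrame            # SMD before/after per covariate
    n_matched: int = 0

    def __post_init__(self):
        self.n_matched = len(self.pairs)


def _design(cohort: CohortTable, covariates) -> pd.DataFrame:
    df = cohort.df
    cols = {}
    for c in covariates:
        if c == "madrs_sum":
            cols[c] = cohort.madrs_sum.to_numpy(dtype=float)
        elif c == "sex":
            cols["female"] = (df["sex"].astype(str) == "F").astype(float).to_numpy()
        else:
            cols[c] = pd.to_numeric(df[c]).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    return sm.add_constant(X, has_constant="add")


def fit_propensity(cohort: CohortTable, config: MatchConfig | None = None) -> pd.Series:
    """Fitted P(high anxiety | covariates) per subject, by logistic MLE.

    The cohort must carry group labels from the anxiety split.  Perfect
    separation raises MatchingError.
    """
    config = config or MatchConfig()
    groups = cohort.df["group"].astype(str)
    if not {"low_anxiety", "high_anxiety"} <= set(groups):
        raise MatchingError("cohort must contain both low_anxiety and high_anxiety subjects")
    y = (groups == "high_anxiety").astype(float).to_numpy()
    X = _design(cohort, config.covariates)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except Exception as e:  # statsmodels PerfectSeparationError and kin
        raise MatchingError(f"propensity model failed ({e}); review covariates for separation") from e
    p = np.asarray(fit.predict(X), dtype=float)
    if np.any(p <= 1e-10) or np.any(p >= 1 - 1e-10):
        raise MatchingError("propensity model produced probabilities at 0/1; "
                            "covariates may perfectly separate the groups")
    return pd.Series(p, index=cohort.df["subject_id"].to_numpy(), name="propensity")


def _smd(x_t: np.ndarray, x_c: np.ndarray, sd_pool: float) -> float:
    if sd_pool == 0:
        return 0.0
    return float((x_t.mean() - x_c.mean()) / sd_pool)


def match(cohort: CohortTable, propensity: pd.Series, config: MatchConfig | None = None) -> MatchResult:
    """Greedy 1:1 nearest-neighbor caliper matching on the logit propensity.

    Pairs are formed closest-first: among all treated-control pairs within
    the caliper, the pair with the least propensity difference is matched
    first, then the next-closest among the remaining subjects, and so on
    (distance ties broken by input order).  Subjects left without an
    in-caliper partner are discarded.  Closest-first pairing avoids the
    systematic one-sided bias of processing treated units in a fixed order
    when the two propensity distributions are shifted.
    """
    config = config or MatchConfig()
    df = cohort.df
    groups = df["group"].astype(str)
    ids = df["subject_id"].to_numpy()
    logit = np.log(propensity / (1 - propensity))
    logit_by_id = pd.Series(logit.to_numpy(), index=propensity.index)

    cal = config.caliper * (logit_by_id.std(ddof=1) if config.caliper_scale == "sd" else 1.0)

    t_ids = list(ids[(groups == "high_anxiety").to_numpy()])
    c_ids = list(ids[(groups == "low_anxiety").to_numpy()])
    if not t_ids or not c_ids:
        raise MatchingError("both groups must be non-empty")
    tl = logit_by_id[t_ids].to_numpy()
    cl = logit_by_id[c_ids].to_numpy()
    dist = np.abs(tl[:, None] - cl[None, :])
    ti, ci = np.nonzero(dist <= cal)
    order = np.lexsort((ci, ti, dist[ti, ci]))  # distance, then input order

    used_t = np.zeros(len(t_ids), dtype=bool)
    used_c = np.zeros(len(c_ids), dtype=bool)
    pairs = []
    for k in order:
        a, b = ti[k], ci[k]
        if used_t[a] or used_c[b]:
            continue
        used_t[a] = used_c[b] = True
        pairs.append((t_ids[a], c_ids[b]))
    if not pairs:
        raise MatchingError("no pairs found within the caliper")

    # balance diagnostics on the propensity-model covariates
    X = _design(cohort, config.covariates).drop(columns="const")
    X.index = ids
    t_mask = (groups == "high_anxiety").to_numpy()
    rows = []
    t_ids = [a for a, _ in pairs]
    c_ids = [b for _, b in pairs]
    for col in X.columns:
        sd_pool = np.sqrt((X[col][t_mask].var(ddof=1) + X[col][~t_mask].var(ddof=1)) / 2.0)
        rows.append({
            "covariate": col,
            "smd_before": _smd(X[col][t_mask].to_numpy(), X[col][~t_mask].to_numpy(), sd_pool),
            "smd_after": _smd(X[col].loc[t_ids].to_numpy(), X[col].loc[c_ids].to_numpy(), sd_pool),
        })

    return MatchResult(pairs=pairs, propensity=propensity, caliper_logit=float(cal),
                       balance=pd.DataFrame(rows))


def matched_tables(cohort: CohortTable, result: MatchResult):
    """(low, high) CohortTables restricted to matched pairs, in pair order."""
    df = cohort.df.set_index(cohort.df["subject_id"].to_numpy())
    high = df.loc[[a for a, _ in result.pairs]].reset_index(drop=True)
    low = df.loc[[b for _, b in result.pairs]].reset_index(drop=True)
    return CohortTable(low), CohortTable(high)


def match_cohort(cohort: CohortTable, config: MatchConfig | None = None) -> MatchResult:
    """fit_propensity + match in one call."""
    config = config or MatchConfig()
    return match(cohort, fit_propensity(cohort, config), config)
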