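"""Permutation network comparison between two independent groups.

Both groups' networks are estimated with the same polychoric +
graphical-lasso + EBIC chain.  Three families of statistics are compared:

* global strength — |sum of absolute edge weights(A) - (B)|;
* global structure — the maximum absolute single-edge difference
  (the invariance statistic);
* per-edge differences, with Holm step-down adjustment.

The null distribution comes from pooling subjects and randomly re-splitting
them at the original group sizes, refitting both networks for every
permutation.  p-values use the plus-one estimator, so they are never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import association_matrix
from .data_io import CohortTable
from .network import GlassoConfig, fit_network


class ComparisonError(RuntimeError):
    pass


@dataclass
class NCTResult:
    labels: list
    s_observed: float
    m_observed: float
    edge_diffs: np.ndarray           # upper-triangle order, signed (A - B)
    p_strength: float
    p_structure: float
    p_edges_raw: np.ndarray
    p_edges: np.ndarray              # Holm-adjusted
    n_perm: int
    seed: int
    weights_a: np.ndarray = None
    weights_b: np.ndarray = None

    def edge_pairs(self):
        p = len(self.labels)
        iu, ju = np.triu_indices(p, 1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(iu, ju)]


def _fit_weights(df, config: GlassoConfig, include_anxiety_node: bool):
    sub = CohortTable(df.reset_index(drop=True))
    assoc = association_matrix(sub, include_anxiety_node=include_anxiety_node)
    net = fit_network(assoc, len(df), config)
    return net.labels, net.weights


def _stats(wa, wb, iu):
    da = np.abs(wa[iu]).sum() - np.abs(wb[iu]).sum()
    diffs = wa[iu] - wb[iu]
    return abs(float(da)), float(np.max(np.abs(diffs))), diffs


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def nct(group_a: CohortTable, group_b: CohortTable, config: GlassoConfig | None = None,
        n_perm: int = 1000, seed: int = 0, include_anxiety_node: bool = False) -> NCTResult:
    """Two-tailed permutation comparison of two symptom networks.

    Each permutation pools the subjects (sorted by subject id, so the
    result is invariant to which table is called A), re-splits them at the
    original sizes, and refits the full estimation chain on both halves.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    config = config or GlassoConfig()
    na, nb = group_a.n, group_b.n
    min_n = 31
    if na < min_n or nb < min_n:
        raise ComparisonError(
            f"groups of sizes ({na}, {nb}) too small; each needs >= {min_n} subjects for estimation")

    labels, wa = _fit_weights(group_a.df, config, include_anxiety_node)
    _, wb = _fit_weights(group_b.df, config, include_anxiety_node)
    p = len(labels)
    iu = np.triu_indices(p, 1)
    s_obs, m_obs, diffs = _stats(wa, wb, iu)

    pooled = pd.concat([group_a.df, group_b.df], ignore_index=True)
    pooled = pooled.sort_values("subject_id", kind="mergesort").reset_index(drop=True)

    rng = np.random.default_rng(seed)
    ge_s = 0
    ge_m = 0
    ge_e = np.zeros(len(diffs))
    ntot = na + nb
    for _ in range(n_perm):
        perm = rng.permutation(ntot)
        da = pooled.iloc[perm[:na]]
        db = pooled.iloc[perm[na:]]
        _, pwa = _fit_weights(da, config, include_anxiety_node)
        _, pwb = _fit_weights(db, config, include_anxiety_node)
        ps, pm, pdiffs = _stats(pwa, pwb, iu)
        ge_s += ps >= s_obs
        ge_m += pm >= m_obs
        ge_e += np.abs(pdiffs) >= np.abs(diffs)

    p_strength = (1.0 + ge_s) / (1.0 + n_perm)
    p_structure = (1.0 + ge_m) / (1.0 + n_perm)
    p_raw = (1.0 + ge_e) / (1.0 + n_perm)

    return NCTResult(
        labels=labels, s_observed=s_obs, m_observed=m_obs, edge_diffs=diffs,
        p_strength=float(p_strength), p_structure=float(p_structure),
        p_edges_raw=p_raw, p_edges=holm_adjust(p_raw), n_perm=n_perm, seed=seed,
        weights_a=wa, weights_b=wb,
    )


def edge_tests(result: NCTResult, alpha: float = 0.05):
    """Edges whose Holm-adjusted permutation p falls below alpha."""
    pairs = result.edge_pairs()
    return [pairs[k] for k in range(len(pairs)) if result.p_edges[k] < alpha]
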