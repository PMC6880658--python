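"""Bootstrap accuracy and stability of the estimated network.

Edge-weight accuracy: nonparametric bootstrap (resample subjects with
replacement, refit the polychoric + graphical-lasso chain, collect each
edge's distribution, report 2.5/97.5 percentile intervals).

Centrality stability: case-dropping bootstrap — re-estimate on subsamples
with a growing fraction of subjects dropped and measure how well subsample
node strength tracks the full-sample ordering.  The CS coefficient is the
largest drop fraction at which the correlation stays >= 0.7 in at least
95% of resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .association import association_matrix
from .centrality import strength
from .data_io import CohortTable
from .network import GlassoConfig, fit_network

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))


class ResamplingError(RuntimeError):
    pass


@dataclass
class BootstrapResult:
    labels: list
    point_weights: np.ndarray          # full-sample edge weights (upper triangle order)
    edge_ci_low: np.ndarray
    edge_ci_high: np.ndarray
    n_boot: int
    seed: int
    n_failed: int = 0
    cs_coefficient: dict = field(default_factory=dict)

    def edge_index(self):
        p = len(self.labels)
        return list(zip(*np.triu_indices(p, 1)))

    def ci_contains_zero(self) -> np.ndarray:
        return (self.edge_ci_low <= 0) & (self.edge_ci_high >= 0)


def _refit_weights(cohort: CohortTable, rows: np.ndarray, config: GlassoConfig,
                   include_anxiety_node: bool):
    sub = CohortTable(cohort.df.iloc[rows].reset_index(drop=True).assign(
        subject_id=[f"r{i}" for i in range(len(rows))]))
    assoc = association_matrix(sub, include_anxiety_node=include_anxiety_node)
    return fit_network(assoc, len(rows), config)


def bootstrap_edges(cohort: CohortTable, config: GlassoConfig | None = None,
                    n_boot: int = 1000, seed: int = 0,
                    include_anxiety_node: bool = False) -> BootstrapResult:
    """Percentile bootstrap CIs for every edge weight.

    Resamples failing to estimate are skipped and counted; more than 5%
    failures raises ResamplingError.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    config = config or GlassoConfig()
    rng = np.random.default_rng(seed)
    n = cohort.n
    full = _refit_weights(cohort, np.arange(n), config, include_anxiety_node)
    iu = np.triu_indices(full.p, 1)

    draws = []
    failed = 0
    while len(draws) < n_boot:
        rows = rng.integers(0, n, size=n)
        try:
            net = _refit_weights(cohort, rows, config, include_anxiety_node)
        except Exception:  # noqa: BLE001 - any estimation failure counts
            failed += 1
            if failed > 0.05 * n_boot:
                raise ResamplingError(f"{failed} bootstrap resamples failed (> 5% of {n_boot})")
            continue
        draws.append(net.weights[iu])
    draws = np.array(draws)

    return BootstrapResult(
        labels=list(full.labels),
        point_weights=full.weights[iu],
        edge_ci_low=np.percentile(draws, 2.5, axis=0),
        edge_ci_high=np.percentile(draws, 97.5, axis=0),
        n_boot=n_boot,
        seed=seed,
        n_failed=failed,
    )


def case_drop_stability(cohort: CohortTable, config: GlassoConfig | None = None,
                        drop_grid=DEFAULT_DROP_GRID, n_boot: int = 250, seed: int = 0,
                        threshold: float = 0.7, coverage: float = 0.95):
    """Case-dropping stability of node strength.

    Returns (cs_coefficient, detail) where detail maps each drop
    proportion to the 5th-percentile Spearman correlation between
    subsample strength and full-sample strength.  cs_coefficient is the
    largest grid proportion whose low quantile is >= `threshold` (0 if
    none qualifies).
    """
    config = config or GlassoConfig()
    drop_grid = sorted(drop_grid)
    if not all(0 < d <= 0.75 for d in drop_grid):
        raise ValueError("drop proportions must lie in (0, 0.75]")
    rng = np.random.default_rng(seed)
    n = cohort.n
    full_strength = strength(_refit_weights(cohort, np.arange(n), config, False))

    detail = {}
    for d in drop_grid:
        m = max(int(round(n * (1 - d))), 31)
        cors = []
        failed = 0
        while len(cors) < n_boot:
            rows = rng.choice(n, size=m, replace=False)
            try:
                s = strength(_refit_weights(cohort, rows, config, False))
            except Exception:  # noqa: BLE001
                failed += 1
                if failed > 0.05 * n_boot:
                    raise ResamplingError(f"too many failures at drop={d}")
                continue
            if np.std(s) == 0 or np.std(full_strength) == 0:
                cors.append(0.0)
            else:
                cors.append(float(spearmanr(s, full_strength).statistic))
        detail[d] = float(np.quantile(cors, 1.0 - coverage))

    cs = 0.0
    for d in drop_grid:
        if detail[d] >= threshold:
            cs = d
    return cs, detail
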