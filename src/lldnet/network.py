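"""Regularized partial-correlation network estimation.

Fits an L1-penalized Gaussian graphical model (graphical lasso) over a
log-spaced penalty path and selects the penalty by the Extended Bayesian
Information Criterion, EBIC = -2 loglik + E log n + 4 gamma E log P, where
E is the number of edges and P the number of nodes; gamma = 0 reduces to
plain BIC.  Edge weights of the selected model are the partial
correlations -K_ij / sqrt(K_ii K_jj) of the estimated precision K.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

try:  # warm-startable solver; falls back to the public API if unavailable
    from sklearn.covariance._graph_lasso import _graphical_lasso as _glasso_warm
except ImportError:  # pragma: no cover
    _glasso_warm = None

from .association import AssociationMatrix

_ZERO_TOL = 1e-8


class GlassoError(RuntimeError):
    def __init__(self, msg, partial_path=None):
        super().__init__(msg)
        self.partial_path = partial_path or []


@dataclass
class GlassoConfig:
    """Penalty-path and EBIC settings.

    gamma: EBIC hyperparameter (0 = BIC).
    n_lambda: number of penalties on the log-spaced path.
    lambda_min_ratio: smallest penalty as a fraction of lambda_max
        (the largest absolute off-diagonal correlation).
    """

    gamma: float = 0.0
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    penalize_diagonal: bool = False

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.penalize_diagonal:
            raise ValueError("diagonal penalization is not supported")


@dataclass
class SymptomNetwork:
    """Weighted network: symmetric zero-diagonal partial correlations."""

    labels: list
    weights: np.ndarray
    lambda_selected: float
    ebic: float
    n: int
    cluster_tags: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_list(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(self.p, 1)
        keep = self.weights[iu, ju] != 0
        return pd.DataFrame({
            "node_i": [self.labels[i] for i in iu[keep]],
            "node_j": [self.labels[j] for j in ju[keep]],
            "weight": self.weights[iu, ju][keep],
        })

    def global_strength(self) -> float:
        return float(np.abs(np.triu(self.weights, 1)).sum())

    def to_json(self) -> str:
        return json.dumps({
            "labels": list(self.labels),
            "weights": self.weights.tolist(),
            "lambda_selected": self.lambda_selected,
            "ebic": self.ebic,
            "n": self.n,
            "cluster_tags": self.cluster_tags,
        })

    def write(self, stem) -> None:
        """Write square CSV, edge-list CSV and JSON next to `stem`."""
        pd.DataFrame(self.weights, index=self.labels, columns=self.labels).to_csv(f"{stem}_matrix.csv")
        self.edge_list().to_csv(f"{stem}_edges.csv", index=False)
        with open(f"{stem}.json", "w") as fh:
            fh.write(self.to_json())


def lambda_grid(assoc_values: np.ndarray, config: GlassoConfig) -> np.ndarray:
    off = np.abs(assoc_values - np.diag(np.diag(assoc_values)))
    lam_max = max(off.max(), 1e-4)
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)


def glasso_path(assoc: AssociationMatrix, n: int, config: GlassoConfig | None = None):
    """Graphical lasso solutions along the penalty path.

    Returns a list of (lambda, precision, loglik) with loglik =
    (n/2)(log det K - trace(S K)), constants dropped.  Raises GlassoError
    (carrying the partial path) if any penalty fails to converge.
    """
    config = config or GlassoConfig()
    S = np.asarray(assoc.values, dtype=float)
    if n <= S.shape[0]:
        raise GlassoError(f"sample size {n} must exceed node count {S.shape[0]}")
    path = []
    cov_prev = None
    for lam in lambda_grid(S, config):
        try:
            with warnings.catch_warnings():
                # the dual gap bottoms out around -1e-5 from rounding; the
                # solution is converged, only the warning is spurious
                warnings.simplefilter("ignore", ConvergenceWarning)
                if _glasso_warm is not None:
                    # warm start from the previous (larger) penalty's solution
                    out = _glasso_warm(S, float(lam), cov_init=cov_prev,
                                       tol=1e-6, enet_tol=1e-6, max_iter=200)
                    cov_prev, K = out[0], out[1]
                else:
                    cov_prev, K = graphical_lasso(S, alpha=float(lam), tol=1e-6,
                                                  enet_tol=1e-6, max_iter=200)
        except Exception as e:  # noqa: BLE001 - sklearn raises FloatingPointError etc.
            raise GlassoError(f"graphical lasso failed to converge at lambda={lam:.6g}: {e}",
                              partial_path=path) from e
        K = (K + K.T) / 2.0
        sign, logdet = np.linalg.slogdet(K)
        loglik = (n / 2.0) * (logdet - float(np.sum(S * K)))
        path.append((float(lam), K, float(loglik)))
    return path


def _partial_corr(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) < _ZERO_TOL] = 0.0
    return (W + W.T) / 2.0


def ebic_score(loglik: float, K: np.ndarray, n: int, gamma: float) -> float:
    P = K.shape[0]
    iu = np.triu_indices(P, 1)
    E = int(np.count_nonzero(np.abs(K[iu]) > _ZERO_TOL))
    return -2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(P)


def select_ebic(path, n: int, config: GlassoConfig | None = None,
                labels=None, cluster_tags=None) -> SymptomNetwork:
    """Pick the EBIC-minimizing penalty (ties resolved toward the sparser,
    larger-lambda model) and return the partial-correlation network."""
    config = config or GlassoConfig()
    if not path:
        raise GlassoError("empty path")
    scores = [ebic_score(ll, K, n, config.gamma) for (_, K, ll) in path]
    # path is ordered from large lambda (sparse) down; first minimum wins ties
    best = int(np.argmin(scores))
    lam, K, _ = path[best]
    W = _partial_corr(K)
    p = K.shape[0]
    labels = list(labels) if labels is not None else [f"v{i}" for i in range(p)]
    return SymptomNetwork(labels=labels, weights=W, lambda_selected=lam,
                          ebic=float(scores[best]), n=n,
                          cluster_tags=dict(cluster_tags or {}))


def fit_network(assoc: AssociationMatrix, n: int, config: GlassoConfig | None = None,
                cluster_tags=None) -> SymptomNetwork:
    """Convenience: full path + EBIC selection from an association matrix."""
    config = config or GlassoConfig()
    path = glasso_path(assoc, n, config)
    return select_ebic(path, n, config, labels=assoc.labels, cluster_tags=cluster_tags)
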