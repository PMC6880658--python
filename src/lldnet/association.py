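"""Latent-correlation estimation for ordinal and mixed data.

Polychoric correlation treats two ordinal variables as discretizations of a
bivariate standard normal; polyserial is the ordinal-continuous analogue.
Both are estimated by the two-step method: thresholds from the inverse
normal CDF of the marginal cumulative proportions, then a bounded
one-dimensional likelihood maximization over the latent correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr
from scipy.stats import norm

from ._bvn import bvn_cdf
from .data_io import CohortTable, MADRS_COLS

RHO_BOUND = 0.999
_OPT_TOL = 1e-6


class AssociationError(ValueError):
    pass


@dataclass
class AssociationMatrix:
    """Symmetric unit-diagonal correlation matrix with estimation metadata."""

    labels: list
    values: np.ndarray
    method_per_pair: dict = field(default_factory=dict)
    psd_repaired: bool = False

    @property
    def p(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, stem) -> None:
        """Square-matrix CSV plus a JSON sidecar (methods, PSD flag)."""
        import json

        self.to_dataframe().to_csv(f"{stem}.csv")
        sidecar = {
            "labels": list(self.labels),
            "psd_repaired": bool(self.psd_repaired),
            "method_per_pair": {f"{a}--{b}": m for (a, b), m in self.method_per_pair.items()},
        }
        with open(f"{stem}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def _thresholds(x: np.ndarray):
    """Category values and interior thresholds from marginal proportions."""
    cats, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    tau = norm.ppf(cum)
    return cats, tau


def _cell_counts(x, y):
    cx, cy = np.unique(x), np.unique(y)
    table = np.zeros((len(cx), len(cy)))
    ix = np.searchsorted(cx, x)
    iy = np.searchsorted(cy, y)
    np.add.at(table, (ix, iy), 1.0)
    return table


def _table_loglik_factory(table: np.ndarray, tau_x: np.ndarray, tau_y: np.ndarray):
    # Zero cells are harmless to the ML criterion (they contribute no terms)
    # except in 2x2 tables, where an empty cell makes the MLE degenerate at
    # +/-1; there the standard 0.5 continuity correction is applied.
    if table.shape == (2, 2) and np.any(table == 0):
        table = table + 0.5
    ax = np.concatenate([[-30.0], tau_x, [30.0]])
    ay = np.concatenate([[-30.0], tau_y, [30.0]])
    gx, gy = np.meshgrid(ax, ay, indexing="ij")

    def negloglik(rho: float) -> float:
        cdf = bvn_cdf(gx, gy, rho)
        cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
        cell = np.clip(cell, 1e-300, None)
        return -float(np.sum(table * np.log(cell)))

    return negloglik


def _maximize(negloglik) -> float:
    res = minimize_scalar(negloglik, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": _OPT_TOL})
    return float(res.x)


def polychoric(x, y) -> float:
    """Two-step polychoric correlation of two ordinal vectors.

    Thresholds come from the marginal cumulative proportions; the latent
    correlation maximizes the bivariate-normal cell likelihood of the
    contingency table. Result clipped to (-0.999, 0.999).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y) or len(x) < 10:
        raise AssociationError("vectors must have equal length >= 10")
    _, tau_x = _thresholds(x)
    _, tau_y = _thresholds(y)
    if tau_x.size == 0 or tau_y.size == 0:
        raise AssociationError("polychoric undefined: a variable has a single observed category")
    table = _cell_counts(x, y)
    return _maximize(_table_loglik_factory(table, tau_x, tau_y))


def polychoric_from_table(table) -> float:
    """Polychoric correlation from a contingency table of counts."""
    table = np.asarray(table, dtype=float)
    rowp = table.sum(axis=1)
    colp = table.sum(axis=0)
    n = table.sum()
    tau_x = norm.ppf(np.cumsum(rowp)[:-1] / n)
    tau_y = norm.ppf(np.cumsum(colp)[:-1] / n)
    return _maximize(_table_loglik_factory(table, tau_x, tau_y))


def tetrachoric_closed_form(table) -> float:
    """cos(pi / (1 + sqrt(ad/bc))) approximation for 2x2 tables (reference)."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    if b * c == 0:
        return 1.0 if a * d > 0 else 0.0
    return float(np.cos(np.pi / (1.0 + np.sqrt((a * d) / (b * c)))))


def polyserial(x, y) -> float:
    """Two-step polyserial correlation of ordinal x with continuous y.

    y is standardized; thresholds for x come from its marginals; the latent
    correlation maximizes the conditional ordinal likelihood
    P(x_i = c | y_i) under the bivariate normal model.
    """
    x = np.asarray(x)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 10:
        raise AssociationError("vectors must have equal length >= 10")
    if np.std(y) == 0:
        raise AssociationError("polyserial undefined: continuous variable is constant")
    cats, tau = _thresholds(x)
    if tau.size == 0:
        raise AssociationError("polyserial undefined: ordinal variable has a single category")
    z = (y - y.mean()) / y.std()
    ix = np.searchsorted(cats, x)
    lo_t = np.concatenate([[-30.0], tau])[ix]
    hi_t = np.concatenate([tau, [30.0]])[ix]

    def negloglik(rho: float) -> float:
        s = np.sqrt(max(1.0 - rho * rho, 1e-12))
        p = ndtr((hi_t - rho * z) / s) - ndtr((lo_t - rho * z) / s)
        return -float(np.sum(np.log(np.clip(p, 1e-300, None))))

    return _maximize(negloglik)


def nearest_psd_correlation(values: np.ndarray, eig_floor: float = 0.0):
    """Clip negative eigenvalues and rescale to unit diagonal.

    Returns (repaired matrix, was_repaired flag)."""
    values = (values + values.T) / 2.0
    w, v = np.linalg.eigh(values)
    if w.min() >= -1e-8:
        return values, False
    w = np.clip(w, eig_floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0, True


def association_matrix(cohort: CohortTable, include_anxiety_node: bool = False,
                       anxiety_method: str = "polyserial") -> AssociationMatrix:
    """Polychoric correlation matrix over the 10 MADRS items, optionally with
    an 11th anxiety node computed from the BAI sum (polyserial by default,
    Pearson if requested).

    Applies nearest-PSD repair (eigenvalue clipping + unit-diagonal
    rescaling) when needed, flagged in `psd_repaired`.
    """
    if cohort.n < 30:
        raise AssociationError("association_matrix needs >= 30 subjects")
    items = cohort.madrs_matrix()
    labels = list(MADRS_COLS)
    p = 10 + (1 if include_anxiety_node else 0)
    vals = np.eye(p)
    methods: dict = {}

    for i in range(10):
        for j in range(i + 1, 10):
            try:
                r = polychoric(items[:, i], items[:, j])
            except AssociationError as e:
                raise AssociationError(f"pair ({labels[i]}, {labels[j]}): {e}") from e
            vals[i, j] = vals[j, i] = r
            methods[(labels[i], labels[j])] = "polychoric"

    if include_anxiety_node:
        labels = labels + ["anxiety"]
        bai = cohort.df["bai_sum"].to_numpy(dtype=float)
        for i in range(10):
            try:
                if anxiety_method == "polyserial":
                    r = polyserial(items[:, i], bai)
                elif anxiety_method == "pearson":
                    r = float(np.corrcoef(items[:, i], bai)[0, 1])
                else:
                    raise AssociationError(f"unknown anxiety_method {anxiety_method!r}")
            except AssociationError as e:
                raise AssociationError(f"pair ({labels[i]}, anxiety): {e}") from e
            vals[i, 10] = vals[10, i] = r
            methods[(labels[i], "anxiety")] = anxiety_method

    repaired_vals, repaired = nearest_psd_correlation(vals)
    return AssociationMatrix(labels=labels, values=repaired_vals,
                             method_per_pair=methods, psd_repaired=repaired)
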