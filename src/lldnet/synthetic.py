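"""Synthetic ordinal symptom cohorts from a known sparse latent network.

The generative model is the latent-Gaussian threshold model that underlies
polychoric correlation: each subject has a 10-dimensional latent symptom
vector drawn from a multivariate normal whose precision matrix encodes a
sparse partial-correlation network, plus a scalar latent anxiety factor
that can (a) load on individual symptoms and (b) shift *all* symptoms per
unit anxiety (the severity-confounding knob).  Observed item scores arise
by thresholding the standardized latent values; the anxiety inventory sum
is generated from the same latent anxiety factor, so splitting a cohort at
the BAI cutoff recovers groups that differ in severity but — when only the
severity shift is active — share one partial-correlation structure.

Because the generator knows the truth, every downstream stage (association,
sparse network recovery, matching, permutation comparison) can be tested
against a gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .data_io import BAI_COLS, CLUSTER_TAGS, CohortTable, MADRS_COLS

import pandas as pd

PRESET_NAMES = ("baseline_lld", "confounded_anxiety", "null_two_group")

# Item-score targets used to place thresholds (means/SDs on the 0-6 scale,
# loosely matching a community sample of elderly depressed outpatients).
_ITEM_MEANS = np.array([2.64, 3.13, 2.69, 2.70, 1.95, 1.76, 2.01, 2.36, 2.29, 2.08])
_ITEM_SDS = np.array([1.39, 1.43, 1.34, 1.88, 2.04, 1.40, 1.55, 1.46, 1.35, 1.54])

# Sparse true partial correlations: three clusters
#   dysphoric apathy/retardation {m1,m2,m6,m7,m8},
#   psychic anxiety {m3,m9,m10}, vegetative {m4,m5},
# with the strongest edges inside clusters (apparent-reported sadness,
# concentration-lassitude, pessimism-suicidality) and one negative
# cross edge (reduced sleep - pessimistic thought).
_BASE_EDGES = {
    (0, 1): 0.40,   # apparent sadness - reported sadness
    (5, 6): 0.35,   # concentration - lassitude
    (8, 9): 0.45,   # pessimistic - suicidal
    (6, 7): 0.15,   # lassitude - inability to feel
    (0, 7): 0.15,   # apparent sadness - inability to feel
    (1, 5): 0.15,   # reported sadness - concentration
    (2, 8): 0.15,   # inner tension - pessimistic
    (2, 9): 0.30,   # inner tension - suicidal
    (3, 4): 0.30,   # reduced sleep - reduced appetite
    (3, 8): -0.15,  # reduced sleep - pessimistic (negative)
    (1, 8): 0.20,   # reported sadness - pessimistic (cross-cluster)
    (4, 6): 0.15,   # reduced appetite - lassitude (cross-cluster)
}


@dataclass
class GeneratorSpec:
    """Full description of a synthetic cohort's data-generating process.

    precision_matrix: 10x10 SPD precision of the latent symptoms (unit
        partial-correlation convention: the implied covariance is
        standardized to unit variances before use).
    item_thresholds: (10, 6) strictly increasing cut-points on the
        standardized marginal latent scale mapping to scores 0..6.
    anxiety_loading: per-item loading of the latent anxiety factor.
    severity_shift: mean shift of *every* latent symptom per unit latent
        anxiety — the severity-confounding knob; 0 plus zero loadings
        decouples the BAI from the MADRS items.
    bai_loading: loading of latent anxiety on each of the 21 BAI items
        (item-level generation), or on the BAI ranking latent when
        bai_rank_marginal is set.
    bai_thresholds: 3 cut-points mapping a unit-variance item latent
        to scores 0..3.
    bai_rank_marginal: optional fixed probability vector over BAI sums
        0..63; when present, per-subject BAI sums are assigned by mapping
        latent-anxiety ranks through this marginal (inverse-CDF coupling),
        which pins the size of the >= cutoff group deterministically.
    bai_noise_sd: SD of the noise added to latent anxiety in the ranking
        latent (controls the anxiety-BAI correlation).
    """

    n_subjects: int = 776
    precision_matrix: np.ndarray = None
    item_thresholds: np.ndarray = None
    anxiety_loading: np.ndarray = None
    severity_shift: float = 0.0
    bai_loading: float = 1.2
    bai_thresholds: np.ndarray = field(default_factory=lambda: np.array([0.4, 1.1, 1.9]))
    bai_rank_marginal: np.ndarray | None = None
    bai_noise_sd: float = 0.5
    age_mean: float = 73.87
    age_sd: float = 8.06
    age_anxiety_beta: float = 0.0
    female_prob: float = 0.72
    education_mean: float = 6.16
    education_sd: float = 4.52
    education_anxiety_beta: float = 0.0
    seed: int = 2019

    def __post_init__(self):
        if self.precision_matrix is None:
            self.precision_matrix = np.eye(10)
        self.precision_matrix = np.asarray(self.precision_matrix, dtype=float)
        if self.item_thresholds is None:
            self.item_thresholds = default_thresholds()
        self.item_thresholds = np.asarray(self.item_thresholds, dtype=float)
        if self.anxiety_loading is None:
            self.anxiety_loading = np.zeros(10)
        self.anxiety_loading = np.asarray(self.anxiety_loading, dtype=float)
        if np.any(np.diff(self.item_thresholds, axis=1) <= 0):
            raise ValueError("item_thresholds must be strictly increasing per item")
        eig = np.linalg.eigvalsh(self.precision_matrix)
        if eig.min() <= 0:
            raise ValueError(f"precision_matrix not positive definite (min eigenvalue {eig.min():.3g})")


@dataclass
class GoldStandard:
    """True quantities behind a generated cohort."""

    true_partial_correlations: np.ndarray
    true_anxiety_values: np.ndarray
    spec: GeneratorSpec

    @property
    def true_edges(self) -> np.ndarray:
        """Boolean upper-triangle adjacency of nonzero true partial correlations."""
        p = self.true_partial_correlations
        return np.abs(np.triu(p, 1)) > 1e-12


def default_thresholds(means=_ITEM_MEANS, sds=_ITEM_SDS) -> np.ndarray:
    """Cut-points (k + 0.5 - mean)/sd, k = 0..5: a discretized-normal item model."""
    k = np.arange(6)[None, :] + 0.5
    return (k - np.asarray(means)[:, None]) / np.asarray(sds)[:, None]


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """-K_ij / sqrt(K_ii K_jj), zero diagonal."""
    d = np.sqrt(np.diag(precision))
    p = -precision / np.outer(d, d)
    np.fill_diagonal(p, 0.0)
    return p


def _standardized_sigma(precision: np.ndarray) -> np.ndarray:
    """Inverse precision rescaled to unit variances (partial corrs unchanged)."""
    sigma = np.linalg.inv(precision)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def _bai_marginal(low_frac: float = 462.0 / 776.0, cutoff: int = 16) -> np.ndarray:
    """Discrete BAI-sum marginal: two truncated-normal lobes split exactly at
    the cutoff with mass `low_frac` below it (so rank coupling reproduces the
    group sizes deterministically at matching n)."""
    v = np.arange(64, dtype=float)
    low = np.where(v < cutoff, norm.pdf((v - 7.08) / 4.58), 0.0)
    high = np.where(v >= cutoff, norm.pdf((v - 27.15) / 9.30), 0.0)
    low = low / low.sum() * low_frac
    high = high / high.sum() * (1.0 - low_frac)
    return low + high


def generate_cohort(spec: GeneratorSpec, seed: int | None = None):
    """Draw a cohort from `spec`. Returns (CohortTable, GoldStandard).

    Deterministic given (spec, seed); seed defaults to spec.seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    sigma = _standardized_sigma(spec.precision_matrix)
    chol = np.linalg.cholesky(sigma)

    anx = rng.standard_normal(n)
    eps = rng.standard_normal((n, 10)) @ chol.T
    load = spec.anxiety_loading + spec.severity_shift
    z = eps + np.outer(anx, load)
    # thresholds live on the standardized marginal scale
    z = z / np.sqrt(1.0 + load**2)

    items = np.empty((n, 10), dtype=int)
    for j in range(10):
        items[:, j] = np.searchsorted(spec.item_thresholds[j], z[:, j])

    data = {"subject_id": [f"S{i:05d}" for i in range(n)]}
    for j, c in enumerate(MADRS_COLS):
        data[c] = items[:, j]

    bai_items = None
    if spec.bai_rank_marginal is not None:
        u = spec.bai_loading * anx + spec.bai_noise_sd * rng.standard_normal(n)
        ranks = np.argsort(np.argsort(u))
        q = (ranks + 0.5) / n
        cdf = np.cumsum(spec.bai_rank_marginal)
        bai_sum = np.searchsorted(cdf, q, side="left").astype(int)
    else:
        lam = spec.bai_loading
        y = lam * anx[:, None] + rng.standard_normal((n, 21))
        y = y / np.sqrt(1.0 + lam**2)
        bai_items = np.searchsorted(spec.bai_thresholds, y.ravel()).reshape(n, 21)
        bai_sum = bai_items.sum(axis=1)
    data["bai_sum"] = bai_sum
    if bai_items is not None:
        for j, c in enumerate(BAI_COLS):
            data[c] = bai_items[:, j]

    age = spec.age_mean + spec.age_anxiety_beta * anx + spec.age_sd * rng.standard_normal(n)
    data["age"] = np.clip(age, 60.0, 105.0).round(1)
    data["sex"] = np.where(rng.random(n) < spec.female_prob, "F", "M")
    edu = spec.education_mean + spec.education_anxiety_beta * anx + spec.education_sd * rng.standard_normal(n)
    data["education_years"] = np.clip(edu, 0.0, 22.0).round(1)
    data["flags"] = ""
    data["group"] = ""

    table = CohortTable(pd.DataFrame(data))
    gold = GoldStandard(
        true_partial_correlations=partial_correlations(spec.precision_matrix),
        true_anxiety_values=anx,
        spec=spec,
    )
    return table, gold


def _base_precision() -> np.ndarray:
    K = np.eye(10)
    for (i, j), w in _BASE_EDGES.items():
        K[i, j] = K[j, i] = -w
    return K


def preset_lld(spec_name: str) -> GeneratorSpec:
    """Named study-condition presets.

    baseline_lld: three-cluster sparse network, anxiety decoupled from the
        symptom items, BAI sums rank-coupled to an independent anxiety factor.
    confounded_anxiety: same network plus a severity shift (0.5 latent SD per
        unit anxiety), producing a large MADRS-sum gap between BAI groups
        while leaving the partial-correlation structure identical — the
        confound that matching must remove.
    null_two_group: alias conditions under which the two BAI groups are
        exchangeable draws from one network (anxiety fully decoupled).
    """
    if spec_name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {spec_name!r}; available: {PRESET_NAMES}")
    base = GeneratorSpec(
        n_subjects=776,
        precision_matrix=_base_precision(),
        bai_rank_marginal=_bai_marginal(),
        bai_loading=1.0,
        bai_noise_sd=0.5,
        age_anxiety_beta=-2.0,
        education_anxiety_beta=-0.3,
        seed=2019,
    )
    if spec_name == "baseline_lld":
        return base
    if spec_name == "null_two_group":
        return replace(base, age_anxiety_beta=0.0, education_anxiety_beta=0.0, seed=1137)
    # confounded_anxiety: severity shift only (no item-specific loadings),
    # so group networks share one structure by construction
    return replace(base, severity_shift=0.5, seed=848)


def cluster_tags_for(labels) -> dict:
    """Cluster metadata for network nodes (anxiety node tagged separately)."""
    return {lab: CLUSTER_TAGS.get(lab, "anxiety_node") for lab in labels}
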