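"""Alpha diversity (Hill numbers) and beta diversity.

Alpha diversity is expressed as Hill numbers — effective species counts
``D_q = (sum p_i^q)^(1/(1-q))`` — which put richness (q=0), exponential
Shannon entropy (q=1) and inverse Simpson concentration (q=2) on one common
scale.  Beta diversity follows the Hellinger -> Bray-Curtis -> PCoA /
PERMANOVA / ANOSIM route, with pairwise group contrasts adjusted by
Benjamini-Hochberg.

Permutation p-values use the add-one estimator
``p = (1 + #{permuted stat >= observed}) / (1 + n_perm)`` so that p is never
zero and is bounded below by ``1/(n_perm+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable, SampleMetadata, TableError


# ---------------------------------------------------------------------------
# alpha diversity


def hill_number(p: np.ndarray, q: float) -> float:
    """Hill number of order ``q`` for one composition.

    Zeros are excluded from the sums; ``q=1`` uses the entropy limit form
    ``exp(-sum p ln p)`` exactly rather than an epsilon approximation.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0 or not np.any(p > 0):
        raise ValueError("empty or all-zero composition")
    if (p < 0).any():
        raise ValueError("negative entries in composition")
    p = p[p > 0]
    p = p / p.sum()
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def hill_profile(t: FeatureTable, orders: Sequence[float] = (0, 1, 2)) -> pd.DataFrame:
    """Hill numbers per sample for each order; rows samples, columns q."""
    out = {}
    for s in t.sample_ids:
        col = t.data[s].to_numpy(dtype=float)
        out[s] = {q: hill_number(col, q) for q in orders}
    return pd.DataFrame(out).T.rename_axis("sample_id")


def alpha_contrasts(profile: pd.DataFrame, meta: SampleMetadata,
                    q: float) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests of one Hill order.

    Exact p-values where scipy supports them (no ties), normal
    approximation with tie correction otherwise.
    """
    if q not in profile.columns:
        raise ValueError(f"order {q} absent from profile")
    groups = [g for g in meta.groups if meta.samples_in(g)]
    for g in groups:
        if len(meta.samples_in(g)) < 2:
            raise ValueError(f"group {g} has <2 samples")
    rows = []
    for a, b in combinations(groups, 2):
        xa = profile.loc[[s for s in meta.samples_in(a) if s in profile.index], q]
        xb = profile.loc[[s for s in meta.samples_in(b) if s in profile.index], q]
        if np.array_equal(np.sort(xa), np.sort(xb)):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        rows.append({"group_a": a, "group_b": b, "q": q, "p": min(p, 1.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta diversity


def hellinger(t: FeatureTable) -> FeatureTable:
    """Hellinger transform: entry -> sqrt(count / sample total)."""
    depths = t.depths()
    zero = depths.index[depths <= 0].tolist()
    if zero:
        raise TableError(f"zero-total samples: {zero[:5]}")
    out = np.sqrt(t.data.div(depths, axis=1))
    ft = FeatureTable.__new__(FeatureTable)
    ft.data = out
    ft.is_relative = False
    return ft


@dataclass
class DistanceMatrix:
    """Symmetric sample dissimilarity matrix with a zero diagonal."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.sample_ids):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        self.matrix = m

    def submatrix(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.matrix[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids,
                            columns=self.sample_ids)


def bray_curtis(t: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)`` between samples."""
    x = t.data.to_numpy(dtype=float).T  # samples x taxa
    sums = x.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size >= 2:
        names = [t.sample_ids[i] for i in zero]
        raise TableError(f"Bray-Curtis undefined for all-zero sample pair: {names}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(t.sample_ids), d)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray      # samples x k
    eigenvalues: np.ndarray      # all eigenvalues, non-increasing (incl. negative)
    proportion_explained: np.ndarray  # relative to sum of positive eigenvalues


def pcoa(d: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical metric scaling of a dissimilarity matrix.

    Eigenvalues of the double-centred -D^2/2 matrix are reported in full,
    negative ones included; coordinates use the top ``k`` positive axes.
    """
    n = len(d.sample_ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    a = -0.5 * d.matrix ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    if k > int(pos.sum()):
        raise ValueError(f"k={k} exceeds the number of positive axes ({pos.sum()})")
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    prop = np.where(pos, vals / vals[pos].sum(), 0.0)
    return OrdinationResult(list(d.sample_ids), coords, vals, prop)


# ---------------------------------------------------------------------------
# group tests on distance matrices


def _group_masks(labels: np.ndarray) -> list[np.ndarray]:
    return [labels == g for g in pd.unique(labels)]


def _permanova_stat(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R^2) from squared distances and group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    n_groups = 0
    for mask in _group_masks(labels):
        ng = int(mask.sum())
        n_groups += 1
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        if ss_between <= 0:
            return 0.0, 0.0
        return np.inf, 1.0
    f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def permanova(d: DistanceMatrix, labels: Sequence[str], n_perm: int = 999,
              seed: int = 0) -> dict:
    """One-way PERMANOVA on a distance matrix.

    Returns R^2, pseudo-F and the add-one permutation p-value.  Degenerate
    all-zero distance matrices report R^2 = 0 with ``degenerate=True``.
    """
    labels = np.asarray(labels)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >=2 groups with >=2 samples each")
    d2 = d.matrix ** 2
    if not d2.any():
        return {"R2": 0.0, "F": 0.0, "p": 1.0, "n_perm": n_perm,
                "degenerate": True}
    f_obs, r2 = _permanova_stat(d2, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_stat(d2, rng.permutation(labels))
        if f_perm >= f_obs:
            exceed += 1
    return {"R2": r2, "F": f_obs, "p": (1 + exceed) / (1 + n_perm),
            "n_perm": n_perm, "degenerate": False}


def _anosim_stat(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    n = rank_matrix.shape[0]
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, 1)
    within = rank_matrix[iu][same[iu]]
    between = rank_matrix[iu][~same[iu]]
    m = n * (n - 1) / 2
    return float((between.mean() - within.mean()) / (m / 2))


def anosim(d: DistanceMatrix, labels: Sequence[str], n_perm: int = 999,
           seed: int = 0) -> dict:
    """ANOSIM R statistic with an add-one permutation p-value."""
    labels = np.asarray(labels)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >=2 groups with >=2 samples each")
    n = d.matrix.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(d.matrix[iu])
    rank_matrix = np.zeros_like(d.matrix)
    rank_matrix[iu] = ranks
    rank_matrix = rank_matrix + rank_matrix.T
    r_obs = _anosim_stat(rank_matrix, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if _anosim_stat(rank_matrix, rng.permutation(labels)) >= r_obs:
            exceed += 1
    return {"R": r_obs, "p": (1 + exceed) / (1 + n_perm), "n_perm": n_perm}


def pairwise_beta(d: DistanceMatrix, meta: SampleMetadata,
                  statistic_kind: str = "permanova_R2", n_perm: int = 999,
                  seed: int = 0, pairs: Sequence[tuple[str, str]] | None = None,
                  ) -> pd.DataFrame:
    """Pairwise group contrasts on sub-distance-matrices, BH-adjusted.

    ``pairs`` restricts the family of comparisons (default: every unordered
    group pair present in the metadata).  Distances between two samples do
    not depend on other samples, so sub-matrices are sliced, not recomputed.
    """
    if statistic_kind not in ("permanova_R2", "anosim_R"):
        raise ValueError(f"unknown statistic_kind {statistic_kind!r}")
    groups = [g for g in meta.groups if meta.samples_in(g)]
    if pairs is None:
        pairs = list(combinations(groups, 2))
    rows = []
    for i, (a, b) in enumerate(pairs):
        samples = meta.samples_in(a) + meta.samples_in(b)
        samples = [s for s in samples if s in d.sample_ids]
        labels = meta.labels_for(samples)
        sub = d.submatrix(samples)
        if statistic_kind == "permanova_R2":
            res = permanova(sub, labels, n_perm=n_perm, seed=seed + i)
            stat, p = res["R2"], res["p"]
        else:
            res = anosim(sub, labels, n_perm=n_perm, seed=seed + i)
            stat, p = res["R"], res["p"]
        rows.append({"comparison": f"{a} vs {b}", "statistic_kind": statistic_kind,
                     "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
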