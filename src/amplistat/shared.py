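"""Shared-species counts between sample groups and their permutation null.

The observed statistic is the number of taxa detected (>= 1 read) in at
least one sample of each of two groups.  The null ("A2") reshuffles
sample-to-group labels at fixed group sizes and recomputes the shared
count; an optional second stage additionally reallocates each pseudo-
group's reads across its samples by multinomial resampling at fixed sample
depths, which perturbs presence patterns within groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tables import FeatureTable


@dataclass
class SharedSpeciesResult:
    group_a: str
    group_b: str
    observed: int
    null_mean: float
    null_sd: float
    p: float
    n_perm: int
    seed: int
    null_kind: str  # "A2-labels" or "A2-reads"


def shared_observed(t: FeatureTable, samples_a, samples_b) -> int:
    """Count taxa present (>=1 read in >=1 sample) in both groups."""
    samples_a, samples_b = list(samples_a), list(samples_b)
    overlap = set(samples_a) & set(samples_b)
    if overlap:
        raise ValueError(f"sample sets overlap: {sorted(overlap)[:5]}")
    pres_a = (t.data[samples_a].to_numpy() >= 1).any(axis=1)
    pres_b = (t.data[samples_b].to_numpy() >= 1).any(axis=1)
    return int(np.sum(pres_a & pres_b))


def shared_taxa(t: FeatureTable, samples_a, samples_b) -> list[str]:
    """Identifiers of the taxa shared between the two groups."""
    pres_a = (t.data[list(samples_a)].to_numpy() >= 1).any(axis=1)
    pres_b = (t.data[list(samples_b)].to_numpy() >= 1).any(axis=1)
    return [tid for tid, keep in zip(t.taxon_ids, pres_a & pres_b) if keep]


def _shared_from_presence(presence: np.ndarray, idx_a: np.ndarray,
                          idx_b: np.ndarray) -> int:
    return int(np.sum(presence[:, idx_a].any(axis=1)
                      & presence[:, idx_b].any(axis=1)))


def a2_null(t: FeatureTable, samples_a, samples_b, n_perm: int = 1000,
            seed: int = 0, permute_reads: bool = False,
            group_a: str = "A", group_b: str = "B") -> SharedSpeciesResult:
    """Permutation null for the shared-species count of two groups.

    ``permute_reads=False`` (A2-labels) only reshuffles sample labels.
    ``permute_reads=True`` (A2-reads) additionally redistributes each
    pseudo-group's pooled reads over its samples by multinomial draws at
    the original sample depths before recomputing presence.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need >=2 samples")
    if set(samples_a) & set(samples_b):
        raise ValueError("sample sets overlap")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: null SD estimate unstable")
    observed = shared_observed(t, samples_a, samples_b)
    pool = samples_a + samples_b
    counts = t.data[pool].to_numpy(dtype=float)
    presence = counts >= 1
    n_a = len(samples_a)
    n = len(pool)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        idx_a, idx_b = perm[:n_a], perm[n_a:]
        if not permute_reads:
            null[i] = _shared_from_presence(presence, idx_a, idx_b)
            continue
        shared = 0
        pres_sides = []
        for idx in (idx_a, idx_b):
            sub = counts[:, idx]
            pooled = sub.sum(axis=1)
            total = pooled.sum()
            probs = pooled / total
            depths = sub.sum(axis=0).astype(int)
            resampled_presence = np.zeros(sub.shape[0], dtype=bool)
            for d in depths:
                draw = rng.multinomial(d, probs)
                resampled_presence |= draw >= 1
            pres_sides.append(resampled_presence)
        shared = int(np.sum(pres_sides[0] & pres_sides[1]))
        null[i] = shared
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    exceed = int(np.sum(np.abs(null - mu) >= abs(observed - mu) - 1e-12))
    p = (1 + exceed) / (1 + n_perm)
    return SharedSpeciesResult(
        group_a=group_a, group_b=group_b, observed=observed, null_mean=mu,
        null_sd=sd, p=p, n_perm=n_perm, seed=seed,
        null_kind="A2-reads" if permute_reads else "A2-labels")
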