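"""Community spatial heterogeneity via Type-I Taylor's power law extension.

For each sample, the mean M and variance V of per-taxon abundances are
computed across the taxa detected in that sample; across the samples of a
group, ``ln V = ln a + b ln M`` is fitted by ordinary least squares.  The
slope ``b`` indexes aggregation: larger values mean greater spatial
heterogeneity of the community.  Groups are contrasted by permuting sample
-to-group assignments and recomputing |Δb| (and |Δ ln a|).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class TPLEFit:
    group: str
    b: float        # slope: heterogeneity exponent
    ln_a: float     # intercept
    R: float        # Pearson r of the log-log fit
    p: float        # two-sided p of the correlation test
    n: int          # number of (M, V) points
    include_zeros: bool = False
    variance_ddof: int = 1

    def to_dict(self) -> dict:
        return {"group": self.group, "b": self.b, "ln_a": self.ln_a,
                "R": self.R, "p": self.p, "n": self.n,
                "include_zeros": self.include_zeros,
                "variance_ddof": self.variance_ddof}


@dataclass
class TPLEContrast:
    group_a: str
    group_b: str
    delta_b: float          # observed |b_A - b_B|
    delta_ln_a: float
    p_b: float
    p_ln_a: float
    n_perm: int
    seed: int


def tple_points(t: FeatureTable, samples=None, include_zeros: bool = False,
                ddof: int = 1) -> pd.DataFrame:
    """Per-sample (M, V): mean and variance of abundances across taxa.

    By default only taxa detected (count > 0) in the sample enter the mean
    and variance; ``include_zeros=True`` uses every row of the table.
    Degenerate points (M = 0 or V = 0) are excluded with a warning.
    """
    ids = list(t.sample_ids) if samples is None else list(samples)
    rows = []
    for s in ids:
        x = t.data[s].to_numpy(dtype=float)
        if not include_zeros:
            x = x[x > 0]
        if x.size < 2:
            warnings.warn(f"sample {s}: fewer than 2 usable taxa, excluded")
            continue
        m = float(x.mean())
        v = float(x.var(ddof=ddof))
        if m <= 0 or v <= 0:
            warnings.warn(f"sample {s}: degenerate point (M={m}, V={v}), excluded")
            continue
        rows.append({"sample_id": s, "M": m, "V": v})
    if len(rows) < 3:
        raise ValueError(f"fewer than 3 usable (M, V) points ({len(rows)})")
    return pd.DataFrame(rows).set_index("sample_id")


def tple_fit(points: pd.DataFrame, group: str = "", include_zeros: bool = False,
             ddof: int = 1) -> TPLEFit:
    """OLS of ln V on ln M; slope is the heterogeneity exponent b."""
    if len(points) < 3:
        raise ValueError("need >=3 points")
    ln_m = np.log(points["M"].to_numpy(dtype=float))
    ln_v = np.log(points["V"].to_numpy(dtype=float))
    if np.ptp(ln_m) < 1e-12:
        raise ValueError("all M equal: log-log regression degenerate")
    res = stats.linregress(ln_m, ln_v)
    return TPLEFit(group=group, b=float(res.slope), ln_a=float(res.intercept),
                   R=float(res.rvalue), p=float(res.pvalue), n=len(points),
                   include_zeros=include_zeros, variance_ddof=ddof)


def fit_group(t: FeatureTable, samples, group: str = "",
              include_zeros: bool = False, ddof: int = 1) -> TPLEFit:
    pts = tple_points(t, samples, include_zeros=include_zeros, ddof=ddof)
    return tple_fit(pts, group=group, include_zeros=include_zeros, ddof=ddof)


def tple_compare(t: FeatureTable, samples_a, samples_b, n_perm: int = 999,
                 seed: int = 0, include_zeros: bool = False,
                 group_a: str = "A", group_b: str = "B") -> TPLEContrast:
    """Permutation contrast of TPLE parameters between two sample groups.

    The null pools the two groups' samples and reassigns membership at the
    original sizes; p is the add-one proportion of permuted |Δ| >= observed.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    pts = tple_points(t, samples_a + samples_b, include_zeros=include_zeros)
    n_a = sum(1 for s in samples_a if s in pts.index)
    avail = list(pts.index)
    n_distinct = comb(len(avail), n_a)
    if n_distinct < n_perm:
        warnings.warn(
            f"only {n_distinct} distinct reassignments possible (< {n_perm})")

    def delta(idx_a: np.ndarray) -> tuple[float, float]:
        mask = np.zeros(len(avail), dtype=bool)
        mask[idx_a] = True
        fa = tple_fit(pts.iloc[mask])
        fb = tple_fit(pts.iloc[~mask])
        return abs(fa.b - fb.b), abs(fa.ln_a - fb.ln_a)

    obs_idx = np.array([avail.index(s) for s in samples_a if s in pts.index])
    obs_b, obs_ln_a = delta(obs_idx)
    rng = np.random.default_rng(seed)
    exceed_b = exceed_a = 0
    for _ in range(n_perm):
        idx = rng.choice(len(avail), size=n_a, replace=False)
        db, da = delta(idx)
        if db >= obs_b - 1e-12:
            exceed_b += 1
        if da >= obs_ln_a - 1e-12:
            exceed_a += 1
    return TPLEContrast(group_a=group_a, group_b=group_b, delta_b=obs_b,
                        delta_ln_a=obs_ln_a, p_b=(1 + exceed_b) / (1 + n_perm),
                        p_ln_a=(1 + exceed_a) / (1 + n_perm),
                        n_perm=n_perm, seed=seed)


def compact_letters(groups, significant: dict[frozenset, bool]) -> dict[str, str]:
    """Compact letter display over a pairwise significance map.

    Groups sharing a letter are not significantly different.  Uses the
    insert-and-absorb algorithm: start from one set holding all groups,
    split any set containing a significantly different pair, then drop sets
    contained in others.  Letters are assigned a, b, c, ... in group order.
    """
    groups = list(groups)
    sets: list[set] = [set(groups)]
    for a, b in combinations(groups, 2):
        if not significant.get(frozenset((a, b)), False):
            continue
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    # stable ordering: by first member's position in `groups`
    sets.sort(key=lambda s: min(groups.index(g) for g in s))
    letters = {g: "" for g in groups}
    for i, s in enumerate(sets):
        ch = chr(ord("a") + i)
        for g in groups:
            if g in s:
                letters[g] += ch
    return letters


def fit_all_groups(t: FeatureTable, meta, include_zeros: bool = False,
                   ddof: int = 1) -> pd.DataFrame:
    """TPLE fits for every metadata group present in the table."""
    rows = []
    for g in meta.groups:
        samples = [s for s in meta.samples_in(g) if s in t.sample_ids]
        if len(samples) < 3:
            logger.info("group %s skipped for TPLE (n=%d < 3)", g, len(samples))
            continue
        rows.append(fit_group(t, samples, group=g, include_zeros=include_zeros,
                              ddof=ddof).to_dict())
    return pd.DataFrame(rows)
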