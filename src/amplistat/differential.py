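"""Effect-size biomarker screening and marker ROC analysis.

The screen follows the LEfSe recipe: a Kruskal-Wallis rank-sum test per
taxon across all groups, a pairwise Wilcoxon consistency check in
one-against-all mode, then a bootstrapped two-class linear discriminant
whose per-feature effect is converted to a log10 score; taxa with score >=
3.0 (and a significant KW test) are called biomarkers.  Numeric parity
with the original LEfSe program is not claimed; recovery of planted
differential taxa is the contract.

ROC analysis scores single markers (a taxon's relative abundance, or the
summed abundance of a species list) and two-marker combinations via a
weakly regularised logistic discriminant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .tables import FeatureTable, SampleMetadata


@dataclass
class EffectSizeRecord:
    taxon: str
    enriched_group: str
    kw_p: float
    lda_score: float
    passes_threshold: bool


@dataclass
class RocResult:
    marker: str
    scores: pd.Series          # per-sample score
    labels: pd.Series          # binary label per sample (1 = positive class)
    auc: float
    curve: pd.DataFrame        # fpr, tpr, threshold
    group_pair: tuple[str, str] = ("", "")
    separable: bool = False    # perfect separation flag (combined markers)


# ---------------------------------------------------------------------------
# Kruskal-Wallis screen


def kw_screen(t: FeatureTable, meta: SampleMetadata, alpha: float = 0.05,
              check_consistency: bool = True) -> pd.DataFrame:
    """Per-taxon Kruskal-Wallis test across all groups (tie-corrected).

    A taxon passes when the KW p is below ``alpha`` and, with >2 groups,
    the group with the highest mean abundance beats every other group in
    pairwise direction (one-against-all consistency).  Constant taxa get
    p = 1 and fail.
    """
    if not t.is_relative:
        raise ValueError("kw_screen expects a relative-abundance table")
    groups = [g for g in meta.groups if meta.samples_in(g)]
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    sample_sets = {g: [s for s in meta.samples_in(g) if s in t.sample_ids]
                   for g in groups}
    rows = []
    for taxon in t.taxon_ids:
        per_group = [t.data.loc[taxon, sample_sets[g]].to_numpy(dtype=float)
                     for g in groups]
        flat = np.concatenate(per_group)
        if np.ptp(flat) == 0:
            rows.append({"taxon": taxon, "kw_p": 1.0, "enriched_group": groups[0],
                         "passes": False, "constant": True})
            continue
        if len(per_group) == 2:
            # two-group KW reduces to the rank-sum test; use the exact
            # distribution where scipy supports it (small n, no ties)
            p = float(stats.mannwhitneyu(per_group[0], per_group[1],
                                         alternative="two-sided").pvalue)
        else:
            p = float(stats.kruskal(*per_group).pvalue)
        means = [g.mean() for g in per_group]
        top = int(np.argmax(means))
        consistent = True
        if check_consistency and len(groups) > 2 and p < alpha:
            for j, other in enumerate(per_group):
                if j == top:
                    continue
                # direction: top group's values must tend larger
                u = stats.mannwhitneyu(per_group[top], other,
                                       alternative="two-sided")
                greater = u.statistic > len(per_group[top]) * len(other) / 2
                if not greater:
                    consistent = False
                    break
        rows.append({"taxon": taxon, "kw_p": p, "enriched_group": groups[top],
                     "passes": bool(p < alpha and consistent),
                     "constant": False})
    return pd.DataFrame(rows).set_index("taxon")


# ---------------------------------------------------------------------------
# LDA effect size


def _two_class_lda_direction(x: np.ndarray, y: np.ndarray,
                             shrink: float = 0.1) -> np.ndarray:
    """Fisher discriminant direction with diagonal-shrunk pooled covariance."""
    mu1 = x[y == 1].mean(axis=0)
    mu0 = x[y == 0].mean(axis=0)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    c1 = np.cov(x[y == 1], rowvar=False, ddof=1) if n1 > 1 else np.zeros((x.shape[1],) * 2)
    c0 = np.cov(x[y == 0], rowvar=False, ddof=1) if n0 > 1 else np.zeros((x.shape[1],) * 2)
    pooled = ((n1 - 1) * np.atleast_2d(c1) + (n0 - 1) * np.atleast_2d(c0)) / max(n1 + n0 - 2, 1)
    diag = np.diag(np.diag(pooled))
    cov = (1 - shrink) * pooled + shrink * diag
    cov = cov + 1e-8 * np.trace(cov) / max(x.shape[1], 1) * np.eye(x.shape[1]) + 1e-12 * np.eye(x.shape[1])
    w = np.linalg.solve(cov, mu1 - mu0)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lda_effect_size(t: FeatureTable, meta: SampleMetadata,
                    taxa=None, n_boot: int = 30,
                    subsample_fraction: float = 2 / 3, seed: int = 0,
                    alpha: float = 0.05, lda_threshold: float = 3.0,
                    shrink: float = 0.1) -> list[EffectSizeRecord]:
    """LEfSe-style LDA effect sizes for taxa passing the KW screen.

    Per taxon: abundances scaled to 1e6 per sample; the enriched group is
    split against the rest; over ``n_boot`` bootstraps of
    ``ceil(fraction*n)`` samples per class a regularised two-class LDA is
    fitted, and the per-feature effect is the mean of
    ``0.5*(|raw class-mean difference| + |discriminant-projected class-mean
    difference|)``; the score is ``log10(1 + effect)``.
    """
    screen = kw_screen(t, meta, alpha=alpha)
    if taxa is None:
        taxa = list(screen.index[screen["passes"]])
    if not taxa:
        return []
    groups = [g for g in meta.groups if meta.samples_in(g)]
    sample_ids = [s for s in t.sample_ids
                  if any(s in meta.samples_in(g) for g in groups)]
    x_all = t.data[sample_ids].to_numpy(dtype=float).T  # samples x taxa
    x_all = x_all / x_all.sum(axis=1, keepdims=True) * 1e6
    taxon_idx = {tid: i for i, tid in enumerate(t.taxon_ids)}
    cols = [taxon_idx[tid] for tid in taxa]
    x_feat = x_all[:, cols]  # samples x screened taxa
    labels = np.asarray(meta.labels_for(sample_ids))
    rng = np.random.default_rng(seed)
    records: list[EffectSizeRecord] = []
    # one discriminant fit per enriched-vs-rest split, jointly over features
    by_group: dict[str, list[int]] = {}
    for j, taxon in enumerate(taxa):
        by_group.setdefault(str(screen.at[taxon, "enriched_group"]), []).append(j)
    for enriched, feat_js in by_group.items():
        y = (labels == enriched).astype(int)
        boots = []
        for _ in range(n_boot):
            boot_idx = []
            ok = True
            for cls in (0, 1):
                members = np.flatnonzero(y == cls)
                k = max(int(np.ceil(subsample_fraction * members.size)), 1)
                pick = rng.choice(members, size=k, replace=False)
                if pick.size < min(3, members.size):
                    ok = False
                boot_idx.append(pick)
            if not ok:
                continue
            idx = np.concatenate(boot_idx)
            xb, yb = x_feat[idx], y[idx]
            mu1 = xb[yb == 1].mean(axis=0)
            mu0 = xb[yb == 0].mean(axis=0)
            raw = np.abs(mu1 - mu0)
            if np.ptp(xb) == 0:
                boots.append(np.zeros(len(taxa)))
                continue
            w = _two_class_lda_direction(xb, yb, shrink=shrink)
            proj_gap = float(w @ (mu1 - mu0))
            projected = np.abs(w * proj_gap)
            boots.append(0.5 * (raw + projected))
        if not boots:
            warnings.warn(f"split {enriched}: no valid bootstrap, taxa skipped")
            continue
        mean_effect = np.mean(boots, axis=0)
        for j in feat_js:
            taxon = taxa[j]
            score = float(np.log10(1.0 + mean_effect[j]))
            kw_p = float(screen.at[taxon, "kw_p"])
            records.append(EffectSizeRecord(
                taxon=taxon, enriched_group=enriched, kw_p=kw_p,
                lda_score=score,
                passes_threshold=bool(kw_p < alpha and score >= lda_threshold)))
    records.sort(key=lambda r: -r.lda_score)
    return records


def effect_size_frame(records: list[EffectSizeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# ROC


def roc_auc(scores: pd.Series, labels: pd.Series, marker: str = "",
            group_pair: tuple[str, str] = ("", "")) -> RocResult:
    """AUC as the Mann-Whitney U probability (ties count 1/2), plus curve."""
    scores = pd.Series(scores).astype(float)
    labels = pd.Series(labels).astype(int)
    pos = scores[labels == 1].to_numpy()
    neg = scores[labels == 0].to_numpy()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = float((greater + 0.5 * ties) / (pos.size * neg.size))
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    fpr = [(neg >= th).mean() for th in thresholds]
    tpr = [(pos >= th).mean() for th in thresholds]
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return RocResult(marker=marker, scores=scores, labels=labels, auc=auc,
                     curve=curve, group_pair=group_pair)


def marker_scores(t: FeatureTable, species: list[str],
                  name: str = "marker") -> pd.Series:
    """Per-sample summed relative abundance of a species list."""
    rel = t.data if t.is_relative else t.data.div(t.data.sum(axis=0), axis=1)
    present = [s for s in species if s in rel.index]
    return rel.loc[present].sum(axis=0).rename(name)


def _logistic_fit(x: np.ndarray, y: np.ndarray, ridge: float = 1e-6,
                  tol: float = 1e-8) -> np.ndarray:
    """Ridge-regularised logistic regression; strictly convex, deterministic."""
    n, d = x.shape
    xd = np.hstack([np.ones((n, 1)), x])

    def loss(beta):
        z = xd @ beta
        # log(1+exp(-yz)) with y in {-1, +1}
        ys = 2 * y - 1
        m = -ys * z
        val = np.logaddexp(0, m).sum() / n + 0.5 * ridge * beta[1:] @ beta[1:]
        p = 1 / (1 + np.exp(-z))
        grad = xd.T @ (p - y) / n
        grad[1:] += ridge * beta[1:]
        return val, grad

    res = minimize(loss, np.zeros(d + 1), jac=True, method="L-BFGS-B",
                   tol=tol, options={"maxiter": 2000})
    return res.x


def combine_markers(scores_a: pd.Series, scores_b: pd.Series,
                    labels: pd.Series, marker: str = "combined",
                    group_pair: tuple[str, str] = ("", "")) -> RocResult:
    """Two-marker combination by a logistic discriminant.

    Features are standardised and combined by a weakly ridge-regularised
    logistic fit (deterministic, tolerance 1e-8).  Under perfect
    separation the ridge solution concentrates weight on the separating
    feature; the result is flagged ``separable``.
    """
    idx = scores_a.index
    y = pd.Series(labels).loc[idx].astype(int).to_numpy()
    x = np.column_stack([scores_a.to_numpy(dtype=float),
                         pd.Series(scores_b).loc[idx].to_numpy(dtype=float)])
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    xz = (x - x.mean(axis=0)) / sd
    beta = _logistic_fit(xz, y)
    combined = pd.Series(xz @ beta[1:], index=idx, name=marker)
    res = roc_auc(combined, pd.Series(y, index=idx), marker=marker,
                  group_pair=group_pair)
    # separation check on the fitted direction
    pos = combined[y == 1]
    neg = combined[y == 0]
    res.separable = bool(pos.min() > neg.max() or neg.min() > pos.max())
    return res
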