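"""Clinical-table statistics: Fisher's exact test for r x c tables,
one-way ANOVA from raw vectors or printed summaries, and a cohort
characteristics report.

The r x c exact test is the Freeman-Halton generalisation: with margins
fixed, the two-sided p-value sums the multivariate hypergeometric
probabilities of every table no more probable than the observed one
(within a small slack for floating-point ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .tables import SampleMetadata

_SLACK = 1e-12


def _log_fact(n: int) -> float:
    return lgamma(n + 1)


def _log_table_prob(tab: np.ndarray, log_denominator: float,
                    row_margins: np.ndarray, col_margins: np.ndarray) -> float:
    lp = sum(_log_fact(int(m)) for m in row_margins)
    lp += sum(_log_fact(int(m)) for m in col_margins)
    lp -= log_denominator
    lp -= sum(_log_fact(int(x)) for x in tab.ravel())
    return lp


def fisher_exact_rc(table) -> float:
    """Two-sided Freeman-Halton exact p for an r x c contingency table.

    Enumerates every table with the observed margins; feasible for the
    small cohort tables this targets (total count <= 1e4 and few cells).
    Degenerate tables (a zero row/column margin) return p = 1.
    """
    tab = np.asarray(table, dtype=int)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (tab < 0).any():
        raise ValueError("negative cell counts")
    n = int(tab.sum())
    if n > 10_000:
        raise ValueError("table total too large for exact enumeration")
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        warnings.warn("zero margin: degenerate table, p = 1")
        return 1.0
    log_den = _log_fact(n)
    lp_obs = _log_table_prob(tab, log_den, rows, cols)

    r, c = tab.shape
    p_total = 0.0

    # Recursive enumeration over rows of compositions matching column margins.
    def recurse(row_idx: int, remaining_cols: np.ndarray, lp_acc: float) -> None:
        nonlocal p_total
        if row_idx == r - 1:
            # last row forced
            last = remaining_cols
            lp = lp_acc - sum(_log_fact(int(x)) for x in last)
            if lp <= lp_obs + _SLACK:
                p_total += np.exp(lp)
            return
        target = int(rows[row_idx])

        def fill(col_idx: int, left: int, row_cells: list[int]) -> None:
            if col_idx == c - 1:
                if left <= remaining_cols[col_idx]:
                    cells = row_cells + [left]
                    lp_row = -sum(_log_fact(x) for x in cells)
                    recurse(row_idx + 1,
                            remaining_cols - np.array(cells), lp_acc + lp_row)
                return
            for x in range(min(left, int(remaining_cols[col_idx])) + 1):
                fill(col_idx + 1, left - x, row_cells + [x])

        fill(0, target, [])

    base = (sum(_log_fact(int(m)) for m in rows)
            + sum(_log_fact(int(m)) for m in cols) - log_den)
    recurse(0, cols.copy(), base)
    return float(min(p_total, 1.0))


@dataclass
class GroupSummary:
    """Continuous covariate summary for one group: n, mean, sd."""
    n: int
    mean: float
    sd: float


def anova_oneway(groups) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA from raw vectors or :class:`GroupSummary` objects.

    Summary mode reconstructs SSB from group means/sizes and SSW from
    ``(n_i - 1) sd_i^2``; the two modes agree exactly on consistent input.
    Returns (F, (df_between, df_within), p).
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    if all(isinstance(g, GroupSummary) for g in groups):
        ns = np.array([g.n for g in groups], dtype=float)
        means = np.array([g.mean for g in groups], dtype=float)
        sds = np.array([g.sd for g in groups], dtype=float)
        if (ns < 2).any():
            raise ValueError("summary mode needs n >= 2 per group")
    else:
        arrs = [np.asarray(g, dtype=float) for g in groups]
        ns = np.array([a.size for a in arrs], dtype=float)
        means = np.array([a.mean() for a in arrs])
        sds = np.array([a.std(ddof=1) for a in arrs])
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds ** 2).sum())
    df_b = len(groups) - 1
    df_w = int(n_total) - len(groups)
    if ssw <= 0:
        if ssb <= 0:
            return 0.0, (df_b, df_w), 1.0
        return float("inf"), (df_b, df_w), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    if f == 0:
        return 0.0, (df_b, df_w), 1.0
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), (df_b, df_w), p


def summary_table(meta: SampleMetadata, covariates: list[str] | None = None,
                  groups: list[str] | None = None) -> pd.DataFrame:
    """Cohort characteristics report: one row per covariate.

    Binary/categorical covariates are shown as ``count (pct%)`` per group
    with a Freeman-Halton Fisher p; numeric covariates as ``mean (sd)``
    with a one-way ANOVA p.  An overall column pools all groups.
    """
    if groups is None:
        groups = [g for g in meta.groups if meta.samples_in(g)]
    if covariates is None:
        covariates = meta.covariates
    sub = meta.table[meta.table["group"].isin(groups)]
    rows = []
    for cov in covariates:
        if cov not in meta.table.columns:
            raise ValueError(f"covariate {cov!r} missing from metadata")
        series = sub[cov]
        row: dict = {"characteristic": cov}
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
            row["ALL"] = f"{series.mean():.1f} ({series.std(ddof=1):.3g})"
            summaries = []
            for g in groups:
                vals = sub.loc[sub["group"] == g, cov].astype(float)
                row[g] = f"{vals.mean():.1f} ({vals.std(ddof=1):.3g})"
                summaries.append(GroupSummary(len(vals), float(vals.mean()),
                                              float(vals.std(ddof=1))))
            _, _, p = anova_oneway(summaries)
            row["test"] = "anova"
        else:
            yes_value = 1 if pd.api.types.is_numeric_dtype(series) else "yes"
            n_all = len(series)
            yes_all = int((series == yes_value).sum())
            row["ALL"] = f"{yes_all} ({100 * yes_all / n_all:.1f}%)"
            tab = []
            for g in groups:
                vals = sub.loc[sub["group"] == g, cov]
                yes = int((vals == yes_value).sum())
                row[g] = f"{yes} ({100 * yes / len(vals):.2f}%)" if len(vals) \
                    else "0 (0.00%)"
                tab.append([yes, len(vals) - yes])
            contingency = np.array(tab).T  # 2 x n_groups: yes/no by group
            if contingency.sum(axis=1).min() == 0:
                p = 1.0
            else:
                p = fisher_exact_rc(contingency)
            row["test"] = "fisher"
        row["p"] = round(p, 3)
        row["p_full"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("characteristic")
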