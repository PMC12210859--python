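"""Compositional co-occurrence networks.

SparCC estimates taxon-taxon correlations from count data without the
spurious negative bias that naive correlations on proportions suffer.  Per
iteration, fractions are drawn by Dirichlet smoothing of the counts
(pseudocount 1), the log-ratio variance matrix ``t_ij = Var(ln(x_i/x_j))``
is computed, and basis variances ``w`` are solved from the sparsity
approximation ``sum_j t_ij ~ d_i w_i + sum_{j in inc(i)} w_j``; correlations
follow as ``rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j))``.  Strongly
correlated pairs are iteratively excluded from the system and it is
re-solved; the final estimate is the median over iterations.

Edges surviving a BH false-discovery filter (q < 0.05 by default, p from a
per-taxon column-permutation null) and a magnitude filter (|rho| > 0.4,
strict) form the network; dense cores come from an MCODE-style heuristic,
the backbone is the maximum spanning forest on |rho|, and the functional-
group procedure intersects edges across the healthy and dysplasia networks
before confirming membership in the carcinoma network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    taxon_ids: list[str]
    rho: np.ndarray
    p: np.ndarray | None = None
    q: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        if not np.allclose(r, r.T, atol=1e-9):
            raise ValueError("correlation matrix not symmetric")
        self.rho = np.clip((r + r.T) / 2, -1.0, 1.0)
        np.fill_diagonal(self.rho, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.taxon_ids,
                            columns=self.taxon_ids)


# ---------------------------------------------------------------------------
# SparCC


def _logratio_variance(frac: np.ndarray) -> np.ndarray:
    """t_ij = Var over samples of ln(x_i/x_j); frac is taxa x samples."""
    logf = np.log(frac)
    v = logf.var(axis=1, ddof=1)
    cov = np.cov(logf, ddof=1)
    return v[:, None] + v[None, :] - 2 * cov


def _solve_basis(t_mat: np.ndarray, include: np.ndarray) -> np.ndarray:
    """Solve basis variances from the sparsity-approximated linear system.

    ``include`` is a boolean matrix of pairs still in the system (diagonal
    ignored).  Row i: sum_{j in inc(i)} t_ij = d_i w_i + sum_{j in inc(i)} w_j.
    """
    d = t_mat.shape[0]
    inc = include.copy()
    np.fill_diagonal(inc, False)
    m = inc.astype(float)
    m[np.diag_indices(d)] = inc.sum(axis=1)
    rhs = (t_mat * inc).sum(axis=1)
    try:
        w = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError:
        w, *_ = np.linalg.lstsq(m, rhs, rcond=None)
    return w


def _rho_from_basis(t_mat: np.ndarray, w: np.ndarray) -> np.ndarray:
    w_safe = np.maximum(w, 1e-12)
    denom = 2 * np.sqrt(np.outer(w_safe, w_safe))
    rho = (w[:, None] + w[None, :] - t_mat) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_once(t_mat: np.ndarray, exclusion_threshold: float,
                 max_excluded_per_taxon: int,
                 max_exclusions: int = 10) -> np.ndarray:
    d = t_mat.shape[0]
    include = np.ones((d, d), dtype=bool)
    np.fill_diagonal(include, False)
    excluded_count = np.zeros(d, dtype=int)
    frozen = np.full((d, d), np.nan)
    for _ in range(max_exclusions + 1):
        w = _solve_basis(t_mat, include)
        rho = _rho_from_basis(t_mat, w)
        off = np.abs(rho).copy()
        np.fill_diagonal(off, 0)
        off[~include] = 0
        i, j = np.unravel_index(np.argmax(off), off.shape)
        if off[i, j] <= exclusion_threshold:
            break
        # keep the basis system well-posed: never let an included degree
        # drop below 3, and respect the per-taxon exclusion budget
        if (excluded_count[i] >= max_excluded_per_taxon
                or excluded_count[j] >= max_excluded_per_taxon
                or include[i].sum() <= 3 or include[j].sum() <= 3):
            break
        # an excluded pair is no longer constrained by later solves, so
        # its estimate is frozen at the iteration that excluded it
        frozen[i, j] = frozen[j, i] = rho[i, j]
        include[i, j] = include[j, i] = False
        excluded_count[i] += 1
        excluded_count[j] += 1
    mask = ~np.isnan(frozen)
    rho[mask] = frozen[mask]
    bad = np.flatnonzero(w <= 0)
    if bad.size:
        # basis variance not estimable: zero the taxon's correlations
        # rather than report clipped +-1 artifacts
        warnings.warn(
            f"non-positive basis variance for taxa indices {bad.tolist()}; "
            "their correlations are set to 0")
        rho[bad, :] = 0.0
        rho[:, bad] = 0.0
        np.fill_diagonal(rho, 1.0)
    return rho


def sparcc(t: FeatureTable, n_iterations: int = 20,
           exclusion_threshold: float = 0.1, seed: int = 0,
           resample: bool = True) -> CorrelationMatrix:
    """SparCC correlation estimate on a count table.

    ``resample=False`` skips the Dirichlet draw and uses the (pseudocount-
    smoothed) observed fractions directly with a single pass — the mode the
    D=3 closed-form oracle checks.
    """
    counts = t.data.to_numpy(dtype=float)
    d, n = counts.shape
    if n < 10 and resample:
        warnings.warn(f"only {n} samples: SparCC estimates will be noisy")
    if d < 4 and resample:
        warnings.warn("fewer than 4 taxa: basis approximation is weak")
    max_excl = max(d - 3, 0)
    rng = np.random.default_rng(seed)
    if not resample:
        frac = (counts + 1) / (counts + 1).sum(axis=0, keepdims=True)
        t_mat = _logratio_variance(frac)
        rho = _sparcc_once(t_mat, exclusion_threshold, max_excl)
        return CorrelationMatrix(list(t.taxon_ids), rho)
    rhos = np.empty((n_iterations, d, d))
    for it in range(n_iterations):
        frac = np.empty_like(counts)
        for s in range(n):
            frac[:, s] = rng.dirichlet(counts[:, s] + 1)
        t_mat = _logratio_variance(frac)
        rhos[it] = _sparcc_once(t_mat, exclusion_threshold, max_excl)
    rho = np.median(rhos, axis=0)
    return CorrelationMatrix(list(t.taxon_ids), (rho + rho.T) / 2)


def edge_significance(t: FeatureTable, corr: CorrelationMatrix,
                      n_permutations: int = 1000, n_bootstrap: int = 100,
                      seed: int = 0, n_iterations: int = 5,
                      compute_bootstrap_sd: bool = False) -> CorrelationMatrix:
    """Permutation p-values and BH q-values for SparCC edges.

    The null shuffles each taxon's counts across samples independently and
    re-estimates SparCC; the two-sided p per edge is the add-one fraction
    of null |rho*| >= |rho|, BH-adjusted over the upper triangle.
    Optionally, bootstrap resampling of samples quantifies estimate
    stability (stored as ``corr.bootstrap_sd``).
    """
    if n_bootstrap < 100 and compute_bootstrap_sd:
        warnings.warn(f"n_bootstrap={n_bootstrap} < 100: SD estimate unstable")
    counts = t.data.to_numpy(dtype=float)
    d, n = counts.shape
    rng = np.random.default_rng(seed)
    obs = np.abs(corr.rho)
    exceed = np.zeros((d, d))
    max_excl = max(d - 3, 0)
    for _ in range(n_permutations):
        perm = np.empty_like(counts)
        for i in range(d):
            perm[i] = counts[i, rng.permutation(n)]
        null_rho = _null_estimate(perm, rng, n_iterations, max_excl)
        exceed += np.abs(null_rho) >= obs - 1e-12
    p = (1 + exceed) / (1 + n_permutations)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices(d, 1)
    q_flat = multipletests(p[iu], method="fdr_bh")[1]
    q = np.zeros((d, d))
    q[iu] = q_flat
    q = q + q.T
    out = CorrelationMatrix(corr.taxon_ids, corr.rho, p=p, q=q)
    if compute_bootstrap_sd:
        boots = np.empty((n_bootstrap, d, d))
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            boots[b] = _null_estimate(counts[:, idx], rng, n_iterations, max_excl)
        out.bootstrap_sd = boots.std(axis=0, ddof=1)
    return out


def _null_estimate(counts: np.ndarray, rng, n_iterations: int,
                   max_excl: int) -> np.ndarray:
    d, n = counts.shape
    rhos = np.empty((n_iterations, d, d))
    for it in range(n_iterations):
        frac = np.empty_like(counts, dtype=float)
        for s in range(n):
            frac[:, s] = rng.dirichlet(counts[:, s] + 1)
        t_mat = _logratio_variance(frac)
        rhos[it] = _sparcc_once(t_mat, 0.1, max_excl)
    return np.median(rhos, axis=0)


# ---------------------------------------------------------------------------
# network construction


@dataclass
class CorrelationNetwork:
    graph: nx.Graph                       # nodes: taxon ids; edge attrs rho, q, sign, backbone
    r_min: float = 0.4
    q_max: float = 0.05
    clusters: list[list[str]] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def role_of(self, node: str) -> str:
        return self.graph.nodes[node].get("role", "none")

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, attrs in self.graph.edges(data=True):
            rows.append({"source": u, "target": v, "rho": attrs["rho"],
                         "q": attrs.get("q", np.nan), "sign": attrs["sign"],
                         "backbone": attrs.get("backbone", False)})
        return pd.DataFrame(rows)


def build_network(corr: CorrelationMatrix, q_max: float = 0.05,
                  r_min: float = 0.4) -> CorrelationNetwork:
    """Keep edges with q < q_max and |rho| > r_min (both strict)."""
    if corr.q is None:
        raise ValueError("correlation matrix lacks q-values; run edge_significance")
    g = nx.Graph()
    ids = corr.taxon_ids
    d = len(ids)
    for i, j in combinations(range(d), 2):
        rho = corr.rho[i, j]
        q = corr.q[i, j]
        if abs(rho) > r_min and q < q_max:
            g.add_edge(ids[i], ids[j], rho=float(rho), q=float(q),
                       sign="positive" if rho > 0 else "negative",
                       backbone=False)
    if g.number_of_edges() == 0:
        warnings.warn("no edges pass the filters: empty network")
    return CorrelationNetwork(graph=g, r_min=r_min, q_max=q_max)


# ---------------------------------------------------------------------------
# MCODE-style dense cores


def _mcode_weights(g: nx.Graph) -> dict:
    weights = {}
    for v in g.nodes:
        nbhd = g.subgraph(list(g.neighbors(v)) + [v])
        if nbhd.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_nums = nx.core_number(nbhd)
        k = max(core_nums.values())
        kcore_nodes = [u for u, c in core_nums.items() if c >= k]
        sub = nbhd.subgraph(kcore_nodes)
        nn = sub.number_of_nodes()
        density = (2 * sub.number_of_edges() / (nn * (nn - 1))) if nn > 1 else 0.0
        weights[v] = k * density
    return weights


def mcode_cores(net: CorrelationNetwork, node_score_cutoff: float = 0.2,
                k_core: int = 2, degree_cutoff: int = 2) -> CorrelationNetwork:
    """MCODE-style clustering: k-core weighted seeds, greedy expansion.

    Cluster members are labeled ``core``; non-members adjacent to a core
    node are ``peripheral``.  Clusters are ordered by (score, lexical seed)
    and each vertex joins at most one cluster.  Clusters whose subgraph
    lacks a ``k_core``-core are discarded.
    """
    g = net.graph
    work = g.subgraph([v for v in g.nodes if g.degree(v) >= degree_cutoff])
    weights = _mcode_weights(work)
    visited: set = set()
    clusters: list[list[str]] = []
    order = sorted(weights, key=lambda v: (-weights[v], str(v)))
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1 - node_score_cutoff)
        cluster = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            v = frontier.pop()
            for u in work.neighbors(v):
                if u in visited or u in cluster:
                    continue
                if weights[u] >= threshold:
                    cluster.add(u)
                    visited.add(u)
                    frontier.append(u)
        sub = work.subgraph(cluster)
        core_nums = nx.core_number(sub) if sub.number_of_edges() else {}
        if not core_nums or max(core_nums.values()) < k_core:
            continue
        clusters.append(sorted(cluster))
    # deterministic ordering: by mean member weight, then lexical first member
    clusters.sort(key=lambda c: (-np.mean([weights[v] for v in c]), c[0]))
    core_nodes = {v for c in clusters for v in c}
    for v in g.nodes:
        if v in core_nodes:
            g.nodes[v]["role"] = "core"
        elif any(u in core_nodes for u in g.neighbors(v)):
            g.nodes[v]["role"] = "peripheral"
        else:
            g.nodes[v]["role"] = "none"
    for i, c in enumerate(clusters):
        for v in c:
            g.nodes[v]["cluster"] = i
    net.clusters = clusters
    return net


def backbone(net: CorrelationNetwork) -> CorrelationNetwork:
    """Flag the maximum spanning forest on |rho| as the network skeleton."""
    g = net.graph
    if g.number_of_edges() == 0:
        return net
    weighted = nx.Graph()
    weighted.add_weighted_edges_from(
        (u, v, abs(attrs["rho"])) for u, v, attrs in g.edges(data=True))
    forest_edges = set()
    for comp in nx.connected_components(weighted):
        sub = weighted.subgraph(comp)
        mst = nx.maximum_spanning_tree(sub)
        forest_edges |= {frozenset(e) for e in mst.edges}
    for u, v in g.edges:
        g.edges[u, v]["backbone"] = frozenset((u, v)) in forest_edges
    return net


# ---------------------------------------------------------------------------
# cross-network functional group


@dataclass
class FunctionalGroup:
    species: list[str]
    abundance: pd.Series | None = None  # per-sample summed relative abundance
    provenance: dict = field(default_factory=dict)


def functional_group(net_hc: CorrelationNetwork, net_esin: CorrelationNetwork,
                     net_escc: CorrelationNetwork,
                     abundance_table: FeatureTable | None = None,
                     sign_strict: bool = False) -> FunctionalGroup:
    """Species with common interactions in the HC and ESIN networks that
    are confirmed present in the ESCC network.

    Step 1: unordered edges occurring in both the HC and ESIN networks
    (sign ignored unless ``sign_strict``).  Step 2: collect their endpoint
    species.  Step 3: keep species that are nodes of the ESCC network.
    """
    def edge_set(net):
        if sign_strict:
            return {(frozenset((u, v)), attrs["sign"])
                    for u, v, attrs in net.graph.edges(data=True)}
        return {frozenset((u, v)) for u, v in net.graph.edges}

    common = edge_set(net_hc) & edge_set(net_esin)
    if sign_strict:
        endpoints = {x for pair, _sign in common for x in pair}
    else:
        endpoints = {x for pair in common for x in pair}
    retained = sorted(endpoints & set(net_escc.graph.nodes))
    if not retained:
        warnings.warn("functional group is empty (no common interactions "
                      "confirmed in the carcinoma network)")
    abundance = None
    if abundance_table is not None and retained:
        rel = abundance_table.data
        if not abundance_table.is_relative:
            rel = rel.div(rel.sum(axis=0), axis=1)
        present = [s for s in retained if s in rel.index]
        abundance = rel.loc[present].sum(axis=0)
    return FunctionalGroup(
        species=retained, abundance=abundance,
        provenance={"n_common_edges": len(common),
                    "n_candidate_species": len(endpoints),
                    "sign_strict": sign_strict})
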