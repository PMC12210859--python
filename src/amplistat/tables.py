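"""Feature tables, taxonomy maps and sample metadata.

The central container is :class:`FeatureTable`, a thin wrapper around a
pandas DataFrame oriented taxa x samples, carrying a flag that says whether
the matrix holds raw read counts or per-sample relative abundances.  All
downstream stages (diversity, heterogeneity, networks, ...) consume this
container, so validation lives here: identifiers must be unique, counts
non-negative, and relative tables must have unit column sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_REL_TOL = 1e-9


class TableError(ValueError):
    """Raised on malformed or inconsistent table inputs."""


@dataclass
class FeatureTable:
    """Taxa x samples abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with taxon identifiers as the index and sample identifiers
        as columns.  Values are read counts (``is_relative=False``) or
        per-sample proportions summing to one (``is_relative=True``).
    is_relative:
        Whether columns are proportions rather than counts.
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample column sums (sequencing depth for count tables)."""
        return self.data.sum(axis=0)

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise TableError(f"duplicate taxon identifiers: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise TableError(f"duplicate sample identifiers: {dupes[:5]}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise TableError("non-numeric values in feature table")
        if np.any(~np.isfinite(vals)):
            raise TableError("non-finite values in feature table")
        if (vals < 0).any():
            raise TableError("negative values in feature table")
        if self.is_relative and self.data.shape[1]:
            sums = vals.sum(axis=0)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
            if bad.size:
                raise TableError(
                    "relative table columns do not sum to 1: "
                    f"{[self.sample_ids[i] for i in bad[:5]]}"
                )

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), is_relative=self.is_relative)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise TableError(f"unknown sample identifiers: {missing[:5]}")
        return FeatureTable(self.data[list(sample_ids)].copy(), self.is_relative)

    def drop_empty_taxa(self) -> "FeatureTable":
        keep = self.data.sum(axis=1) > 0
        return FeatureTable(self.data.loc[keep].copy(), self.is_relative)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="taxon_id")


@dataclass
class TaxonomyMap:
    """taxon id -> (kingdom, 7-rank lineage, oral-membership flag).

    ``oral`` marks bacteria catalogued as oral-cavity residents; the flag is
    only meaningful (and only allowed true) for kingdom ``bacteria``.
    """

    table: pd.DataFrame  # index taxon_id; columns kingdom, lineage..., oral

    def __post_init__(self) -> None:
        required = {"kingdom", "oral"}
        if not required <= set(self.table.columns):
            raise TableError(f"taxonomy table must have columns {sorted(required)}")
        self.table.index = self.table.index.astype(str)
        bad = self.table.loc[
            (self.table["oral"].astype(bool)) & (self.table["kingdom"] != "bacteria")
        ]
        if len(bad):
            raise TableError(
                f"oral flag set for non-bacterial taxa: {bad.index.tolist()[:5]}"
            )

    def kingdom(self, taxon_id: str) -> str:
        return str(self.table.at[taxon_id, "kingdom"])

    def is_oral(self, taxon_id: str) -> bool:
        return bool(self.table.at[taxon_id, "oral"])

    def lineage(self, taxon_id: str) -> list[str]:
        return [str(self.table.at[taxon_id, r]) for r in RANKS]

    def resolves(self, taxon_ids: Iterable[str]) -> None:
        missing = [t for t in taxon_ids if t not in self.table.index]
        if missing:
            raise TableError(f"taxa missing from taxonomy: {missing[:5]}")

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["lineage"] = [
            ";".join(
                f"{pfx}__{out.at[t, r]}" if out.at[t, r] else f"{pfx}__"
                for pfx, r in zip("kpcofgs", RANKS)
            )
            for t in out.index
        ]
        out["oral"] = out["oral"].astype(int)
        out[["kingdom", "lineage", "oral"]].to_csv(path, sep="\t", index_label="taxon_id")


@dataclass
class SampleMetadata:
    """sample id -> group label plus clinical covariates."""

    table: pd.DataFrame  # index sample_id; column 'group' + covariates
    groups: tuple[str, ...] = ("HC", "ESINA", "ESIN", "ESCCA", "ESCC")

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise TableError("metadata must have a 'group' column")
        self.table.index = self.table.index.astype(str)
        unknown = set(self.table["group"]) - set(self.groups)
        if unknown:
            raise TableError(f"group labels outside declared set: {sorted(unknown)}")

    def group_of(self, sample_id: str) -> str:
        return str(self.table.at[sample_id, "group"])

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.table.loc[list(sample_ids), "group"].to_numpy()

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.table.columns if c != "group"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# readers


def read_feature_table(path, orientation: str = "taxa_rows",
                       is_relative: bool = False) -> FeatureTable:
    """Read a TSV feature table.

    ``orientation`` declares the layout on disk: ``taxa_rows`` (default;
    header row = sample ids) or ``samples_rows``.  The returned table is
    always taxa x samples.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise TableError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise TableError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "samples_rows":
        df = df.T
    return FeatureTable(df, is_relative=is_relative)


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a semicolon-delimited ``k__;p__;...;s__`` lineage into ranks."""
    parts = [p.strip() for p in str(lineage).split(";")]
    out = {}
    for rank, part in zip(RANKS, parts + [""] * (len(RANKS) - len(parts))):
        if "__" in part:
            part = part.split("__", 1)[1]
        out[rank] = part
    return out


def read_taxonomy(path) -> TaxonomyMap:
    """Read a taxonomy TSV with columns taxon_id, kingdom, lineage, oral."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "lineage" in df.columns:
        ranks = pd.DataFrame(
            [parse_lineage(v) for v in df["lineage"]], index=df.index
        )
        df = pd.concat([df.drop(columns=["lineage"]), ranks], axis=1)
    df["oral"] = df["oral"].astype(float).astype(bool) if "oral" in df else False
    return TaxonomyMap(df)


def read_metadata(path, groups=("HC", "ESINA", "ESIN", "ESCCA", "ESCC")) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(df, groups=tuple(groups))


# ---------------------------------------------------------------------------
# filtering and transforms


def filter_features(t: FeatureTable, min_total_reads: int = 10,
                    min_samples: int = 2) -> FeatureTable:
    """Retain taxa with total reads >= ``min_total_reads`` and presence
    (>=1 read) in >= ``min_samples`` samples.  Sample set unchanged."""
    if t.is_relative:
        raise TableError("filter_features requires a count table")
    totals = t.data.sum(axis=1)
    prevalence = (t.data >= 1).sum(axis=1)
    keep = (totals >= min_total_reads) & (prevalence >= min_samples)
    return FeatureTable(t.data.loc[keep].copy(), is_relative=False)


def filter_samples_by_depth(t: FeatureTable, min_depth: int) -> FeatureTable:
    """Drop samples whose column sum is below ``min_depth`` (inclusive keep).

    Taxa rows are left untouched, including rows that become all-zero;
    pruning taxa is a separate explicit call.
    """
    if t.is_relative:
        raise TableError("depth filtering requires a count table")
    depths = t.depths()
    keep = depths[depths >= min_depth].index.tolist()
    if not keep:
        raise TableError(
            f"all {t.n_samples} samples fall below depth threshold {min_depth}"
        )
    dropped = [s for s in t.sample_ids if s not in set(keep)]
    if dropped:
        logger.info("depth filter (min_depth=%d) dropped %d samples: %s",
                    min_depth, len(dropped), dropped)
    return FeatureTable(t.data[keep].copy(), is_relative=False)


def to_relative(t: FeatureTable) -> FeatureTable:
    """Divide each sample column by its sum. Idempotent."""
    depths = t.depths()
    zero = depths.index[depths <= 0].tolist()
    if zero:
        raise TableError(f"zero-depth samples: {zero[:5]}")
    return FeatureTable(t.data.div(depths, axis=1), is_relative=True)


def collapse_rank(t: FeatureTable, tax: TaxonomyMap, rank: str) -> FeatureTable:
    """Sum rows sharing the same lineage prefix up to ``rank``.

    Taxa with an empty value at ``rank`` are pooled under
    ``unclassified_<deepest assigned parent>`` so labels stay unique and
    per-sample totals are conserved.
    """
    if rank not in RANKS:
        raise TableError(f"unknown rank {rank!r}; expected one of {RANKS}")
    tax.resolves(t.taxon_ids)
    depth = RANKS.index(rank)
    labels = []
    for taxon in t.taxon_ids:
        lin = tax.lineage(taxon)
        prefix = lin[: depth + 1]
        if prefix[-1] in ("", "nan"):
            parent = next((p for p in reversed(prefix[:-1]) if p not in ("", "nan")),
                          "root")
            labels.append("|".join(prefix[:-1]) + f"|unclassified_{parent}")
        else:
            labels.append("|".join(prefix))
    grouped = t.data.groupby(pd.Index(labels, name="taxon_id")).sum()
    return FeatureTable(grouped, is_relative=t.is_relative)


def oral_fraction(t: FeatureTable, tax: TaxonomyMap,
                  mode: str = "per_sample") -> pd.Series:
    """Per-sample fraction of abundance in oral-flagged bacterial taxa.

    ``mode='per_sample'`` (default) returns one fraction per sample; group
    means are then taken downstream.  ``mode='pooled'`` is exposed for
    pooling counts within a caller-provided sample set before dividing
    (call on a group-subset table).
    """
    tax.resolves(t.taxon_ids)
    kingdoms = {tax.kingdom(x) for x in t.taxon_ids}
    if "bacteria" not in kingdoms:
        raise TableError("oral_fraction needs bacterial taxa (oral flags undefined)")
    oral_mask = np.array([tax.is_oral(x) for x in t.taxon_ids])
    totals = t.data.sum(axis=0)
    if (totals <= 0).any():
        raise TableError("zero-total sample in oral_fraction input")
    oral_sum = t.data.loc[oral_mask].sum(axis=0)
    if mode == "pooled":
        return pd.Series({"pooled": oral_sum.sum() / totals.sum()})
    return oral_sum / totals
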