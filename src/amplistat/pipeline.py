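"""End-to-end orchestration: simulate (or load) -> filter -> diversity ->
heterogeneity -> shared species -> biomarkers -> networks -> clinical
statistics, with per-stage TSV/JSON artifacts and a manifest.

Every stochastic stage draws its seed deterministically from the single
config seed, so two runs with the same config produce byte-identical
machine outputs.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (FeatureTable, read_feature_table, read_taxonomy,
                     read_metadata, filter_features, filter_samples_by_depth,
                     to_relative, oral_fraction, TableError)
from .simulate import SyntheticConfig, generate_tables
from .diversity import (hill_profile, alpha_contrasts, hellinger, bray_curtis,
                        pcoa, permanova, pairwise_beta)
from .heterogeneity import fit_all_groups, tple_compare, compact_letters
from .shared import a2_null
from .differential import (lda_effect_size, effect_size_frame, marker_scores,
                           roc_auc, combine_markers)
from .networks import (sparcc, edge_significance, build_network, mcode_cores,
                       backbone, functional_group)
from .clinical import summary_table

logger = logging.getLogger(__name__)

STAGES = ("tables", "diversity", "tple", "shared", "lefse", "network",
          "markers", "clinstats")


@dataclass
class PipelineConfig:
    """All pipeline thresholds in one place; defaults follow the study
    constants (depth 14000/19500, feature filter 10 reads & 2 samples,
    LDA threshold 3.0, network filters |r| > 0.4 and q < 0.05)."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    synthetic: SyntheticConfig | None = None
    bacteria_path: str | None = None
    fungi_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    min_depth_bacteria: int = 14_000
    min_depth_fungi: int = 19_500
    min_feature_reads: int = 10
    min_feature_samples: int = 2
    n_perm: int = 199
    lda_threshold: float = 3.0
    r_min: float = 0.4
    q_max: float = 0.05
    network_groups: tuple = ("HC", "ESIN", "ESCC")
    sparcc_iterations: int = 10
    network_permutations: int = 200
    network_max_taxa: int = 40
    force: bool = False

    def validate(self) -> None:
        for name in ("min_depth_bacteria", "min_depth_fungi",
                     "min_feature_reads", "min_feature_samples", "n_perm",
                     "lda_threshold", "r_min", "q_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.synthetic is None and not (self.bacteria_path and
                                           self.taxonomy_path and
                                           self.metadata_path):
            raise ValueError("need either a synthetic config or input paths")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    if out.exists() and any(out.iterdir()) and not cfg.force:
        raise FileExistsError(
            f"output directory {out} is non-empty (pass force=True to overwrite)")
    if out.exists() and cfg.force:
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {},
                      "parameters": {k: v for k, v in asdict(cfg).items()
                                     if k not in ("synthetic", "out_dir")}}

    # ---- stage: tables -------------------------------------------------
    stage = "tables"
    try:
        if cfg.synthetic is not None:
            bacteria, fungi, taxonomy, meta, truth = generate_tables(cfg.synthetic)
        else:
            bacteria = read_feature_table(cfg.bacteria_path)
            fungi = (read_feature_table(cfg.fungi_path)
                     if cfg.fungi_path else None)
            taxonomy = read_taxonomy(cfg.taxonomy_path)
            meta = read_metadata(cfg.metadata_path)
            truth = None
        bacteria = filter_features(
            filter_samples_by_depth(bacteria, cfg.min_depth_bacteria),
            cfg.min_feature_reads, cfg.min_feature_samples)
        if fungi is not None:
            fungi = filter_features(
                filter_samples_by_depth(fungi, cfg.min_depth_fungi),
                cfg.min_feature_reads, cfg.min_feature_samples)
        bacteria.to_tsv(out / "bacteria_counts.tsv")
        if fungi is not None:
            fungi.to_tsv(out / "fungi_counts.tsv")
        taxonomy.to_tsv(out / "taxonomy.tsv")
        meta.to_tsv(out / "metadata.tsv")
        orals = oral_fraction(bacteria, taxonomy)
        orals.rename("oral_fraction").to_csv(out / "oral_fraction.tsv", sep="\t")
        manifest["stages"][stage] = ["bacteria_counts.tsv", "taxonomy.tsv",
                                     "metadata.tsv", "oral_fraction.tsv"]
        if fungi is not None:
            manifest["stages"][stage].append("fungi_counts.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    kingdoms = {"bacteria": bacteria}
    if fungi is not None:
        kingdoms["fungi"] = fungi

    # ---- stage: diversity ---------------------------------------------
    stage = "diversity"
    try:
        files = []
        for name, table in kingdoms.items():
            prof = hill_profile(table)
            prof.to_csv(out / f"hill_{name}.tsv", sep="\t")
            contrasts = pd.concat(
                [alpha_contrasts(prof, meta, q) for q in (0, 1, 2)])
            contrasts.to_csv(out / f"alpha_contrasts_{name}.tsv", sep="\t",
                             index=False)
            d = bray_curtis(hellinger(table))
            d.to_frame().to_csv(out / f"braycurtis_{name}.tsv", sep="\t")
            ord_res = pcoa(d, k=2)
            pd.DataFrame(ord_res.coordinates, index=ord_res.sample_ids,
                         columns=["PCo1", "PCo2"]).to_csv(
                out / f"pcoa_{name}.tsv", sep="\t")
            omni = permanova(d, meta.labels_for(d.sample_ids),
                             n_perm=cfg.n_perm, seed=cfg.seed)
            pw = pairwise_beta(d, meta, n_perm=cfg.n_perm, seed=cfg.seed)
            pw.to_csv(out / f"beta_pairwise_{name}.tsv", sep="\t", index=False)
            (out / f"permanova_{name}.json").write_text(json.dumps(omni, indent=1))
            files += [f"hill_{name}.tsv", f"alpha_contrasts_{name}.tsv",
                      f"braycurtis_{name}.tsv", f"pcoa_{name}.tsv",
                      f"beta_pairwise_{name}.tsv", f"permanova_{name}.json"]
        manifest["stages"][stage] = files
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: tple ----------------------------------------------------
    stage = "tple"
    try:
        files = []
        for name, table in kingdoms.items():
            fits = fit_all_groups(table, meta)
            fits.to_csv(out / f"tple_fits_{name}.tsv", sep="\t", index=False)
            groups = list(fits["group"])
            sig = {}
            rows = []
            present = set(table.sample_ids)
            for i, (a, b) in enumerate(combinations(groups, 2)):
                contrast = tple_compare(
                    table,
                    [s for s in meta.samples_in(a) if s in present],
                    [s for s in meta.samples_in(b) if s in present],
                    n_perm=cfg.n_perm, seed=cfg.seed + 100 + i,
                    group_a=a, group_b=b)
                sig[frozenset((a, b))] = contrast.p_b < 0.05
                rows.append(contrast.__dict__)
            pd.DataFrame(rows).to_csv(out / f"tple_contrasts_{name}.tsv",
                                      sep="\t", index=False)
            letters = compact_letters(groups, sig)
            (out / f"tple_letters_{name}.json").write_text(
                json.dumps(letters, indent=1))
            files += [f"tple_fits_{name}.tsv", f"tple_contrasts_{name}.tsv",
                      f"tple_letters_{name}.json"]
        manifest["stages"][stage] = files
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: shared --------------------------------------------------
    stage = "shared"
    try:
        files = []
        for name, table in kingdoms.items():
            rows = []
            present = set(table.sample_ids)
            by_group = {g: [s for s in meta.samples_in(g) if s in present]
                        for g in meta.groups}
            groups = [g for g in meta.groups if len(by_group[g]) >= 2]
            for i, (a, b) in enumerate(combinations(groups, 2)):
                res = a2_null(table, by_group[a], by_group[b],
                              n_perm=max(cfg.n_perm, 100),
                              seed=cfg.seed + 200 + i, group_a=a, group_b=b)
                rows.append(res.__dict__)
            pd.DataFrame(rows).to_csv(out / f"shared_{name}.tsv", sep="\t",
                                      index=False)
            files.append(f"shared_{name}.tsv")
        manifest["stages"][stage] = files
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: lefse ---------------------------------------------------
    stage = "lefse"
    try:
        files = []
        for name, table in kingdoms.items():
            rel = to_relative(table)
            records = lda_effect_size(rel, meta, seed=cfg.seed + 300,
                                      lda_threshold=cfg.lda_threshold)
            effect_size_frame(records).to_csv(out / f"lefse_{name}.tsv",
                                              sep="\t", index=False)
            files.append(f"lefse_{name}.tsv")
        manifest["stages"][stage] = files
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: network -------------------------------------------------
    stage = "network"
    nets = {}
    try:
        files = []
        combined = _combined_counts(kingdoms)
        for gi, g in enumerate(cfg.network_groups):
            samples = [s for s in meta.samples_in(g)
                       if s in combined.sample_ids]
            if len(samples) < 4:
                logger.info("network stage for %s skipped (n=%d)", g,
                            len(samples))
                manifest.setdefault("notices", []).append(
                    f"network stage for {g} skipped: {len(samples)} samples")
                continue
            sub = combined.subset_samples(samples).drop_empty_taxa()
            # keep prevalent, abundant taxa: holds the basis system
            # well-posed and mirrors species-level network practice
            prevalent = (sub.data > 0).sum(axis=1) >= max(2, len(samples) // 2)
            sub = FeatureTable(sub.data.loc[prevalent], is_relative=False)
            if sub.n_taxa > cfg.network_max_taxa:
                top = sub.data.sum(axis=1).nlargest(cfg.network_max_taxa).index
                sub = FeatureTable(sub.data.loc[sorted(top)], is_relative=False)
            corr = sparcc(sub, n_iterations=cfg.sparcc_iterations,
                          seed=cfg.seed + 400 + gi)
            corr = edge_significance(sub, corr,
                                     n_permutations=cfg.network_permutations,
                                     seed=cfg.seed + 500 + gi)
            net = build_network(corr, q_max=cfg.q_max, r_min=cfg.r_min)
            net = backbone(mcode_cores(net))
            nets[g] = net
            frame = net.edge_frame()
            frame.to_csv(out / f"network_{g}.tsv", sep="\t", index=False)
            files.append(f"network_{g}.tsv")
        if all(g in nets for g in ("HC", "ESIN", "ESCC")):
            rel_all = to_relative(_combined_counts(kingdoms))
            fg = functional_group(nets["HC"], nets["ESIN"], nets["ESCC"],
                                  abundance_table=rel_all)
            pd.Series(fg.species, name="species").to_csv(
                out / "functional_group.tsv", sep="\t", index=False)
            files.append("functional_group.tsv")
        else:
            fg = None
            manifest.setdefault("notices", []).append(
                "functional group skipped: missing one of HC/ESIN/ESCC networks")
        manifest["stages"][stage] = files
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: markers -------------------------------------------------
    stage = "markers"
    try:
        files = []
        results = {}
        if fungi is not None and fg is not None and fg.species:
            rel_f = to_relative(fungi)
            # single planted dysplasia-enriched fungus vs the functional group
            marker_a = rel_f.data.loc[rel_f.data.var(axis=1).idxmax()]
            rel_all = to_relative(_combined_counts(kingdoms))
            group_score = marker_scores(rel_all, fg.species, name="group_sum")
            for target in ("ESIN", "ESCC"):
                pos = meta.samples_in(target)
                neg = meta.samples_in("HC")
                samples = [s for s in pos + neg if s in rel_all.sample_ids]
                labels = pd.Series(
                    [1 if s in pos else 0 for s in samples], index=samples)
                a = marker_a.loc[samples]
                b = group_score.loc[samples]
                res_a = roc_auc(a, labels, marker="single",
                                group_pair=(target, "HC"))
                res_b = roc_auc(b, labels, marker="functional_group",
                                group_pair=(target, "HC"))
                res_ab = combine_markers(a, b, labels, marker="combined",
                                         group_pair=(target, "HC"))
                results[target] = {"single": res_a.auc,
                                   "functional_group": res_b.auc,
                                   "combined": res_ab.auc}
        (out / "roc_auc.json").write_text(json.dumps(results, indent=1))
        files.append("roc_auc.json")
        manifest["stages"][stage] = files
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: clinstats -----------------------------------------------
    stage = "clinstats"
    try:
        present = [g for g in ("HC", "ESIN", "ESCC") if meta.samples_in(g)]
        report = summary_table(meta, groups=present)
        report.to_csv(out / "clinical_table.tsv", sep="\t")
        manifest["stages"][stage] = ["clinical_table.tsv"]
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def _combined_counts(kingdoms: dict[str, FeatureTable]) -> FeatureTable:
    """Stack bacterial and fungal counts over the shared sample set."""
    if len(kingdoms) == 1:
        return next(iter(kingdoms.values()))
    tables = list(kingdoms.values())
    common = [s for s in tables[0].sample_ids
              if all(s in t.sample_ids for t in tables[1:])]
    stacked = pd.concat([t.data[common] for t in tables], axis=0)
    return FeatureTable(stacked, is_relative=False)
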