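"""Synthetic five-group bacterial and fungal communities with planted truth.

The generator emulates the structure of an esophageal biopsy cohort across
disease stages (HC, ESINA, ESIN, ESCCA, ESCC): two kingdoms sequenced
separately, per-group compositional shifts, group-specific overdispersion
that drives community spatial heterogeneity, latent correlation blocks for
network inference, and clinical covariates realised to exact contingency
counts.

Counts are drawn hierarchically: per-taxon latent log-abundance = base
(log-normal across taxa) + group effect (planted log2 fold changes) +
correlated per-sample noise (block covariance, marginal SD set by the
group's dispersion parameter); each kingdom is then closed to fractions and
sampled multinomially at a log-normally distributed library size.  Larger
dispersion makes within-sample abundance distributions more uneven and, via
detection of rare taxa scaling with depth, raises the fitted Taylor
exponent — so the dispersion parameter is the heterogeneity dial the
power-law stage is tested against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata, TaxonomyMap, RANKS

GROUPS = ("HC", "ESINA", "ESIN", "ESCCA", "ESCC")

# cohort contingency rows for the clinical covariates (yes count, group n):
# healthy controls / dysplasia patients / carcinoma patients
DEFAULT_CLINICAL_TABLES = {
    "current_alcohol": {"HC": (4, 13), "ESIN": (7, 10), "ESCC": (11, 12)},
    "family_history_cancer": {"HC": (0, 13), "ESIN": (3, 10), "ESCC": (0, 12)},
    "hot_food_preference": {"HC": (0, 13), "ESIN": (5, 10), "ESCC": (3, 12)},
    "low_income": {"HC": (5, 13), "ESIN": (6, 10), "ESCC": (11, 12)},
    "male": {"HC": (9, 13), "ESIN": (9, 10), "ESCC": (11, 12)},
}

DEFAULT_AGE_SUMMARIES = {"HC": (64.3, 11.0), "ESIN": (63.5, 9.80),
                         "ESCC": (66.8, 5.94)}


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give the scaled-down study profile.

    Group sizes follow the cohort (13 healthy controls, 10 dysplasia, 12
    carcinoma patients, adjacent-tissue groups matching their patients);
    taxon counts default to a scaled-down profile (200 bacterial / 60
    fungal taxa) so every downstream stage runs quickly — the full-size
    profile (2314 / 573) is a parameter away.
    """

    seed: int = 0
    group_sizes: dict = field(default_factory=lambda: {
        "HC": 13, "ESINA": 10, "ESIN": 10, "ESCCA": 12, "ESCC": 12})
    n_taxa_bacteria: int = 200
    n_taxa_fungi: int = 60
    # library sizes ~ LogNormal(log(mean) - sigma^2/2, sigma)
    library_mean_bacteria: float = 30_000.0
    library_mean_fungi: float = 25_000.0
    library_sigma: float = 0.4
    # base composition: per-taxon log-abundance ~ Normal(0, base_sigma)
    base_sigma: float = 1.6
    # differential taxa: (taxon_id, affected groups, log2 fold change)
    differential_taxa: list = field(default_factory=lambda: [
        ("B_0001", ("ESIN", "ESINA"), 2.0),      # dysplasia-enriched bacterium
        ("B_0002", ("ESCC", "ESCCA"), 3.0),      # carcinoma-enriched bacterium
        ("B_0003", ("ESCC",), 2.5),
        ("F_0001", ("ESIN",), 3.0),              # dysplasia-enriched fungus
        ("F_0002", ("ESCC",), 2.0),
    ])
    # per-group dispersion: SD of the per-sample latent log-abundance noise;
    # drives unevenness and hence the Taylor heterogeneity exponent
    dispersion_by_group: dict = field(default_factory=lambda: {
        "HC": 0.5, "ESINA": 0.6, "ESIN": 1.0, "ESCCA": 0.7, "ESCC": 0.45})
    # lognormal sigma of the per-sample multiplier on the group dispersion;
    # sample-to-sample variation in unevenness is what tilts the variance-
    # mean slope away from 2 (samples dominated by blown-up taxa sit
    # up-right of even samples on the log-log plane)
    sample_dispersion_spread: float = 0.35
    # weight in [0, 1] tying the library-size draw to the same per-sample
    # activity variable that scales dispersion: "hot" communities yield
    # both deeper libraries and stronger dominance, which aligns the
    # variance-mean points along one tight power-law curve per group
    library_activity_coupling: float = 1.0
    # correlation blocks: (list of taxon ids, latent correlation); the
    # correlation may be a scalar (same in every group) or a mapping
    # group -> scalar, letting e.g. a carcinoma-style group carry weaker
    # coupling and hence a sparser inferred network
    correlation_blocks: list = field(default_factory=lambda: [
        (["B_0010", "B_0011", "B_0012", "B_0013"], 0.7),
        (["B_0020", "B_0021"], -0.6),
        (["B_0030", "F_0010"], 0.6),
    ])
    oral_flag_probability: float = 0.3
    clinical_tables: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_TABLES))
    age_summaries: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SUMMARIES))

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n != 0 and n < 2:  # 0 = group absent from this cohort
                raise ValueError(f"group {g}: size {n} < 2")
        for taxon, groups, lfc in self.differential_taxa:
            if not np.isfinite(lfc):
                raise ValueError(f"non-finite fold change for {taxon}")
        for taxa, r in self.correlation_blocks:
            values = r.values() if isinstance(r, dict) else [r]
            for rv in values:
                if not -1 < rv < 1:
                    raise ValueError(f"latent correlation {rv} outside (-1, 1)")
                if rv < -1.0 / (len(taxa) - 1) + 1e-9 and len(taxa) > 2:
                    raise ValueError(
                        f"equicorrelation {rv} not positive-semidefinite for "
                        f"block of {len(taxa)}")
        for cov, per_group in self.clinical_tables.items():
            for g, (yes, n) in per_group.items():
                if yes > n:
                    raise ValueError(f"{cov}/{g}: yes count {yes} > n {n}")

    @classmethod
    def full_size(cls, **kwargs) -> "SyntheticConfig":
        """Full study-scale profile (2314 bacterial, 573 fungal taxa)."""
        return cls(n_taxa_bacteria=2314, n_taxa_fungi=573, **kwargs)


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside a generated dataset."""
    differential_taxa: list            # (taxon, groups, log2fc)
    correlation_blocks: list           # (taxa, latent r)
    latent_correlation: pd.DataFrame   # full latent correlation matrix
    dispersion_by_group: dict
    clinical_tables: dict


def _sub_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(stream,)))


def _block_covariance(taxon_ids: list[str], blocks: list,
                      group: str | None = None) -> np.ndarray:
    d = len(taxon_ids)
    idx = {t: i for i, t in enumerate(taxon_ids)}
    cov = np.eye(d)
    for taxa, r in blocks:
        if isinstance(r, dict):
            if group is None or group not in r:
                continue
            r = r[group]
        members = [idx[t] for t in taxa if t in idx]
        for a in members:
            for b in members:
                if a != b:
                    cov[a, b] = r
    # planted blocks must be valid covariances
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin < -1e-9:
        raise ValueError("correlation blocks yield a non-PSD covariance")
    return cov


def generate_tables(cfg: SyntheticConfig):
    """Generate (bacteria, fungi, taxonomy, metadata, truth) for one cohort.

    Deterministic under a fixed ``cfg.seed``: all randomness flows from one
    seed through fixed-offset sub-streams.
    """
    cfg.validate()
    taxa_b = [f"B_{i:04d}" for i in range(cfg.n_taxa_bacteria)]
    taxa_f = [f"F_{i:04d}" for i in range(cfg.n_taxa_fungi)]
    taxa_all = taxa_b + taxa_f
    d = len(taxa_all)

    sample_ids, groups_per_sample = [], []
    for g in GROUPS:
        for k in range(cfg.group_sizes.get(g, 0)):
            sample_ids.append(f"{g}_{k + 1:02d}")
            groups_per_sample.append(g)

    rng = _sub_rng(cfg.seed, 0)
    base = rng.normal(0.0, cfg.base_sigma, size=d)

    # group effects from planted log2 fold changes
    effects = {g: np.zeros(d) for g in GROUPS}
    idx = {t: i for i, t in enumerate(taxa_all)}
    for taxon, affected, lfc in cfg.differential_taxa:
        if taxon not in idx:
            continue
        for g in affected:
            effects[g][idx[taxon]] += lfc * np.log(2.0)

    group_specific = any(isinstance(r, dict) for _, r in cfg.correlation_blocks)
    if group_specific:
        cov_by_group = {g: _block_covariance(taxa_all, cfg.correlation_blocks, g)
                        for g in GROUPS}
        chol_by_group = {g: np.linalg.cholesky(c + 1e-10 * np.eye(d))
                         for g, c in cov_by_group.items()}
    else:
        cov = _block_covariance(taxa_all, cfg.correlation_blocks)
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(d))

    counts_b = np.zeros((len(taxa_b), len(sample_ids)), dtype=int)
    counts_f = np.zeros((len(taxa_f), len(sample_ids)), dtype=int)
    noise_rng = _sub_rng(cfg.seed, 1)
    lib_rng = _sub_rng(cfg.seed, 2)
    n_b = len(taxa_b)
    c = float(np.clip(cfg.library_activity_coupling, 0.0, 1.0))
    for s, (sid, g) in enumerate(zip(sample_ids, groups_per_sample)):
        u = noise_rng.normal()  # per-sample activity
        sigma = cfg.dispersion_by_group[g] * np.exp(
            cfg.sample_dispersion_spread * u)
        chol_g = chol_by_group[g] if group_specific else chol
        z = chol_g @ noise_rng.normal(0.0, 1.0, size=d)
        log_lam = base + effects[g] + sigma * z
        lam = np.exp(log_lam)
        for kingdom, taxa_slice, out, mean in (
                ("bacteria", slice(0, n_b), counts_b, cfg.library_mean_bacteria),
                ("fungi", slice(n_b, d), counts_f, cfg.library_mean_fungi)):
            lam_k = lam[taxa_slice]
            probs = lam_k / lam_k.sum()
            v = lib_rng.normal()
            lib_z = c * u + np.sqrt(1 - c ** 2) * v
            lib = int(np.round(np.exp(
                np.log(mean) - cfg.library_sigma ** 2 / 2
                + cfg.library_sigma * lib_z)))
            out[:, s] = lib_rng.multinomial(lib, probs)

    bacteria = FeatureTable(pd.DataFrame(counts_b, index=taxa_b,
                                         columns=sample_ids))
    fungi = FeatureTable(pd.DataFrame(counts_f, index=taxa_f,
                                      columns=sample_ids))

    taxonomy = _make_taxonomy(cfg, taxa_b, taxa_f)
    meta = generate_clinical(cfg)
    if group_specific:
        latent = {g: pd.DataFrame(c, index=taxa_all, columns=taxa_all)
                  for g, c in cov_by_group.items()}
    else:
        latent = pd.DataFrame(cov, index=taxa_all, columns=taxa_all)
    truth = PlantedTruth(
        differential_taxa=list(cfg.differential_taxa),
        correlation_blocks=list(cfg.correlation_blocks),
        latent_correlation=latent,
        dispersion_by_group=dict(cfg.dispersion_by_group),
        clinical_tables=dict(cfg.clinical_tables))
    return bacteria, fungi, taxonomy, meta, truth


def _make_taxonomy(cfg: SyntheticConfig, taxa_b: list[str],
                   taxa_f: list[str]) -> TaxonomyMap:
    rng = _sub_rng(cfg.seed, 3)
    rows = {}
    # enriched bacterial taxa are flagged oral, mirroring the oral-resident
    # enrichment the disease-stage contrast is meant to exhibit
    forced_oral = {t for t, groups, _ in cfg.differential_taxa
                   if t.startswith("B_") and any(g in ("ESIN", "ESINA", "ESCC",
                                                       "ESCCA") for g in groups)}
    n_phyla_b, n_phyla_f = 8, 4
    for t in taxa_b:
        i = int(t.split("_")[1])
        oral = t in forced_oral or rng.random() < cfg.oral_flag_probability
        rows[t] = {
            "kingdom": "bacteria", "oral": bool(oral),
            "domain": "Bacteria", "phylum": f"BPhylum_{i % n_phyla_b}",
            "class": f"BClass_{i % 16}", "order": f"BOrder_{i % 32}",
            "family": f"BFamily_{i % 48}", "genus": f"BGenus_{i % 64}",
            "species": f"BSpecies_{i}",
        }
    for t in taxa_f:
        i = int(t.split("_")[1])
        rows[t] = {
            "kingdom": "fungi", "oral": False,
            "domain": "Fungi", "phylum": f"FPhylum_{i % n_phyla_f}",
            "class": f"FClass_{i % 8}", "order": f"FOrder_{i % 12}",
            "family": f"FFamily_{i % 16}", "genus": f"FGenus_{i % 24}",
            "species": f"FSpecies_{i}",
        }
    df = pd.DataFrame(rows).T
    df["oral"] = df["oral"].astype(bool)
    return TaxonomyMap(df)


def generate_clinical(cfg: SyntheticConfig) -> SampleMetadata:
    """Sample metadata whose covariates hit the configured contingency
    counts exactly; which samples carry a 'yes' is randomised by seed.

    Adjacent-tissue groups (ESINA/ESCCA) mirror the covariates of their
    patient groups sample-for-sample, as adjacent tissue comes from the
    same patient.
    """
    cfg.validate()
    rng = _sub_rng(cfg.seed, 4)
    sample_ids, groups_per_sample = [], []
    for g in GROUPS:
        for k in range(cfg.group_sizes.get(g, 0)):
            sample_ids.append(f"{g}_{k + 1:02d}")
            groups_per_sample.append(g)
    df = pd.DataFrame({"group": groups_per_sample}, index=sample_ids)

    mirror = {"ESINA": "ESIN", "ESCCA": "ESCC"}
    for cov, per_group in cfg.clinical_tables.items():
        mismatched = [g for g, (_yes, n) in per_group.items()
                      if cfg.group_sizes.get(g, 0) != n]
        if mismatched:
            warnings.warn(f"covariate {cov!r} dropped: configured n does not "
                          f"match group sizes for {mismatched}")
            continue
        values = pd.Series(0, index=df.index, dtype=int)
        assignments: dict[str, np.ndarray] = {}
        for g, (yes, n) in per_group.items():
            members = df.index[df["group"] == g]
            if yes > len(members):
                raise ValueError(f"{cov}/{g}: yes count exceeds group size")
            pick = rng.choice(len(members), size=yes, replace=False)
            flags = np.zeros(len(members), dtype=int)
            flags[pick] = 1
            assignments[g] = flags
            values.loc[members] = flags
        for adj, src in mirror.items():
            members = df.index[df["group"] == adj]
            if len(members) and src in assignments:
                flags = assignments[src]
                values.loc[members] = flags[: len(members)] if len(flags) >= len(members) \
                    else np.pad(flags, (0, len(members) - len(flags)))
        df[cov] = values

    age_rng = _sub_rng(cfg.seed, 5)
    ages = pd.Series(0.0, index=df.index)
    for g, (mean, sd) in cfg.age_summaries.items():
        members = df.index[df["group"] == g]
        ages.loc[members] = np.round(age_rng.normal(mean, sd, size=len(members)), 1)
    for adj, src in mirror.items():
        members = df.index[df["group"] == adj]
        src_members = df.index[df["group"] == src]
        if len(members) and len(src_members):
            vals = ages.loc[src_members].to_numpy()
            reps = int(np.ceil(len(members) / len(vals)))
            ages.loc[members] = np.tile(vals, reps)[: len(members)]
    df["age"] = ages
    return SampleMetadata(df, groups=GROUPS)
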