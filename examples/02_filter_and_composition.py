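"""Depth/feature filtering and composition summaries.

Applies the standard amplicon retention rules (>= 10 reads and >= 2
samples per feature; a per-kingdom sequencing-depth floor), collapses to
genus level, and computes the oral-microbiome fraction per sample.
"""

from amplistat import (SyntheticConfig, generate_tables, filter_features,
                       filter_samples_by_depth, to_relative, collapse_rank,
                       oral_fraction)

bacteria, fungi, taxonomy, metadata, _ = generate_tables(SyntheticConfig(seed=7))

bacteria = filter_samples_by_depth(bacteria, min_depth=14_000)
bacteria = filter_features(bacteria, min_total_reads=10, min_samples=2)
print(f"after filtering: {bacteria.n_taxa} taxa x {bacteria.n_samples} samples")

genus = collapse_rank(to_relative(bacteria), taxonomy, "genus")
top = genus.data.mean(axis=1).nlargest(3)
print("three most abundant genus-level groups (mean relative abundance):")
for name, val in top.items():
    print(f"  {name.split('|')[-1]}: {100 * val:.1f}%")

oral = oral_fraction(bacteria, taxonomy)
for g in ("HC", "ESIN", "ESCC"):
    vals = oral[[s for s in metadata.samples_in(g) if s in oral.index]]
    print(f"oral-microbiome fraction, {g}: {100 * vals.mean():.1f}% "
          f"(mean over {len(vals)} samples)")
# The oral fraction is the share of reads assigned to taxa catalogued as
# oral-cavity residents; the study tracks how it shifts with disease stage.
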