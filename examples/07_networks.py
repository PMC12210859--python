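"""SparCC co-occurrence networks, dense cores, backbone, and the
cross-network functional group.

Correlations are estimated compositionally (SparCC), filtered at
FDR-adjusted p < 0.05 and |rho| > 0.4; MCODE-style clustering labels
core vs peripheral species; the maximum spanning forest on |rho| marks
the backbone; and species interacting in both the healthy and dysplasia
networks that persist as carcinoma-network nodes form the candidate
disease-related functional group.
"""

import pandas as pd

from amplistat import (SyntheticConfig, generate_tables, FeatureTable,
                       sparcc, edge_significance, build_network,
                       mcode_cores, backbone, functional_group, to_relative,
                       marker_scores, roc_auc)

GROUPS = ("HC", "ESINA", "ESIN", "ESCCA", "ESCC")
block1 = [f"B_{i:04d}" for i in range(0, 10)]
block2 = [f"B_{i:04d}" for i in range(10, 18)]
block3 = ["B_0018", "B_0019", "F_0000"]
anchors = block1 + block2 + block3
weak_carcinoma = {"HC": 0.8, "ESIN": 0.8, "ESCC": 0.5}
cfg = SyntheticConfig(
    seed=1, group_sizes={"HC": 35, "ESIN": 35, "ESCC": 35},
    n_taxa_bacteria=400, n_taxa_fungi=100,
    dispersion_by_group={"HC": 0.6, "ESIN": 0.6, "ESCC": 0.6},
    differential_taxa=(
        [(t, GROUPS, 6.0) for t in anchors]
        + [(t, ("ESCC",), 1.5) for t in block1 + block2]),
    correlation_blocks=[(block1, weak_carcinoma), (block2, weak_carcinoma),
                        (block3, {"HC": 0.7, "ESIN": 0.7, "ESCC": 0.45})],
    clinical_tables={})
bacteria, fungi, _, meta, _ = generate_tables(cfg)
combined = pd.concat([bacteria.data, fungi.data])

nets = {}
for gi, g in enumerate(("HC", "ESIN", "ESCC")):
    sub = combined[meta.samples_in(g)]
    sub = sub[sub.sum(axis=1) > 0]
    table = FeatureTable(sub.loc[sorted(sub.sum(axis=1).nlargest(30).index)])
    corr = sparcc(table, n_iterations=10, seed=1 + gi)
    corr = edge_significance(table, corr, n_permutations=1000, seed=1 + gi)
    net = backbone(mcode_cores(build_network(corr)))
    nets[g] = net
    n_core = sum(1 for v in net.graph.nodes if net.role_of(v) == "core")
    n_backbone = sum(d["backbone"] for *_, d in net.graph.edges(data=True))
    print(f"{g}: {net.graph.number_of_edges()} edges, "
          f"{n_core} core nodes, {n_backbone} backbone edges")

fg = functional_group(nets["HC"], nets["ESIN"], nets["ESCC"])
n_planted = len(set(fg.species) & set(anchors))
print(f"functional group: {len(fg.species)} species "
      f"(from {fg.provenance['n_common_edges']} common HC/ESIN edges), "
      f"{n_planted} of them planted block members")

# The functional-group species were planted with a carcinoma-stage
# abundance boost, so their summed relative abundance separates the
# carcinoma group from healthy controls:
rel = to_relative(FeatureTable(combined))
score = marker_scores(rel, fg.species, "functional_group")
samples = meta.samples_in("ESCC") + meta.samples_in("HC")
labels = pd.Series([1] * 35 + [0] * 35, index=samples)
print(f"functional-group marker, carcinoma vs healthy: "
      f"AUC = {roc_auc(score.loc[samples], labels).auc:.3f}")
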