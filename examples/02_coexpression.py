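"""Cluster the time-series curves and pull a C4 gene's co-expressed set.

Reproduces the expression stage: smoothing the seven de-etiolation time
points, SD-normalizing, k-means clustering, and the Z-score rule that
keeps only genes whose curves sit in the extreme lower tail of the
within-cluster distance distribution (Z < -1.644853, the 5% normal
quantile).  Runs in well under a minute.
"""

from c4recruit.expression import (build_curves, compute_fom, filter_expressed,
                                  kmeans_cluster, select_coexpressed)
from c4recruit.synth import SynthConfig, generate_dataset

dataset = generate_dataset(SynthConfig(seed=0))
expr = dataset.expr["A"]
expressed = filter_expressed(expr)          # mean RPKM strictly > 1
print(f"{len(expressed)} of {len(expr)} genes pass the expression filter")

curves_cluster = build_curves(expr.loc[expressed], mode="spline", center=True)
curves_dist = build_curves(expr.loc[expressed], mode="poly3", center=True)

fom = compute_fom(curves_cluster, [2, 4, 8], seed=0)
print("figure of merit by k (lower is better):")
print(fom.round(3).to_string())

clusters = kmeans_cluster(curves_cluster, 4, seed=0)
target = dataset.c4_genes[0]
co = select_coexpressed(target, clusters, curves_dist)
print(f"\nco-expressed partners of {target} "
      f"(cluster {clusters.labels[target]}):")
print(co.members.round(3).to_string())
# These are the genes whose motif content will be searched alongside the
# C4 gene itself; on the benchmark they are regulon members by design.
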