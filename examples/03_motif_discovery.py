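"""Run the three discovery engines on one gene list x segment class.

Extracts promoter segments for a C4 gene's co-expression list and runs
ZOOPS EM, exhaustive word enumeration against a first-order Markov
background, and the PWM-library affinity test — then merges them with
the cross-method (>= 2 engines) consensus rule.  Takes ~10 s.
"""

from c4recruit.compare import cross_method_consensus
from c4recruit.discovery import BackgroundModel
from c4recruit.expression import (build_curves, filter_expressed,
                                  kmeans_cluster, select_coexpressed)
from c4recruit.pipeline import PipelineConfig, discover_segment, _feature_db
from c4recruit.scanmap import extract_segments
from c4recruit.synth import SynthConfig, generate_dataset

synth = SynthConfig(seed=0)
dataset = generate_dataset(synth)
cfg = PipelineConfig(synth=synth, seed=0)

expr = dataset.expr["A"]
genes = filter_expressed(expr)
clusters = kmeans_cluster(build_curves(expr.loc[genes], "spline", center=True),
                          4, seed=0)
co = select_coexpressed(dataset.c4_genes[0], clusters,
                        build_curves(expr.loc[genes], "poly3", center=True))
gene_list = [dataset.c4_genes[0]] + co.genes

db = _feature_db(dataset.gff["A"])
prom_len = synth.segment_lengths["promoter"]
segments = {g: extract_segments(db, g, dataset.genomes["A"],
                                promoter_length=prom_len) for g in genes}
bg = BackgroundModel.fit([segments[g]["promoter"] for g in genes], "promoter")
fg = [segments[g]["promoter"] for g in gene_list]
bg_seqs = [segments[g]["promoter"] for g in genes[:40] if g not in gene_list]

hits = discover_segment(fg, bg, dataset.library, bg_seqs, cfg, seed=0)
for engine, engine_hits in hits.items():
    print(f"{engine}: "
          + (", ".join(f"{h.motif.consensus} (p={h.pvalue:.2g})"
                       for h in engine_hits) or "nothing"))

consensus = cross_method_consensus(hits, null_size=999, seed=0)
print("\ncross-method consensus (motifs found by >= 2 engines):")
for cm in consensus:
    print(f"  {cm.pwm.consensus} supported by {sorted(cm.engines)}")
planted = [s.pwm.consensus for s in dataset.motif_specs
           if s.target_segment == "promoter"]
print(f"\nplanted promoter motif(s) for comparison: {planted}")
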