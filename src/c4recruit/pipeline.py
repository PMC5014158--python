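"""End-to-end orchestration: expression -> orthology -> co-expression ->
segment extraction -> three-engine motif discovery -> cross-method /
cross-k / cross-species consensus -> recruitment calls.

The flow mirrors the published analysis design: genes are clustered at
two k values (a fine and a coarse clustering) and only motifs predicted
from both gene lists survive; motifs must be found by at least two of
the three discovery engines; conservation is assessed per ortholog pair
and segment class; and candidate recruited motifs must pass the
two-criterion test.  A random-gene negative control exercises the same
machinery on gene lists with no shared regulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import substream, substream_seed
from .compare import (ConsensusMotif, cross_k_consensus, cross_method_consensus,
                      cross_species_conservation, motifs_match)
from .discovery import (BackgroundModel, MotifHit, em_discover,
                        enrichment_test, library_enrichment, word_enumerate)
from .expression import (Z_THRESHOLD, build_curves, filter_expressed,
                         kmeans_cluster, read_expression_tsv,
                         select_coexpressed)
from .orthology import CallSet, reconcile_orthologs
from .pwm import PWM, read_meme, trim_low_ic_edges
from .recruitment import (PatternThresholds, call_recruited, classify_pattern,
                          segment_enrichment_p)
from .scanmap import SEGMENT_CLASSES, extract_segments
from .synth import SynthConfig, SynthDataset, generate_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis.

    ``k_values`` defaults to (n_clusters, n_clusters // 2) for synthetic
    runs: the published k=80/k=30 presume genome-scale gene counts, so k
    scales with the number of planted clusters instead.
    """

    synth: SynthConfig | None = None
    data_dir: str | None = None
    c4_genes: list | None = None        # required for file-based input
    k_values: tuple | None = None
    z_threshold: float = Z_THRESHOLD
    enrichment_alpha: float = 0.05
    match_alpha: float = 0.01
    max_mm: int = 2
    null_size: int = 999                # alignment-null shuffles in-pipeline
    em_widths: tuple = (6, 8)
    em_min_ic: float = 0.8              # bits/column motif-quality floor
    word_widths: tuple = (6, 8)
    word_max_mm: int = 0                # exact words at desk-scale lengths
    top_words: int = 5                  # per width
    n_library_bg: int = 40
    promoter_length: int | None = None
    seed: int = 0

    def __post_init__(self):
        for a in (self.enrichment_alpha, self.match_alpha):
            if not 0 < a < 1:
                raise ValueError("alphas must lie in (0, 1)")
        if self.k_values is not None and len(self.k_values) < 2:
            raise ValueError("need at least two k values for cross-k consensus")


@dataclass
class RunReport:
    config: PipelineConfig
    k_values: tuple
    n_expressed: dict
    orthologs: list
    targets: dict                       # species -> list of target genes
    coexpression: dict                  # (species, target, k) -> gene list
    consensus: dict                     # (species, target, segment, k) -> [ConsensusMotif]
    overlap: dict                       # (species, target, segment) -> [ConsensusMotif]
    cross_k_table: pd.DataFrame         # per (species, segment): total/mapped/rate
    conservation: pd.DataFrame
    conservation_details: list
    patterns: list
    recruitment_calls: list
    stage_counts: dict = field(default_factory=dict)

    def recruited(self) -> list:
        return [c for c in self.recruitment_calls if c.verdict]

    def summary(self) -> dict:
        return {
            "k_values": list(self.k_values),
            "n_expressed": dict(self.n_expressed),
            "n_ortholog_pairs": len(self.orthologs),
            "n_consensus_motifs": int(sum(len(v) for v in self.consensus.values())),
            "n_overlap_motifs": int(sum(len(v) for v in self.overlap.values())),
            "n_recruited_calls": len(self.recruited()),
            "stage_counts": dict(self.stage_counts),
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cross_k_table.to_csv(outdir / "cross_k.tsv", sep="\t")
        self.conservation.to_csv(outdir / "conservation.tsv", sep="\t")
        pd.DataFrame([vars(p) for p in self.patterns]).to_csv(
            outdir / "patterns.tsv", sep="\t", index=False)
        calls = pd.DataFrame([{
            "motif": c.motif_name, "consensus": c.consensus,
            "c4_gene": c.c4_gene, "segment": c.segment,
            "verdict": c.verdict, "criterion1": c.criterion1,
            "criterion2": c.criterion2,
            "siteA_count": c.siteA_count, "siteB_count": c.siteB_count,
            "coexpressed_support": ",".join(c.coexpressed_support)}
            for c in self.recruitment_calls])
        calls.to_csv(outdir / "recruitment_calls.tsv", sep="\t", index=False)
        lines = ["# Run summary", ""]
        for key, val in self.summary().items():
            lines.append(f"- {key}: {val}")
        (outdir / "summary.md").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# input handling
# ---------------------------------------------------------------------------

def load_dataset_from_dir(data_dir) -> dict:
    """Load the file layout written by SynthDataset.write (or equivalent
    user-provided data): genome FASTA + GFF3 + expression TSV per species,
    call-set TSVs, optional motif library."""
    import pyfaidx
    d = Path(data_dir)
    out = {"genomes": {}, "gff": {}, "expr": {}, "callsets": [], "library": []}
    for sp in ("A", "B"):
        out["genomes"][sp] = pyfaidx.Fasta(str(d / f"genome{sp}.fa"))
        out["gff"][sp] = (d / f"models{sp}.gff3").read_text()
        out["expr"][sp] = read_expression_tsv(d / f"expr{sp}.tsv")
    for rank, path in enumerate(sorted(d.glob("callset_*.tsv")), 1):
        df = pd.read_csv(path, sep="\t")
        method = path.stem.replace("callset_", "")
        rank_val = int(df["rank"].iloc[0]) if "rank" in df else rank
        out["callsets"].append(CallSet(method=method, rank=rank_val, pairs=df))
    lib = d / "library.meme"
    if lib.exists():
        out["library"] = read_meme(lib)
    return out


def _feature_db(gff_text: str):
    import gffutils
    return gffutils.create_db(gff_text, ":memory:", from_string=True,
                              merge_strategy="create_unique")


# ---------------------------------------------------------------------------
# discovery on one gene list x segment class
# ---------------------------------------------------------------------------

def discover_segment(fg: list[str], bg_model: BackgroundModel,
                     library: list[PWM], bg_seqs: list[str],
                     cfg: PipelineConfig, seed: int) -> dict[str, list[MotifHit]]:
    """Run the three engines on one foreground sequence set."""
    hits: dict[str, list[MotifHit]] = {"em": [], "word": [], "library": []}
    usable = [s for s in fg if s]
    if len(usable) < 2:
        return hits
    for width in cfg.em_widths:
        if sum(len(s) >= width for s in usable) < 2:
            continue
        pwm = em_discover(usable, width, seed=substream_seed(seed, "em", width),
                          n_seeds=5, bg_model=bg_model)
        pwm = trim_low_ic_edges(pwm)
        if pwm.information_content().mean() < cfg.em_min_ic:
            continue
        # engine-level enrichment of the learned motif vs genome background
        total_hits = 0
        total_windows = 0
        for s in usable:
            _, h = segment_enrichment_p(pwm, s, bg_model, max_mm=cfg.max_mm)
            total_hits += h
            total_windows += max(len(s) - width + 1, 0)
        rate = bg_model.scan_match_prob(pwm.consensus,
                                        _degen(pwm), max_mm=cfg.max_mm)
        rate = float(np.clip(rate, 1e-15, 1 - 1e-15))
        p = enrichment_test(total_hits, max(total_windows, 1), rate)
        # E-value over the candidate-motif space: the learned motif is the
        # maximizer of over-representation, so its raw p is winner-cursed
        evalue = p * float(4 ** width)
        if evalue <= cfg.enrichment_alpha:
            hits["em"].append(MotifHit(motif=pwm, engine="em", pvalue=p,
                                       extras={"sites": total_hits,
                                               "evalue": evalue}))
    words = word_enumerate(usable, bg_model, widths=cfg.word_widths,
                           max_word_mm=cfg.word_max_mm,
                           alpha=cfg.enrichment_alpha)
    for width in cfg.word_widths:
        sub = words[(words["width"] == width)
                    & (words["evalue"] <= cfg.enrichment_alpha)]
        for row in sub.head(cfg.top_words).itertuples(index=False):
            pwm = PWM.from_word(row.word, name=row.word)
            hits["word"].append(MotifHit(motif=pwm, engine="word",
                                         pvalue=float(row.pvalue),
                                         extras={"support": int(row.support),
                                                 "evalue": float(row.evalue)}))
    if library and bg_seqs:
        hits["library"] = library_enrichment(usable, bg_seqs, library,
                                             alpha=cfg.enrichment_alpha)
    return hits


def _degen(pwm: PWM) -> str:
    from .scanmap import degenerate_consensus
    return degenerate_consensus(pwm)


# ---------------------------------------------------------------------------
# main pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, dataset: SynthDataset | None = None,
                 outdir=None) -> RunReport:
    """Execute the full analysis; deterministic given cfg.seed."""
    seed = cfg.seed
    if dataset is None:
        if cfg.synth is not None:
            dataset = generate_dataset(cfg.synth)
        elif cfg.data_dir is None:
            raise ValueError("need a synthetic config, a dataset, or a data_dir")

    if dataset is not None:
        genomes = dataset.genomes
        gffs = dataset.gff
        exprs = dataset.expr
        callsets = dataset.callsets
        library = dataset.library
        c4_genes = cfg.c4_genes or dataset.c4_genes
        n_clusters = dataset.config.n_clusters
        promoter_length = cfg.promoter_length or \
            dataset.config.segment_lengths["promoter"]
    else:
        loaded = load_dataset_from_dir(cfg.data_dir)
        genomes, gffs, exprs = loaded["genomes"], loaded["gff"], loaded["expr"]
        callsets, library = loaded["callsets"], loaded["library"]
        if not cfg.c4_genes:
            raise ValueError("c4_genes must be given for file-based input")
        c4_genes = cfg.c4_genes
        n_clusters = 8
        promoter_length = cfg.promoter_length or 3000

    k_values = tuple(cfg.k_values) if cfg.k_values else \
        (n_clusters, max(2, n_clusters // 2))
    k_hi, k_lo = k_values[0], k_values[1]

    # ---- expression ----
    expressed, curves_cluster, curves_dist, clusters = {}, {}, {}, {}
    for sp in ("A", "B"):
        genes = filter_expressed(exprs[sp])
        expressed[sp] = genes
        sub = exprs[sp].loc[genes]
        curves_cluster[sp] = build_curves(sub, mode="spline", center=True)
        curves_dist[sp] = build_curves(sub, mode="poly3", center=True)
        clusters[sp] = {k: kmeans_cluster(curves_cluster[sp], k,
                                          seed=substream_seed(seed, "kmeans", sp, k))
                        for k in k_values}

    # ---- orthology ----
    orthos = reconcile_orthologs(callsets, exprs["A"], exprs["B"])
    ortho_map = {p.geneA: p.geneB for p in orthos}

    targets = {"A": list(c4_genes),
               "B": [ortho_map[g] for g in c4_genes if g in ortho_map]}
    pair_list = [(g, ortho_map[g]) for g in c4_genes if g in ortho_map]

    # ---- segments & backgrounds ----
    segments: dict[str, dict] = {}
    bg_models: dict[str, dict] = {}
    for sp in ("A", "B"):
        db = _feature_db(gffs[sp])
        segs = {}
        for gene in exprs[sp].index:
            try:
                segs[gene] = extract_segments(db, gene, genomes[sp],
                                              promoter_length=promoter_length)
            except ValueError as exc:
                log.warning("segment extraction failed for %s: %s", gene, exc)
        segments[sp] = segs
        bg_models[sp] = {
            cls: BackgroundModel.fit([s[cls] for s in segs.values() if s[cls]],
                                     segment_class=cls)
            for cls in SEGMENT_CLASSES}

    # ---- co-expression + discovery ----
    coexpression, consensus = {}, {}
    stage_counts = {"discovery_runs": 0, "engine_hits": 0}
    for sp in ("A", "B"):
        for target in targets[sp]:
            for k in k_values:
                if target not in clusters[sp][k].labels.index:
                    log.warning("target %s not clustered (species %s)", target, sp)
                    continue
                co = select_coexpressed(target, clusters[sp][k],
                                        curves_dist[sp],
                                        z_threshold=cfg.z_threshold)
                coexpression[(sp, target, k)] = co
                gene_list = [target] + co.genes
                for seg_cls in SEGMENT_CLASSES:
                    fg = [segments[sp][g][seg_cls] for g in gene_list
                          if g in segments[sp] and segments[sp][g][seg_cls]]
                    rng = substream(seed, "libbg", sp, target, k, seg_cls)
                    pool = [g for g in expressed[sp]
                            if g not in gene_list and g in segments[sp]
                            and segments[sp][g][seg_cls]]
                    pick = rng.choice(len(pool),
                                      size=min(cfg.n_library_bg, len(pool)),
                                      replace=False) if pool else []
                    bg_seqs = [segments[sp][pool[i]][seg_cls] for i in pick]
                    hits = discover_segment(
                        fg, bg_models[sp][seg_cls], library, bg_seqs, cfg,
                        seed=substream_seed(seed, "discover", sp, target, k,
                                            seg_cls))
                    stage_counts["discovery_runs"] += 1
                    stage_counts["engine_hits"] += sum(len(v) for v in hits.values())
                    cms = cross_method_consensus(
                        hits, match_alpha=cfg.match_alpha,
                        null_size=cfg.null_size,
                        seed=substream_seed(seed, "consensus", sp, target, k,
                                            seg_cls),
                        species=sp, gene=target, segment=seg_cls)
                    for cm in cms:
                        cm.k_runs = frozenset([k])
                    consensus[(sp, target, seg_cls, k)] = cms

    # ---- cross-k ----
    overlap = {}
    xk_rows = []
    for sp in ("A", "B"):
        for seg_cls in SEGMENT_CLASSES:
            total = mapped = 0
            for target in targets[sp]:
                hi = consensus.get((sp, target, seg_cls, k_hi), [])
                lo = consensus.get((sp, target, seg_cls, k_lo), [])
                res = cross_k_consensus(hi, lo, match_alpha=cfg.match_alpha,
                                        null_size=cfg.null_size,
                                        seed=substream_seed(seed, "crossk", sp,
                                                            target, seg_cls))
                overlap[(sp, target, seg_cls)] = res["overlap"]
                total += res["total"]
                mapped += res["mapped"]
            rate = round(100.0 * mapped / total, 1) if total else None
            xk_rows.append({"species": sp, "segment": seg_cls,
                            "total": total, "mapped": mapped, "rate": rate})
    cross_k_table = pd.DataFrame(xk_rows).set_index(["species", "segment"])

    # ---- cross-species conservation ----
    motifsA = {(g, s): overlap.get(("A", g, s), []) for g, _ in pair_list
               for s in SEGMENT_CLASSES}
    motifsB = {(g, s): overlap.get(("B", g, s), []) for _, g in pair_list
               for s in SEGMENT_CLASSES}
    conservation, details = cross_species_conservation(
        motifsA, motifsB, pair_list, list(SEGMENT_CLASSES),
        match_alpha=cfg.match_alpha, null_size=cfg.null_size,
        seed=substream_seed(seed, "conservation"))

    # ---- expression-pattern classes ----
    patterns = []
    for geneA, geneB in pair_list:
        try:
            patterns.append(classify_pattern(
                geneA, geneB, exprs["A"].loc[geneA], exprs["B"].loc[geneB],
                clusters["A"][k_hi], clusters["B"][k_hi],
                thresholds=PatternThresholds(),
                seed=substream_seed(seed, "pattern", geneA)))
        except KeyError as exc:
            log.warning("pattern classification skipped: %s", exc)

    # ---- recruitment calls ----
    calls = []
    for geneA, geneB in pair_list:
        co = coexpression.get(("A", geneA, k_hi))
        if co is None:
            continue
        segsB = segments["B"].get(geneB)
        for seg_cls in SEGMENT_CLASSES:
            for cm in overlap.get(("A", geneA, seg_cls), []):
                calls.append(call_recruited(
                    cm, geneA, co, segments["A"], segsB, seg_cls,
                    bg_models["A"][seg_cls],
                    enrichment_alpha=cfg.enrichment_alpha, max_mm=cfg.max_mm))

    report = RunReport(config=cfg, k_values=k_values,
                       n_expressed={sp: int(len(expressed[sp])) for sp in expressed},
                       orthologs=orthos, targets=targets,
                       coexpression={key: co.genes for key, co in coexpression.items()},
                       consensus=consensus, overlap=overlap,
                       cross_k_table=cross_k_table,
                       conservation=conservation,
                       conservation_details=details,
                       patterns=patterns, recruitment_calls=calls,
                       stage_counts=stage_counts)
    if outdir is not None:
        report.write(outdir)
    return report


# ---------------------------------------------------------------------------
# negative control
# ---------------------------------------------------------------------------

def run_negative_control(cfg: PipelineConfig, n_sets: int = 3,
                         set_size: int = 50, seed: int | None = None) -> dict:
    """Random-gene-list control on background-only sequence.

    Rebuilds the synthetic dataset without planted motifs, samples random
    gene lists, runs all three engines plus the cross-method consensus,
    and reports the consensus motif count per set (expected: none).
    """
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    seed = cfg.seed if seed is None else seed
    if cfg.synth is None:
        raise ValueError("negative control needs a synthetic config")
    base = cfg.synth
    synth_bg = SynthConfig(seed=base.seed, n_genes_per_species=base.n_genes_per_species,
                           n_clusters=base.n_clusters, noise_sd=base.noise_sd,
                           n_c4_genes=base.n_c4_genes,
                           segment_lengths=dict(base.segment_lengths),
                           planted_motifs=[],
                           ortholog_conflict_rate=base.ortholog_conflict_rate,
                           many_to_many_rate=base.many_to_many_rate, gc=base.gc)
    ds = generate_dataset(synth_bg)
    genes = list(filter_expressed(ds.expr["A"]))
    if len(genes) < set_size:
        raise ValueError("gene universe smaller than set_size")
    db = _feature_db(ds.gff["A"])
    promoter_length = ds.config.segment_lengths["promoter"]
    segs = {g: extract_segments(db, g, ds.genomes["A"],
                                promoter_length=promoter_length)
            for g in genes}
    bg_models = {cls: BackgroundModel.fit([s[cls] for s in segs.values() if s[cls]],
                                          segment_class=cls)
                 for cls in SEGMENT_CLASSES}
    rng = substream(seed, "negctrl")
    per_set = []
    for rep in range(n_sets):
        chosen = [genes[i] for i in rng.choice(len(genes), size=set_size,
                                               replace=False)]
        count = 0
        for seg_cls in SEGMENT_CLASSES:
            fg = [segs[g][seg_cls] for g in chosen if segs[g][seg_cls]]
            pool = [g for g in genes if g not in chosen and segs[g][seg_cls]]
            pick = rng.choice(len(pool), size=min(cfg.n_library_bg, len(pool)),
                              replace=False)
            bg_seqs = [segs[pool[i]][seg_cls] for i in pick]
            hits = discover_segment(fg, bg_models[seg_cls], ds.library, bg_seqs,
                                    cfg, seed=substream_seed(seed, "negdisc",
                                                             rep, seg_cls))
            cms = cross_method_consensus(hits, match_alpha=cfg.match_alpha,
                                         null_size=cfg.null_size,
                                         seed=substream_seed(seed, "negcons",
                                                             rep, seg_cls))
            count += len(cms)
        per_set.append(count)
    return {"n_sets": n_sets, "set_size": set_size,
            "consensus_per_set": per_set, "total": int(sum(per_set))}


# ---------------------------------------------------------------------------
# scoring against planted truth
# ---------------------------------------------------------------------------

def score_recruitment(report: RunReport, dataset: SynthDataset,
                      match_alpha: float = 0.01, null_size: int = 999,
                      seed: int = 0) -> dict:
    """Precision/recall of recruited-motif calls against the planted truth.

    A positive call is correct if its PWM matches a planted recruited
    motif of the same segment class (alignment p <= match_alpha).  Recall
    counts (recruited spec, C4 gene) combinations recovered.
    """
    recruited_specs = [s for s in dataset.motif_specs if s.recruited]
    calls = report.recruited()
    dedup = {}
    for c in calls:
        dedup.setdefault((c.c4_gene, c.segment, c.consensus), c)
    calls = list(dedup.values())

    def call_matches(call, spec):
        if call.segment != spec.target_segment:
            return False
        pwm = call.pwm if call.pwm is not None else PWM.from_word(call.consensus)
        ok, _ = motifs_match(pwm, spec.pwm, match_alpha=match_alpha,
                             null_size=null_size, seed=seed)
        return ok

    tp = sum(1 for c in calls if any(call_matches(c, s) for s in recruited_specs))
    precision = tp / len(calls) if calls else float("nan")
    expected = [(s.name, g) for s in recruited_specs for g in dataset.c4_genes]
    hit = 0
    for s in recruited_specs:
        for g in dataset.c4_genes:
            if any(c.c4_gene == g and call_matches(c, s) for c in calls):
                hit += 1
    recall = hit / len(expected) if expected else float("nan")
    return {"n_calls": len(calls), "true_positive_calls": tp,
            "precision": precision, "recall": recall,
            "n_expected": len(expected)}


__all__ = ["PipelineConfig", "RunReport", "run_pipeline",
           "run_negative_control", "score_recruitment", "discover_segment",
           "load_dataset_from_dir"]
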