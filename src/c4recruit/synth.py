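"""Synthetic two-species benchmark with planted ground truth.

The generator emulates the structure of a two-species (C4 vs C3)
de-etiolation study at desk scale: two genomes of single-chromosome
gene arrays with first-order Markov background sequence, gene models
with 5'UTR / 3-exon CDS / two introns / 3'UTR, seven-time-point
expression matrices built from cluster archetype curves plus Gaussian
noise, several deliberately imperfect ortholog call-sets, and planted
PWM motif sites with a complete truth table.

"Recruited" motif specs are planted in species A only, and their chance
background matches are scrubbed from the species-B orthologs of the C4
genes, so the end-to-end recruitment caller has an exact ground truth.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import IUPAC_SETS, revcomp, substream
from .expression import TIMEPOINT_HOURS, TIMEPOINT_LABELS
from .orthology import CallSet
from .pwm import PWM, write_meme
from .scanmap import SPACER, degenerate_consensus, scan_consensus

log = logging.getLogger(__name__)

PAD = 100  # inter-gene padding beyond the promoter region
BODY_PARTS = ("utr5", "cds1", "intron1", "cds2", "intron2", "cds3", "utr3")
PARTS_OF = {"promoter": ("promoter",), "utr5": ("utr5",), "utr3": ("utr3",),
            "cds": ("cds1", "cds2", "cds3"), "intron": ("intron1", "intron2")}


@dataclass
class PlantedMotifSpec:
    pwm: PWM
    target_segment: str             # promoter | utr5 | utr3 | cds | intron
    host_gene_fraction: float = 0.8
    recruited: bool = False
    name: str = ""
    #: planted site copies per host gene; short (6-bp) elements occur at
    #: multi-copy densities in real segments, and need to, to stand out
    #: against the background rate of a 6-mer
    sites_per_gene: int = 1

    def __post_init__(self):
        if not 6 <= self.pwm.width <= 12:
            raise ValueError("planted PWM width must be in [6, 12]")
        if self.sites_per_gene < 1:
            raise ValueError("sites_per_gene must be >= 1")
        if not 0 <= self.host_gene_fraction <= 1:
            raise ValueError("host_gene_fraction must be a probability")
        if self.target_segment not in PARTS_OF:
            raise ValueError(f"unknown segment class {self.target_segment!r}")
        if not self.name:
            self.name = self.pwm.name or f"motif_{self.pwm.consensus}"


def _random_complex_pwm(width: int, rng: np.random.Generator,
                        name: str = "") -> PWM:
    """A random sharp PWM whose consensus passes a complexity floor
    (>= 3 distinct bases, dominant base on at most half the positions).

    A low-complexity motif is indistinguishable from its own column
    shuffle, so shuffle-null matching could never certify it; curated
    motif catalogs are filtered the same way.
    """
    for _ in range(500):
        pwm = PWM.random(width, rng, name=name)
        cons = pwm.consensus
        counts = sorted((cons.count(b) for b in set(cons)), reverse=True)
        max_run = max(len(list(g)) for _, g in itertools.groupby(cons))
        if len(counts) >= 3 and counts[0] <= width // 2 and max_run <= 2:
            return pwm
    raise RuntimeError("could not sample a complex PWM")  # pragma: no cover


def default_planted_motifs(seed: int = 0) -> list[PlantedMotifSpec]:
    """Four planted motifs: two recruited (8-mers) and two shared."""
    rng = substream(seed, "planted-motifs")
    return [
        PlantedMotifSpec(_random_complex_pwm(8, rng, name="REC1"), "promoter",
                         host_gene_fraction=0.8, recruited=True, name="REC1"),
        PlantedMotifSpec(_random_complex_pwm(8, rng, name="REC2"), "utr5",
                         host_gene_fraction=0.8, recruited=True, name="REC2"),
        PlantedMotifSpec(_random_complex_pwm(6, rng, name="SHA1"), "cds",
                         host_gene_fraction=0.8, recruited=False, name="SHA1",
                         sites_per_gene=3),
        PlantedMotifSpec(_random_complex_pwm(8, rng, name="SHA2"), "utr3",
                         host_gene_fraction=0.8, recruited=False, name="SHA2"),
    ]


def _default_segment_lengths() -> dict:
    return {"promoter": 500, "utr5": 150, "utr3": 150, "cds": 600, "intron": 200}


@dataclass
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    Each expression cluster holds a small co-regulated *regulon*
    (including the C4 genes) whose members track the cluster archetype
    almost exactly, plus a bulk of genes sharing the broad shape but
    carrying a large systematic gene-specific deviation — mirroring real
    transcriptomes, where tight co-expression reflects shared regulation.
    Planted motif sites go into regulon genes, the premise the
    co-expression-based motif search relies on.
    """

    seed: int = 0
    n_genes_per_species: int = 480
    n_clusters: int = 4
    n_timepoints: int = 7
    noise_sd: float = 0.04              # iid measurement noise, normalized scale
    n_c4_genes: int = 2
    regulon_size: int = 12              # co-regulated genes per cluster
    regulon_dispersion: tuple = (0.01, 0.06)
    bulk_dispersion: tuple = (0.7, 1.0)
    dispersion_scale: float = 4.0       # systematic-deviation magnitude (SD units)
    segment_lengths: dict = field(default_factory=_default_segment_lengths)
    planted_motifs: list | None = None
    ortholog_conflict_rate: float = 0.05
    many_to_many_rate: float = 0.05
    gc: float = 0.44

    def __post_init__(self):
        if self.planted_motifs is None:
            self.planted_motifs = default_planted_motifs(self.seed)
        if self.n_c4_genes > self.n_genes_per_species:
            raise ValueError("n_c4_genes cannot exceed n_genes_per_species")
        if any(v <= 0 for v in self.segment_lengths.values()):
            raise ValueError("all segment lengths must be positive")
        for p in (self.ortholog_conflict_rate, self.many_to_many_rate):
            if not 0 <= p <= 1:
                raise ValueError("rates must be probabilities in [0, 1]")
        if self.noise_sd < 0 or self.dispersion_scale < 0:
            raise ValueError("noise and dispersion scales must be nonnegative")
        if self.regulon_size * self.n_clusters > self.n_genes_per_species:
            raise ValueError("regulons cannot exceed the cluster size")
        if self.n_timepoints != len(TIMEPOINT_HOURS):
            raise ValueError("the benchmark uses the seven standard time points")
        for spec in self.planted_motifs:
            if spec.pwm.width > self._plantable_length(spec.target_segment):
                raise ValueError(
                    f"segment {spec.target_segment} too short for planted "
                    f"motif {spec.name} (width {spec.pwm.width})")

    def _plantable_length(self, segment: str) -> int:
        L = self.segment_lengths[segment]
        if segment == "cds":
            return L // 3            # a site must fit inside one CDS part
        if segment == "intron":
            return L // 2
        return L

    def part_lengths(self) -> dict:
        u5, u3 = self.segment_lengths["utr5"], self.segment_lengths["utr3"]
        C, I = self.segment_lengths["cds"], self.segment_lengths["intron"]
        c1 = c2 = C // 3
        return {"promoter": self.segment_lengths["promoter"],
                "utr5": u5, "cds1": c1, "intron1": I // 2, "cds2": c2,
                "intron2": I - I // 2, "cds3": C - c1 - c2, "utr3": u3}

    def part_layout(self) -> dict:
        """Local (start, end) offsets of each gene-body part, 5'->3'."""
        lens = self.part_lengths()
        pos, cur = {}, 0
        for name in BODY_PARTS:
            pos[name] = (cur, cur + lens[name])
            cur += lens[name]
        pos["_body"] = (0, cur)
        return pos


# ---------------------------------------------------------------------------
# expression archetypes
# ---------------------------------------------------------------------------

ARCHETYPE_WIDTH_H = 7.5


def archetype_curves(n_clusters: int,
                     hours: np.ndarray = TIMEPOINT_HOURS) -> np.ndarray:
    """SD-normalized cluster archetype curves over the sampling times.

    Archetypes are Gaussian induction bumps centered evenly across the
    24 h course.  The extreme phases are effectively monotone-down (peak
    at 0 h) and monotone-up (peak at 24 h), with peaked and phase-shifted
    shapes in between — the families seen in de-etiolation time courses.
    Neighboring phases are similar, so a coarser clustering merges
    adjacent shapes rather than opposites.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    centers = np.linspace(0.0, 24.0, n_clusters) if n_clusters > 1 else [12.0]
    out = np.array([np.exp(-((hours - c) ** 2) / (2 * ARCHETYPE_WIDTH_H ** 2))
                    for c in centers])
    return out / out.std(axis=1, keepdims=True)


def _orth_cubic_sampler(arch_vals: np.ndarray,
                        hours: np.ndarray = TIMEPOINT_HOURS):
    """Sampler of systematic per-gene shape deviations.

    Deviations live in cubic function space (so degree-3 smoothing
    preserves them exactly), have unit centered norm on the evaluation
    grid, and are orthogonal to the archetype's own cubic fit (so they
    change a gene's curve *shape* without modulating its overall
    variance, keeping SD-normalization stable).
    """
    from .expression import EVAL_GRID
    poly = np.polynomial.polynomial
    ac = poly.polyfit(hours, arch_vals, 3)
    pa = poly.polyval(EVAL_GRID, ac)
    pa = pa - pa.mean()
    pa = pa / np.linalg.norm(pa)

    def sample(rng: np.random.Generator) -> np.ndarray:
        for _ in range(300):
            coef = rng.normal(0.0, 1.0, 4) / np.array([1.0, 24.0, 24.0 ** 2,
                                                       24.0 ** 3])
            g = poly.polyval(EVAL_GRID, coef)
            g = g - g.mean()
            g = g - (g @ pa) * pa
            nrm = np.linalg.norm(g)
            if nrm < 1e-6:
                continue
            hv = poly.polyval(hours, poly.polyfit(EVAL_GRID, g / nrm, 3))
            # reject ill-conditioned cubics that spike at the sampling times
            if 0.02 <= np.abs(hv).max() <= 0.8:
                return hv
        raise RuntimeError("could not sample an admissible shape deviation")

    return sample


# ---------------------------------------------------------------------------
# background sequence
# ---------------------------------------------------------------------------

def background_chain(gc: float) -> tuple[np.ndarray, np.ndarray]:
    """First-order Markov background: stationary composition at the given
    GC content with mild dinucleotide autocorrelation."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    T = 0.75 * np.tile(p, (4, 1)) + 0.25 * np.eye(4)
    return p, T


def _sample_markov(length: int, init: np.ndarray, T: np.ndarray,
                   rng: np.random.Generator) -> str:
    if length <= 0:
        return ""
    cum = np.cumsum(T, axis=1)
    cum0 = np.cumsum(init)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    prev = int(np.searchsorted(cum0, u[0]))
    out[0] = prev
    for i in range(1, length):
        row = cum[prev]
        x = u[i]
        prev = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        out[i] = prev
    return "".join("ACGT"[c] for c in out)


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class SynthDataset:
    config: SynthConfig
    genomes: dict                   # species -> {chrom: sequence}
    gff: dict                       # species -> GFF3 text
    expr: dict                      # species -> DataFrame genes x 7
    callsets: list
    truth: pd.DataFrame             # motif_id, species, gene_id, segment, offset, strand
    library: list                   # PWMs (planted + decoys)
    c4_genes: list                  # species-A C4 gene ids
    orthologs: dict                 # true geneA -> geneB map
    cluster_truth: dict             # species -> Series gene -> cluster index
    motif_specs: list
    regulon_indices: list = field(default_factory=list)

    def feature_db(self, species: str):
        import gffutils
        return gffutils.create_db(self.gff[species], ":memory:",
                                  from_string=True,
                                  merge_strategy="create_unique")

    def write(self, outdir) -> dict:
        """Write every artifact as deterministic text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sp in ("A", "B"):
            fa = outdir / f"genome{sp}.fa"
            with open(fa, "w") as fh:
                for chrom in sorted(self.genomes[sp]):
                    fh.write(f">{chrom}\n")
                    seq = self.genomes[sp][chrom]
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i:i + 80] + "\n")
            paths[f"genome{sp}"] = fa
            gff = outdir / f"models{sp}.gff3"
            gff.write_text(self.gff[sp])
            paths[f"models{sp}"] = gff
            ex = outdir / f"expr{sp}.tsv"
            self.expr[sp].to_csv(ex, sep="\t", float_format="%.4f")
            paths[f"expr{sp}"] = ex
        for cs in self.callsets:
            p = outdir / f"callset_{cs.method}.tsv"
            cs.pairs.to_csv(p, sep="\t", index=False, float_format="%.3f")
            paths[f"callset_{cs.method}"] = p
        tp = outdir / "truth.tsv"
        self.truth.to_csv(tp, sep="\t", index=False)
        paths["truth"] = tp
        lib = outdir / "library.meme"
        write_meme(self.library, lib)
        paths["library"] = lib
        return paths


# ---------------------------------------------------------------------------
# site planting
# ---------------------------------------------------------------------------

def _concat_starts(parts: tuple, lens: dict) -> dict:
    """Start offset of each part inside the spacer-joined segment string."""
    starts, cur = {}, 0
    for p in parts:
        starts[p] = cur
        cur += lens[p] + len(SPACER)
    return starts


def _plant_site(parts_seq: dict, lens: dict, spec: PlantedMotifSpec,
                occupied: dict, rng: np.random.Generator):
    """Insert one sampled site into a random free slot of the target
    segment class; returns (offset-in-concatenated-segment, strand)."""
    seg_parts = PARTS_OF[spec.target_segment]
    starts = _concat_starts(seg_parts, lens)
    w = spec.pwm.width
    allowed = [IUPAC_SETS[c] for c in degenerate_consensus(spec.pwm)]
    site = spec.pwm.sample_site(rng, allowed=allowed)
    strand = "+" if rng.random() < 0.5 else "-"
    inserted = site if strand == "+" else revcomp(site)
    occ = occupied.setdefault(spec.target_segment, [])
    for _ in range(60):
        part = seg_parts[int(rng.integers(0, len(seg_parts)))]
        if lens[part] < w:
            continue
        off = int(rng.integers(0, lens[part] - w + 1))
        goff = starts[part] + off
        if any(not (goff + w <= s or e <= goff) for s, e in occ):
            continue
        occ.append((goff, goff + w))
        s = parts_seq[part]
        parts_seq[part] = s[:off] + inserted + s[off + w:]
        return goff, strand
    log.warning("no free slot for %s in %s", spec.name, spec.target_segment)
    return None


def _scrub_gene(parts_seq: dict, lens: dict, recruited_specs: list,
                occupied: dict, rng: np.random.Generator) -> None:
    """Remove chance matches of recruited motifs from one gene's segments
    (applied to the species-B orthologs of the C4 genes).

    Flips one base per chance match to a base outside the degenerate set,
    never touching an interval where a shared motif site was planted.
    """
    for spec in recruited_specs:
        cons = spec.pwm.consensus
        degen = degenerate_consensus(spec.pwm)
        for seg_class, seg_parts in PARTS_OF.items():
            starts = _concat_starts(seg_parts, lens)
            occ = occupied.get(seg_class, [])
            for part in seg_parts:
                for _ in range(20):  # until this part is clean
                    hits = scan_consensus(parts_seq[part], cons, degen, max_mm=2)
                    hits = [h for h in hits if not any(
                        starts[part] + h.offset < e and
                        s < starts[part] + h.offset + spec.pwm.width
                        for s, e in occ)]
                    if not hits:
                        break
                    h = hits[0]
                    pos = h.offset + spec.pwm.width // 2
                    col = spec.pwm.width // 2
                    bad = (IUPAC_SETS[degen[col]] if h.strand == "+"
                           else {revcomp(b) for b in
                                 IUPAC_SETS[degen[spec.pwm.width - 1 - col]]})
                    choices = [b for b in "ACGT"
                               if b not in bad and b != parts_seq[part][pos]]
                    new = choices[int(rng.integers(0, len(choices)))]
                    s = parts_seq[part]
                    parts_seq[part] = s[:pos] + new + s[pos + 1:]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_dataset(config: SynthConfig, outdir=None) -> SynthDataset:
    """Generate the full two-species benchmark; deterministic in the seed."""
    cfg = config
    layout = cfg.part_layout()
    lens = cfg.part_lengths()
    P = lens["promoter"]
    init, T = background_chain(cfg.gc)
    n = cfg.n_genes_per_species
    arch = archetype_curves(cfg.n_clusters)

    cluster_of = {i: i % cfg.n_clusters for i in range(n)}
    # C4 genes all sit in cluster 0 (indices 0, n_clusters, 2*n_clusters, ...)
    c4_indices = [i * cfg.n_clusters for i in range(cfg.n_c4_genes)]
    c4_genes = [f"gA{i:04d}" for i in c4_indices]
    recruited_specs = [s for s in cfg.planted_motifs if s.recruited]

    # co-regulated regulon per cluster (same gene indices in both species:
    # orthologs share their regulon membership); C4 genes are regulon members
    regulon: set = set(c4_indices)
    for cl in range(cfg.n_clusters):
        members = [i for i in range(n) if cluster_of[i] == cl]
        need = cfg.regulon_size - sum(1 for i in members if i in regulon)
        regulon.update([i for i in members if i not in regulon][:max(0, need)])

    # host genes per motif: sampled from the cluster-0 regulon — the motif
    # is the cause of the shared regulation; decided once and shared across
    # species so the B orthologs carry the same (non-recruited) elements
    host_rng = substream(cfg.seed, "hosts")
    regulon0 = sorted(i for i in regulon if cluster_of[i] == 0)
    hosts: dict[str, set] = {}
    for spec in cfg.planted_motifs:
        chosen = set(c4_indices)
        for i in regulon0:
            if i not in chosen and host_rng.random() < spec.host_gene_fraction:
                chosen.add(i)
        hosts[spec.name] = chosen

    genomes, gffs, exprs, truth_rows = {}, {}, {}, []
    cluster_truth = {}

    for sp in ("A", "B"):
        seq_rng = substream(cfg.seed, "sequence", sp)
        plant_rng = substream(cfg.seed, "plant", sp)
        strand_rng = substream(cfg.seed, "strand", sp)
        scrub_rng = substream(cfg.seed, "scrub", sp)
        chrom_parts, features = [], []
        cursor = 0
        for i in range(n):
            gene = f"g{sp}{i:04d}"
            strand = "+" if strand_rng.random() < 0.5 else "-"
            parts_seq = {part: _sample_markov(lens[part], init, T, seq_rng)
                         for part in ("promoter",) + BODY_PARTS}

            occupied: dict[str, list] = {}
            for spec in cfg.planted_motifs:
                if (spec.recruited and sp == "B") or i not in hosts[spec.name]:
                    continue
                for _ in range(spec.sites_per_gene):
                    placed = _plant_site(parts_seq, lens, spec, occupied,
                                         plant_rng)
                    if placed is not None:
                        off, sstrand = placed
                        truth_rows.append({"motif_id": spec.name, "species": sp,
                                           "gene_id": gene,
                                           "segment": spec.target_segment,
                                           "offset": off, "strand": sstrand})
            if sp == "B" and i in c4_indices and recruited_specs:
                _scrub_gene(parts_seq, lens, recruited_specs, occupied, scrub_rng)

            body = "".join(parts_seq[p] for p in BODY_PARTS)
            unit_local = parts_seq["promoter"] + body
            chrom_parts.append(_sample_markov(PAD, init, T, seq_rng))
            cursor += PAD
            if strand == "+":
                chrom_parts.append(unit_local)
                body_start = cursor + P
            else:
                chrom_parts.append(revcomp(unit_local))
                body_start = cursor
            LB = len(body)

            def genomic(ls, le):
                if strand == "+":
                    return body_start + ls, body_start + le
                return body_start + LB - le, body_start + LB - ls

            def feat(ftype, ls, le, fid, parent=None, phase="."):
                s0, e0 = genomic(ls, le)
                attrs = f"ID={fid}" + (f";Parent={parent}" if parent else "")
                features.append((s0, f"chr1\tsynth\t{ftype}\t{s0 + 1}\t{e0}\t."
                                     f"\t{strand}\t{phase}\t{attrs}"))

            b0, b1 = layout["_body"]
            feat("gene", b0, b1, gene)
            feat("mRNA", b0, b1, f"{gene}.t1", gene)
            exon_bounds = [(layout["utr5"][0], layout["cds1"][1]),
                           (layout["cds2"][0], layout["cds2"][1]),
                           (layout["cds3"][0], layout["utr3"][1])]
            for k, (ls, le) in enumerate(exon_bounds, 1):
                feat("exon", ls, le, f"{gene}.e{k}", f"{gene}.t1")
            for k, part in enumerate(("cds1", "cds2", "cds3"), 1):
                feat("CDS", *layout[part], f"{gene}.c{k}", f"{gene}.t1", phase="0")
            feat("five_prime_UTR", *layout["utr5"], f"{gene}.u5", f"{gene}.t1")
            feat("three_prime_UTR", *layout["utr3"], f"{gene}.u3", f"{gene}.t1")
            cursor += len(unit_local)

        genomes[sp] = {"chr1": "".join(chrom_parts)}
        features.sort(key=lambda f: f[0])
        gffs[sp] = "##gff-version 3\n" + "\n".join(f[1] for f in features) + "\n"

        # expression: archetype + gene-specific systematic shape deviation
        # (small for regulon members, large for bulk genes) + measurement
        # noise, then an amplitude and offset to positive RPKM units
        expr_rng = substream(cfg.seed, "expression", sp)
        samplers = [_orth_cubic_sampler(arch[cl]) for cl in range(cfg.n_clusters)]
        amps = np.exp(expr_rng.normal(2.5, 0.6, size=n))
        rows = []
        for i in range(n):
            lo, hi = (cfg.regulon_dispersion if i in regulon
                      else cfg.bulk_dispersion)
            lam = expr_rng.uniform(lo, hi)
            cl = cluster_of[i]
            profile = (arch[cl]
                       + cfg.dispersion_scale * lam * samplers[cl](expr_rng)
                       + expr_rng.normal(0.0, cfg.noise_sd, size=arch.shape[1]))
            amp = amps[i] * (4.0 if (sp == "A" and i in c4_indices) else 1.0)
            rows.append(np.clip(amp * (profile + 1.0), 0.0, None))
        idx = pd.Index([f"g{sp}{i:04d}" for i in range(n)], name="gene_id")
        exprs[sp] = pd.DataFrame(np.array(rows), index=idx,
                                 columns=TIMEPOINT_LABELS)
        cluster_truth[sp] = pd.Series({f"g{sp}{i:04d}": cluster_of[i]
                                       for i in range(n)})

    truth = pd.DataFrame(truth_rows,
                         columns=["motif_id", "species", "gene_id", "segment",
                                  "offset", "strand"])
    truth = truth.sort_values(["motif_id", "species", "gene_id",
                               "segment", "offset"], ignore_index=True)

    ds = SynthDataset(config=cfg, genomes=genomes, gff=gffs, expr=exprs,
                      callsets=_make_callsets(cfg, n, c4_indices),
                      truth=truth, library=_make_library(cfg),
                      c4_genes=c4_genes,
                      orthologs={f"gA{i:04d}": f"gB{i:04d}" for i in range(n)},
                      cluster_truth=cluster_truth,
                      motif_specs=list(cfg.planted_motifs),
                      regulon_indices=sorted(regulon))
    if outdir is not None:
        ds.write(outdir)
    return ds


def _make_callsets(cfg: SynthConfig, n: int, c4_indices) -> list:
    rng = substream(cfg.seed, "callsets")
    methods = [("bbhls", 1, 0.70), ("orthomcl", 2, 0.85), ("inparanoid", 3, 0.80)]
    callsets = []
    for method, rank, coverage in methods:
        rows = []
        for i in range(n):
            keep = rng.random() < coverage or (rank == 1 and i in c4_indices)
            if not keep:
                continue
            partner = i
            if rank > 1 and rng.random() < cfg.ortholog_conflict_rate:
                partner = (i + 7) % n     # deliberate wrong partner
            rows.append({"geneA": f"gA{i:04d}", "geneB": f"gB{partner:04d}",
                         "method": method, "score": round(float(rng.random()), 3)})
            if rank > 1 and rng.random() < cfg.many_to_many_rate:
                extra = (i + 13) % n      # many-to-many record
                rows.append({"geneA": f"gA{i:04d}", "geneB": f"gB{extra:04d}",
                             "method": method, "score": round(float(rng.random()), 3)})
        callsets.append(CallSet(method=method, rank=rank,
                                pairs=pd.DataFrame(rows)))
    return callsets


def _make_library(cfg: SynthConfig, n_decoys: int = 8) -> list:
    """Toy PWM library: the planted motifs plus random sharp decoys,
    standing in for a curated transcription-factor motif catalog."""
    rng = substream(cfg.seed, "library")
    lib = [PWM(s.pwm.matrix.copy(), name=f"LIB_{s.name}")
           for s in cfg.planted_motifs]
    for k in range(n_decoys):
        width = int(rng.integers(6, 11))
        lib.append(PWM.random(width, rng, name=f"DECOY{k + 1}"))
    return lib


__all__ = ["PlantedMotifSpec", "SynthConfig", "SynthDataset",
           "default_planted_motifs", "archetype_curves", "background_chain",
           "generate_dataset"]
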