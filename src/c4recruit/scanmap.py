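"""Gene-segment extraction and consensus-based motif mapping.

For every gene five segment classes are extracted from genome FASTA +
GFF3 annotation: the promoter (up to 3 kb upstream of the TSS), 5'UTR,
3'UTR, CDS, and intron.  Multi-part CDS and intron segments are
concatenated with runs of exactly 10 ``N`` so that downstream scanners
never match across a junction.  All segments are reported 5'->3' in the
gene's orientation.

Motif occurrences are verified by scanning a degenerate (IUPAC)
consensus: a window matches iff it is within ``max_mm`` mismatches of the
literal consensus AND every base is compatible with the degenerate
consensus (zero degenerate mismatches).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import IUPAC_BY_SET, IUPAC_SETS, encode, revcomp, revcomp_iupac
from .pwm import PWM

log = logging.getLogger(__name__)

SEGMENT_CLASSES = ("promoter", "utr5", "utr3", "cds", "intron")
SPACER = "N" * 10
PROMOTER_LENGTH = 3000


@dataclass
class SegmentSet:
    """Per-gene segment sequences, 5'->3' in gene orientation."""

    gene_id: str
    strand: str
    segments: dict = field(default_factory=dict)  # class -> sequence string
    coordinates: dict = field(default_factory=dict)  # class -> list of (chrom, start, end) 0-based half-open

    def __getitem__(self, cls: str) -> str:
        return self.segments.get(cls, "")


@dataclass
class MotifOccurrence:
    motif_id: str
    gene: str
    segment: str
    offset: int  # 0-based within the segment string
    strand: str  # '+' / '-' relative to the scanned sequence
    mismatches: int


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """0-based half-open fetch from a pyfaidx.Fasta or a plain dict of strings."""
    if start >= end:
        return ""
    if hasattr(genome, "keys") and not hasattr(genome, "faidx"):
        return genome[chrom][start:end].upper()
    return str(genome[chrom][start:end]).upper()


def _contig_length(genome, chrom: str) -> int:
    if hasattr(genome, "keys") and not hasattr(genome, "faidx"):
        return len(genome[chrom])
    return len(genome[chrom])


def extract_segments(db, gene_id: str, genome,
                     promoter_length: int = PROMOTER_LENGTH) -> SegmentSet:
    """Extract the five segment classes for one gene.

    Parameters
    ----------
    db : gffutils.FeatureDB
        Annotation database with gene/mRNA/exon/CDS/UTR features.
    gene_id : str
        ID of the gene feature.
    genome : pyfaidx.Fasta or dict
        Chromosome sequences.
    """
    gene = db[gene_id]
    chrom, strand = gene.seqid, gene.strand
    clen = _contig_length(genome, chrom)
    mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
    if not mrnas:
        raise ValueError(f"gene {gene_id} has no mRNA feature")
    mrna = mrnas[0]  # first transcript; isoform complexity out of scope

    def parts(ftype):
        feats = list(db.children(mrna, featuretype=ftype, order_by="start"))
        return [(f.start - 1, f.end) for f in feats]  # to 0-based half-open

    exons = parts("exon")
    cds = parts("CDS")
    utr5 = parts("five_prime_UTR")
    utr3 = parts("three_prime_UTR")
    if not exons:
        raise ValueError(f"gene {gene_id} has no exon features")

    introns = [(a_end, b_start) for (_, a_end), (b_start, _)
               in zip(exons[:-1], exons[1:]) if b_start > a_end]

    def oriented(intervals):
        """Sequences of each part, 5'->3' in gene orientation, in gene order."""
        seqs = [_fetch(genome, chrom, s, e) for s, e in intervals]
        if strand == "-":
            seqs = [revcomp(s) for s in reversed(seqs)]
            intervals = list(reversed(intervals))
        return seqs, intervals

    seg = SegmentSet(gene_id=gene_id, strand=strand)

    # promoter: upstream of the TSS on the gene's strand, clipped at contig edge
    if strand == "-":
        p_start, p_end = gene.end, min(clen, gene.end + promoter_length)
        prom = revcomp(_fetch(genome, chrom, p_start, p_end))
    else:
        p_start, p_end = max(0, gene.start - 1 - promoter_length), gene.start - 1
        prom = _fetch(genome, chrom, p_start, p_end)
    if p_end - p_start < promoter_length:
        log.info("gene %s promoter clipped to %d bp at contig edge",
                 gene_id, p_end - p_start)
    seg.segments["promoter"] = prom
    seg.coordinates["promoter"] = [(chrom, p_start, p_end)]

    for name, intervals, spaced in (("utr5", utr5, False), ("utr3", utr3, False),
                                    ("cds", cds, True), ("intron", introns, True)):
        if not intervals:
            seg.segments[name] = ""
            seg.coordinates[name] = []
            if name in ("utr5", "utr3"):
                log.info("gene %s has no %s annotation", gene_id, name)
            continue
        seqs, ordered = oriented(intervals)
        joiner = SPACER if spaced else ""
        seg.segments[name] = joiner.join(seqs)
        seg.coordinates[name] = [(chrom, s, e) for s, e in ordered]
    return seg


def degenerate_consensus(pwm: PWM, include_threshold: float = 0.25) -> str:
    """IUPAC consensus: per position, bases with frequency >= threshold.

    An empty set (all frequencies below threshold) falls back to the argmax
    base so the code is always scannable.
    """
    out = []
    for i in range(pwm.width):
        bases = tuple(sorted(b for j, b in enumerate("ACGT")
                             if pwm.matrix[i, j] >= include_threshold))
        if not bases:
            bases = (pwm.consensus[i],)
        out.append(IUPAC_BY_SET[bases])
    return "".join(out)


def _degenerate_mask(degenerate: str) -> np.ndarray:
    """(width, 5) bool: allowed[pos, base]; base 4 (N) never allowed."""
    mask = np.zeros((len(degenerate), 5), dtype=bool)
    for i, code in enumerate(degenerate):
        for b in IUPAC_SETS[code]:
            mask[i, "ACGT".index(b)] = True
    return mask


def scan_consensus(seq: str, consensus: str, degenerate: str,
                   max_mm: int = 2, both_strands: bool = True,
                   motif_id: str = "", gene: str = "",
                   segment: str = "") -> list[MotifOccurrence]:
    """Find all windows within ``max_mm`` of the consensus and fully
    compatible with the degenerate consensus.

    Windows overlapping an N spacer never match.  On the minus strand the
    reverse complement of the window is compared; offsets always refer to
    the scanned sequence.
    """
    if len(consensus) != len(degenerate):
        raise ValueError("consensus and degenerate consensus must have equal length")
    w = len(consensus)
    if len(seq) < w:
        return []
    codes = encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    occ: list[MotifOccurrence] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        cons = consensus if strand == "+" else revcomp(consensus)
        degen = degenerate if strand == "+" else revcomp_iupac(degenerate)
        cons_codes = encode(cons)
        allowed = _degenerate_mask(degen)
        ok = allowed[np.arange(w)[None, :], windows].all(axis=1)
        mm = (windows != cons_codes[None, :]).sum(axis=1)
        hits = np.nonzero(ok & (mm <= max_mm))[0]
        for off in hits:
            occ.append(MotifOccurrence(motif_id=motif_id, gene=gene,
                                       segment=segment, offset=int(off),
                                       strand=strand, mismatches=int(mm[off])))
    occ.sort(key=lambda o: (o.offset, o.strand))
    return occ


def scan_pwm_consensus(seq: str, pwm: PWM, include_threshold: float = 0.25,
                       max_mm: int = 2, both_strands: bool = True,
                       **ids) -> list[MotifOccurrence]:
    """Convenience wrapper: derive consensus + degenerate consensus and scan."""
    return scan_consensus(seq, pwm.consensus, degenerate_consensus(pwm, include_threshold),
                          max_mm=max_mm, both_strands=both_strands,
                          motif_id=ids.get("motif_id", pwm.name),
                          gene=ids.get("gene", ""), segment=ids.get("segment", ""))


__all__ = ["SEGMENT_CLASSES", "SPACER", "PROMOTER_LENGTH", "SegmentSet",
           "MotifOccurrence", "extract_segments", "degenerate_consensus",
           "scan_consensus", "scan_pwm_consensus"]
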