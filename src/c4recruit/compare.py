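"""PWM-PWM alignment and consensus motif construction.

Motif matching follows the column-comparison approach of motif-alignment
tools: every ungapped offset of one PWM against the other, in both
orientations, with at least 4 overlapping columns; each aligned column
pair is scored by the Pearson correlation of the two base-frequency
4-vectors, the alignment score is the mean column score over the
overlap, and significance comes from an empirical column-shuffle null
with an add-one correction.

Consensus building mirrors the multi-evidence filters used to suppress
false discoveries: a motif is retained only if independently found by at
least two prediction engines (cross-method), only if a motif from the
high-k clustering maps to one from the low-k clustering (cross-k), and
cross-species conservation is recorded per (ortholog pair, segment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discovery import MotifHit
from .pwm import PWM

log = logging.getLogger(__name__)

MIN_OVERLAP = 4


@dataclass
class MotifAlignment:
    pwm_a: PWM
    pwm_b: PWM
    offset: int                     # start of b relative to start of a
    orientation: str                # forward | revcomp
    column_scores: np.ndarray
    score: float                    # mean column score over the overlap
    pvalue: float | None = None


@dataclass
class ConsensusMotif:
    pwm: PWM                        # representative (highest-IC member)
    engines: frozenset
    members: list = field(default_factory=list)
    k_runs: frozenset = frozenset()
    species: str = ""
    gene: str = ""
    segment: str = ""

    @property
    def name(self) -> str:
        return self.pwm.name or self.pwm.consensus


def _norm_columns(matrix: np.ndarray) -> np.ndarray:
    """Center and L2-normalize each frequency 4-vector; zero-variance
    columns become zero vectors (column score 0 by convention)."""
    c = matrix - matrix.mean(axis=1, keepdims=True)
    n = np.linalg.norm(c, axis=1)
    out = np.zeros_like(c)
    nz = n > 1e-12
    out[nz] = c[nz] / n[nz, None]
    return out


def _offsets(wa: int, wb: int, min_overlap: int):
    """(offset, a0, b0, L) for every ungapped placement with enough overlap."""
    for off in range(-(wb - min_overlap), wa - min_overlap + 1):
        a0 = max(0, off)
        b0 = max(0, -off)
        L = min(wa - a0, wb - b0)
        if L >= min_overlap:
            yield off, a0, b0, L


def _best_from_dot(D: np.ndarray, min_overlap: int):
    """Best (score, offset, a0, b0, L) over all offsets of a column-dot matrix.

    Ties prefer the longer overlap, then the more central offset, so an
    exact full-width self-alignment beats a periodic partial one.
    """
    best = None
    best_key = None
    for off, a0, b0, L in _offsets(D.shape[0], D.shape[1], min_overlap):
        diag = D[a0:a0 + L, b0:b0 + L].diagonal()
        score = float(diag.mean())
        key = (score, L, -abs(off), -off)
        if best is None or key > best_key:
            best = (score, off, a0, b0, L, diag)
            best_key = key
    return best


def align_pwms(a: PWM, b: PWM, min_overlap: int = MIN_OVERLAP) -> MotifAlignment:
    """Best ungapped alignment of two PWMs over offsets and orientations."""
    if a.width < min_overlap or b.width < min_overlap:
        raise ValueError(f"PWM widths must be >= {min_overlap}")
    na = _norm_columns(a.matrix)
    candidates = []
    for orientation, bb in (("forward", b), ("revcomp", b.reverse_complement())):
        nb = _norm_columns(bb.matrix)
        best = _best_from_dot(na @ nb.T, min_overlap)
        candidates.append((best[0], orientation, best))
    # deterministic tie-break: forward preferred, then smaller offset
    candidates.sort(key=lambda c: (-c[0], c[1] != "forward", c[2][1]))
    score, orientation, (s, off, a0, b0, L, diag) = candidates[0]
    return MotifAlignment(pwm_a=a, pwm_b=b, offset=off, orientation=orientation,
                          column_scores=np.asarray(diag, dtype=float), score=score)


def match_pvalue(alignment: MotifAlignment, null_size: int = 10000,
                 seed: int = 0, min_overlap: int = MIN_OVERLAP) -> float:
    """Empirical match p-value from a span-matched column-shuffle null.

    Null alignments re-run the best-offset/orientation search on
    column-shuffled copies of both PWMs, restricted to offsets whose
    overlap is at least as long as the observed alignment's (mean column
    scores are not comparable across spans: a short overlap reaches a
    high mean too cheaply, which would mask genuine full-width matches).
    p = (r + 1) / (n + 1) with r the number of null scores >= observed.
    """
    a, b = alignment.pwm_a, alignment.pwm_b
    na = _norm_columns(a.matrix)
    nb = _norm_columns(b.matrix)
    nb_rc = _norm_columns(b.reverse_complement().matrix)
    if not na.any() or not (nb.any() or nb_rc.any()):
        return 1.0  # degenerate: all columns uniform, correlation undefined
    D = na @ nb.T
    D_rc = na @ nb_rc.T
    offsets = list(_offsets(a.width, b.width, min_overlap))

    def max_sum(Ma, Mb):
        """Best summed column score over offsets/orientations; the sum is
        comparable across overlap spans (a mean is not: short overlaps
        reach a high mean too cheaply, masking full-width matches)."""
        out = None
        for M in (Ma, Mb):
            for off, a0, b0, L in offsets:
                s = M[..., a0:a0 + L, b0:b0 + L].diagonal(
                    axis1=-2, axis2=-1).sum(axis=-1)
                out = s if out is None else np.maximum(out, s)
        return out

    obs = float(max_sum(D, D_rc))
    rng = np.random.default_rng(seed)
    wa, wb = a.width, b.width
    perm_a = np.argsort(rng.random((null_size, wa)), axis=1)
    perm_b = np.argsort(rng.random((null_size, wb)), axis=1)
    Dn = D[perm_a[:, :, None], perm_b[:, None, :]]       # (null, wa, wb)
    Dn_rc = D_rc[perm_a[:, :, None], perm_b[:, None, :]]
    best = max_sum(Dn, Dn_rc)
    r = int((best >= obs - 1e-12).sum())
    return (r + 1) / (null_size + 1)


def motifs_match(a: PWM, b: PWM, match_alpha: float = 0.01,
                 null_size: int = 10000, seed: int = 0) -> tuple[bool, float]:
    try:
        aln = align_pwms(a, b)
    except ValueError:
        return False, 1.0
    p = match_pvalue(aln, null_size=null_size, seed=seed)
    return p <= match_alpha, p


def cross_method_consensus(hits_by_engine: dict[str, list[MotifHit]],
                           match_alpha: float = 0.01, null_size: int = 10000,
                           seed: int = 0, min_engines: int = 2,
                           **labels) -> list[ConsensusMotif]:
    """Merge motifs independently found by >= ``min_engines`` engines.

    Hits are matched pairwise across engines (alignment + shuffle-null
    p-value <= match_alpha) and merged by connected components; a
    component qualifying on engine support yields one ConsensusMotif
    whose representative is the member PWM with the highest total
    information content.
    """
    flat: list[MotifHit] = []
    for engine, hits in hits_by_engine.items():
        for h in hits:
            if h.engine != engine:
                raise ValueError("hit engine label mismatch")
            flat.append(h)
    n = len(flat)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if flat[i].engine == flat[j].engine:
                continue
            ok, _ = motifs_match(flat[i].motif, flat[j].motif,
                                 match_alpha=match_alpha,
                                 null_size=null_size, seed=seed)
            if ok:
                parent[find(i)] = find(j)

    groups: dict[int, list[MotifHit]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(flat[i])
    out = []
    for members in groups.values():
        engines = frozenset(h.engine for h in members)
        if len(engines) < min_engines:
            continue
        rep = max(members, key=lambda h: h.motif.information_content().sum())
        out.append(ConsensusMotif(pwm=rep.motif, engines=engines,
                                  members=members, **labels))
    out.sort(key=lambda c: c.pwm.consensus)
    return out


def mapped_rate(total: int, mapped: int) -> float:
    """Percentage of motifs mapped, to one decimal (Table-2 style)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * mapped / total, 1)


def cross_k_consensus(k_hi_motifs: list[ConsensusMotif],
                      k_lo_motifs: list[ConsensusMotif],
                      match_alpha: float = 0.01, null_size: int = 10000,
                      seed: int = 0) -> dict:
    """Map each high-k motif onto the low-k motif set.

    A high-k motif counts as mapped if it matches at least one low-k motif
    at the match threshold (many-to-one allowed).  Returns total, mapped,
    the mapped flags, the surviving (overlap) motifs, and the rate as a
    percentage with one decimal; an empty high-k list yields rate None.
    """
    total = len(k_hi_motifs)
    if total == 0:
        return {"total": 0, "mapped": 0, "rate": None, "flags": [], "overlap": []}
    flags = []
    for cm in k_hi_motifs:
        mapped = any(motifs_match(cm.pwm, other.pwm, match_alpha=match_alpha,
                                  null_size=null_size, seed=seed)[0]
                     for other in k_lo_motifs)
        flags.append(mapped)
    n_mapped = int(sum(flags))
    overlap = [cm for cm, f in zip(k_hi_motifs, flags) if f]
    return {"total": total, "mapped": n_mapped,
            "rate": mapped_rate(total, n_mapped), "flags": flags,
            "overlap": overlap}


def cross_species_conservation(motifsA: dict, motifsB: dict,
                               pairs: list[tuple[str, str]],
                               segments: list[str],
                               match_alpha: float = 0.01,
                               null_size: int = 10000,
                               seed: int = 0) -> tuple[pd.DataFrame, list[dict]]:
    """Per (ortholog pair, segment) conservation calls.

    ``motifsA``/``motifsB`` map (gene, segment) -> list of ConsensusMotif.
    A cell is conserved iff at least one cross-species motif pair matches.
    Returns the boolean matrix (rows = species-A genes, columns = segment
    classes) and the matched-motif detail records.
    """
    matrix = pd.DataFrame(False, index=pd.Index([a for a, _ in pairs], name="gene"),
                          columns=segments)
    details = []
    for geneA, geneB in pairs:
        for seg in segments:
            for ma in motifsA.get((geneA, seg), []):
                for mb in motifsB.get((geneB, seg), []):
                    ok, p = motifs_match(ma.pwm, mb.pwm, match_alpha=match_alpha,
                                         null_size=null_size, seed=seed)
                    if ok:
                        matrix.loc[geneA, seg] = True
                        details.append({"geneA": geneA, "geneB": geneB,
                                        "segment": seg,
                                        "motifA": ma.name, "motifB": mb.name,
                                        "pvalue": p})
    return matrix, details


__all__ = ["MIN_OVERLAP", "MotifAlignment", "ConsensusMotif", "align_pwms",
           "match_pvalue", "motifs_match", "cross_method_consensus",
           "mapped_rate", "cross_k_consensus", "cross_species_conservation"]
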