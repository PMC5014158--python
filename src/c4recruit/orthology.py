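"""Reconciliation of ortholog call-sets into one-to-one pairs.

Several orthology callers (a bidirectional-best-hit style basis method
plus supplementary clustering methods) each produce a pair list.  They
are merged by priority: (1) every basis pair is kept; (2) pairs reported
only by lower-priority methods are added; (3) when different methods
match the same gene to different partners, the partner with the higher
mean expression wins, on the assumption that functional genes are more
highly expressed; (4) any residual many-to-many relations are dropped so
the output is a strict one-to-one matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class CallSet:
    method: str
    rank: int                      # 1 = basis (most stringent) method
    pairs: pd.DataFrame            # columns geneA, geneB (score optional)

    @classmethod
    def from_tsv(cls, path, method: str, rank: int) -> "CallSet":
        df = pd.read_csv(path, sep="\t")
        return cls(method=method, rank=rank, pairs=df)


@dataclass
class OrthologPair:
    geneA: str
    geneB: str
    methods: tuple
    note: str                      # basis | supplemented | expression-resolved


def _mean_expr(gene: str, expr: pd.DataFrame) -> float:
    if gene not in expr.index:
        log.info("gene %s missing from expression matrix; treated as 0", gene)
        return 0.0
    return float(expr.loc[gene].mean())


def reconcile_orthologs(callsets: list[CallSet], exprA: pd.DataFrame,
                        exprB: pd.DataFrame) -> list[OrthologPair]:
    """Merge priority-ordered call-sets into a one-to-one pair list."""
    callsets = sorted(callsets, key=lambda c: c.rank)
    if not callsets or callsets[0].rank != 1:
        raise ValueError("a rank-1 basis call-set is required")

    # pair -> set of supporting methods
    support: dict[tuple, set] = {}
    for cs in callsets:
        for a, b in cs.pairs[["geneA", "geneB"]].itertuples(index=False):
            support.setdefault((a, b), set()).add(cs.method)

    basis = callsets[0]
    basis_pairs = [tuple(r) for r in
                   basis.pairs[["geneA", "geneB"]].drop_duplicates().itertuples(index=False)]
    usedA = {a for a, _ in basis_pairs}
    usedB = {b for _, b in basis_pairs}

    accepted: dict[tuple, str] = {p: "basis" for p in basis_pairs}

    # candidate non-basis pairs not touching any basis gene
    cand: dict[tuple, set] = {}
    for cs in callsets[1:]:
        for a, b in cs.pairs[["geneA", "geneB"]].itertuples(index=False):
            if (a, b) in accepted or a in usedA or b in usedB:
                continue
            cand.setdefault((a, b), set()).add(cs.method)

    def resolve(side: int, expr_partner: pd.DataFrame):
        """Keep, per gene on ``side``, the partner with higher mean expression.

        A gene matched to several partners *by the same method* is a
        within-method many-to-many record and all of its pairs are dropped.
        """
        by_gene: dict[str, list[tuple]] = {}
        for pair in cand:
            by_gene.setdefault(pair[side], []).append(pair)
        for gene, pairs in by_gene.items():
            live = [p for p in pairs if p in cand]
            if len(live) <= 1:
                continue
            # a single method asserting two partners is many-to-many, not a
            # between-method conflict; such records are simply dropped
            methods_here = {m for p in live for m in cand[p]}
            method_multi = any(
                sum(1 for p in live if m in cand[p]) > 1 for m in methods_here)
            if method_multi:
                log.info("dropping within-method many-to-many pairs for %s", gene)
                for p in live:
                    cand.pop(p, None)
                continue
            keyed = sorted(live, key=lambda p: (-_mean_expr(p[1 - side], expr_partner),
                                                p[1 - side]))
            keep = keyed[0]
            for p in keyed[1:]:
                cand.pop(p, None)
            resolved.add(keep)

    resolved: set = set()
    resolve(0, exprB)
    resolve(1, exprA)

    # residual non-one-to-one (defensive; resolution above is exhaustive)
    countA: dict[str, int] = {}
    countB: dict[str, int] = {}
    for a, b in cand:
        countA[a] = countA.get(a, 0) + 1
        countB[b] = countB.get(b, 0) + 1
    for pair in [p for p in cand if countA[p[0]] > 1 or countB[p[1]] > 1]:
        cand.pop(pair)

    for pair, methods in cand.items():
        accepted[pair] = "expression-resolved" if pair in resolved else "supplemented"

    out = [OrthologPair(geneA=a, geneB=b,
                        methods=tuple(sorted(support.get((a, b), set()))),
                        note=note)
           for (a, b), note in accepted.items()]
    out.sort(key=lambda p: (p.geneA, p.geneB))
    # invariant: strict matching
    assert len({p.geneA for p in out}) == len(out)
    assert len({p.geneB for p in out}) == len(out)
    return out


def pairs_frame(pairs: list[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame([{"geneA": p.geneA, "geneB": p.geneB,
                          "methods": ",".join(p.methods), "note": p.note}
                         for p in pairs])


def pick_c4_isoform(family: list[str], expr: pd.DataFrame,
                    known_specificity: dict | None = None) -> str:
    """Pick the pathway isoform within a paralog family.

    A member annotated with known cell-specific expression wins outright;
    otherwise the highest mean expression does, with lexicographic
    tie-breaking (logged).
    """
    if not family:
        raise ValueError("empty paralog family")
    if known_specificity:
        annotated = [g for g in family if known_specificity.get(g)]
        if annotated:
            return sorted(annotated)[0]
    scored = sorted(family, key=lambda g: (-_mean_expr(g, expr), g))
    if len(scored) > 1 and _mean_expr(scored[0], expr) == _mean_expr(scored[1], expr):
        log.info("expression tie in family %s; lexicographic pick %s",
                 family, scored[0])
    return scored[0]


__all__ = ["CallSet", "OrthologPair", "reconcile_orthologs", "pairs_frame",
           "pick_c4_isoform"]
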