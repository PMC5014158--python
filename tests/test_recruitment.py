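import itertools
import math

import numpy as np
import pytest

from c4recruit.compare import ConsensusMotif
from c4recruit.discovery import BackgroundModel, MotifHit
from c4recruit.expression import ClusterResult, CoexpressionList
from c4recruit.pwm import PWM
from c4recruit.recruitment import (PatternThresholds, call_recruited,
                                   classify_pattern, mutual_information,
                                   permutation_null_mi, segment_enrichment_p)
from c4recruit.scanmap import SegmentSet

import pandas as pd


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def test_mi_of_vector_with_itself_is_one():
    x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3])
    out = mutual_information(x, x)
    assert out["mi_norm"] == pytest.approx(1.0, abs=1e-12)
    assert out["mi_max_norm"] == 1.0


def test_mi_is_symmetric(rng):
    for _ in range(10):
        x, y = rng.normal(size=7), rng.normal(size=7)
        assert mutual_information(x, y)["mi_norm"] == pytest.approx(
            mutual_information(y, x)["mi_norm"], abs=1e-12)


def _mi_oracle(x, y, bins=3):
    """Independent oracle: explicit rank-binning and direct counts."""
    def binned(v):
        order = np.argsort(np.argsort(v, kind="stable"), kind="stable")
        return order * bins // len(v)
    bx, by = binned(np.asarray(x)), binned(np.asarray(y))
    n = len(bx)
    mi = 0.0
    for a in range(bins):
        for b in range(bins):
            pab = np.mean((bx == a) & (by == b))
            if pab > 0:
                mi += pab * math.log(pab / (np.mean(bx == a) * np.mean(by == b)))
    hx = -sum(p * math.log(p) for p in
              [np.mean(bx == a) for a in range(bins)] if p > 0)
    hy = -sum(p * math.log(p) for p in
              [np.mean(by == b) for b in range(bins)] if p > 0)
    return mi / min(hx, hy)


def test_mi_matches_direct_contingency_oracle():
    x = np.array([0.3, 2.9, 1.1, 7.4, 5.0, 0.9, 3.3])
    y = np.array([9.0, 0.1, 4.4, 2.2, 8.8, 6.1, 0.7])
    assert mutual_information(x, y)["mi_norm"] == pytest.approx(
        _mi_oracle(x, y), abs=1e-12)


def test_mi_constant_vector_is_flagged_zero():
    out = mutual_information(np.ones(7), np.arange(7.0))
    assert out["mi_norm"] == 0.0 and out["flagged"]


def test_mi_invariant_under_monotone_transforms(rng):
    for _ in range(10):
        x, y = rng.normal(size=7), rng.normal(size=7)
        base = mutual_information(x, y)["mi_norm"]
        assert mutual_information(np.exp(x), y ** 3)["mi_norm"] == \
            pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _exhaustive_null(x, y):
    vals = [mutual_information(x, np.asarray(p))["mi_norm"]
            for p in itertools.permutations(y)]
    return float(np.mean(vals))


def test_permutation_null_agrees_with_exhaustive_mean():
    x = np.array([0.3, 2.9, 1.1, 7.4, 5.0, 0.9, 3.3])
    y = np.array([9.0, 0.1, 4.4, 2.2, 8.8, 6.1, 0.7])
    exact = _exhaustive_null(x, y)
    assert 0.30 <= exact <= 0.50
    sampled = permutation_null_mi(x, y, n_perm=2000, seed=0)
    assert sampled == pytest.approx(exact, abs=0.02)


def test_permutation_null_is_deterministic():
    x = np.arange(7.0)
    y = np.array([2.0, 5, 1, 7, 3, 6, 4])
    a = permutation_null_mi(x, y, n_perm=100, seed=9)
    b = permutation_null_mi(x, y, n_perm=100, seed=9)
    assert a == b


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

def _clusters(gene, centroid):
    return ClusterResult(k=1, labels=pd.Series({gene: 0}),
                         centroids=np.array([centroid]), seed=0, inertia=0.0)


def test_identical_curves_classify_similar():
    x = np.array([1.0, 2, 4, 9, 16, 12, 3])
    grid_curve = np.linspace(0, 1, 25)
    out = classify_pattern("gA", "gB", x, x,
                           _clusters("gA", grid_curve),
                           _clusters("gB", grid_curve))
    assert out.pattern == "similar"
    assert out.centroid_distance == pytest.approx(0.0)
    assert out.rank_correlation == pytest.approx(1.0)


def test_time_permuted_profile_classifies_shifted():
    """The shifted class: same profile values re-ordered in time, giving
    low/negative rank correlation with high normalized MI (the DiT1-style
    signature).  The best such permutation is found exhaustively, so the
    test is deterministic."""
    from scipy import stats as sps
    x = np.array([1.0, 2, 4, 9, 16, 12, 3])
    best, best_mi = None, -1.0
    for perm in itertools.permutations(range(7)):
        y = x[list(perm)]
        if sps.spearmanr(x, y).statistic >= 0.0:
            continue
        mi = mutual_information(x, y)["mi_norm"]
        if mi > best_mi:
            best, best_mi = y, mi
    assert best_mi >= 0.7  # the shifted region is reachable
    a = np.linspace(0, 3, 25)
    b = np.linspace(3, 0, 25)  # far centroids: not "similar"
    out = classify_pattern("gA", "gB", x, best, _clusters("gA", a),
                           _clusters("gB", b), seed=1)
    assert out.rank_correlation < 0.4
    assert out.pattern == "shifted"


def test_independent_noise_classifies_distinct(rng):
    a = np.linspace(0, 3, 25)
    b = np.linspace(3, 0, 25)
    n_distinct = 0
    for i in range(10):
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        out = classify_pattern("gA", "gB", x, y, _clusters("gA", a),
                               _clusters("gB", b), seed=i)
        n_distinct += out.pattern == "distinct"
    assert n_distinct >= 8


def test_unclustered_gene_raises():
    x = np.arange(7.0)
    with pytest.raises(KeyError):
        classify_pattern("gA", "missing", x, x,
                         _clusters("gA", np.zeros(25)),
                         _clusters("gB", np.zeros(25)))


# ---------------------------------------------------------------------------
# recruited-motif calling
# ---------------------------------------------------------------------------

def _segment_set(gene, promoter):
    return SegmentSet(gene_id=gene, strand="+", segments={
        "promoter": promoter, "utr5": "", "utr3": "", "cds": "", "intron": ""})


def _scenario(rng, site="TACGCGAC", in_b=False, in_coexpressed=True):
    def bgseq(n):
        return "".join(rng.choice(list("ACGT"), size=n))
    pwm = PWM.from_word(site, name="cand")
    motif = ConsensusMotif(pwm=pwm, engines=frozenset({"em", "word"}))
    segsA = {
        "c4": _segment_set("c4", bgseq(100) + site + bgseq(100)),
        "co1": _segment_set("co1", bgseq(90) + (site if in_coexpressed
                                                 else "") + bgseq(90)),
        "other": _segment_set("other", bgseq(200)),
    }
    segsB = _segment_set("ortho", bgseq(100) + (site if in_b else "")
                         + bgseq(100))
    bg = BackgroundModel.fit([bgseq(400) for _ in range(10)], "promoter")
    coexpr = CoexpressionList(target="c4",
                              members=pd.DataFrame(index=["co1"]),
                              threshold=-1.644853)
    return motif, segsA, segsB, bg, coexpr


def test_recruited_motif_gets_positive_verdict(rng):
    motif, segsA, segsB, bg, coexpr = _scenario(rng)
    call = call_recruited(motif, "c4", coexpr, segsA, segsB, "promoter", bg)
    assert call.verdict and call.criterion1 and call.criterion2
    assert call.siteB_count == 0 and "co1" in call.coexpressed_support


def test_shared_motif_fails_criterion_two(rng):
    motif, segsA, segsB, bg, coexpr = _scenario(rng, in_b=True)
    call = call_recruited(motif, "c4", coexpr, segsA, segsB, "promoter", bg)
    assert call.criterion1 and not call.criterion2 and not call.verdict
    assert call.siteB_count >= 1


def test_motif_without_coexpressed_support_fails_criterion_one(rng):
    motif, segsA, segsB, bg, coexpr = _scenario(rng, in_coexpressed=False)
    call = call_recruited(motif, "c4", coexpr, segsA, segsB, "promoter", bg)
    assert not call.criterion1 and not call.verdict


def test_missing_ortholog_is_not_callable(rng):
    motif, segsA, _, bg, coexpr = _scenario(rng)
    call = call_recruited(motif, "c4", coexpr, segsA, None, "promoter", bg)
    assert not call.callable and not call.verdict


def test_segment_enrichment_p_detects_planted_sites(rng):
    site = "GTACGACT"
    pwm = PWM.from_word(site)
    bg = BackgroundModel.fit(
        ["".join(rng.choice(list("ACGT"), size=400)) for _ in range(10)])
    seq = ("".join(rng.choice(list("ACGT"), size=200)) + site
           + "".join(rng.choice(list("ACGT"), size=200)))
    p, hits = segment_enrichment_p(pwm, seq, bg)
    assert hits >= 1 and p < 0.05
    p0, hits0 = segment_enrichment_p(
        pwm, "".join(rng.choice(list("AC"), size=50)), bg)
    assert hits0 == 0 and p0 == 1.0
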