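import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from c4recruit.expression import (EVAL_GRID, TIMEPOINT_HOURS, TIMEPOINT_LABELS,
                                  Z_THRESHOLD, ClusterResult, CurveSet,
                                  aggregate_pathways, build_curves,
                                  compute_fom, compute_rpkm, filter_expressed,
                                  kmeans_cluster, normalize_sd,
                                  select_coexpressed, smooth_curve)
from c4recruit.synth import SynthConfig, generate_dataset


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def _counts(values):
    return pd.DataFrame({"s1": values}, index=[f"g{i}" for i in range(len(values))])


def test_rpkm_formula_identity():
    counts = _counts([0, 10])
    lengths = pd.Series([500, 1000], index=counts.index)
    libs = pd.Series([1e6], index=["s1"])
    rpkm = compute_rpkm(counts, lengths, libs)
    assert rpkm.loc["g0", "s1"] == 0.0
    assert rpkm.loc["g1", "s1"] == pytest.approx(10.0)


def test_rpkm_halves_when_library_doubles():
    counts = _counts([7, 13])
    lengths = pd.Series([300, 700], index=counts.index)
    a = compute_rpkm(counts, lengths, pd.Series([1e6], index=["s1"]))
    b = compute_rpkm(counts, lengths, pd.Series([2e6], index=["s1"]))
    assert np.allclose(b.to_numpy() * 2, a.to_numpy())


def test_rpkm_preserves_rank_order_for_equal_lengths(rng):
    counts = _counts(rng.integers(0, 1000, size=20))
    lengths = pd.Series(400, index=counts.index)
    rpkm = compute_rpkm(counts, lengths, pd.Series([5e6], index=["s1"]))
    assert (rpkm["s1"].rank() == counts["s1"].rank()).all()


def test_rpkm_rejects_degenerate_inputs():
    counts = _counts([1])
    with pytest.raises(ValueError):
        compute_rpkm(counts, pd.Series([0], index=counts.index),
                     pd.Series([1e6], index=["s1"]))
    with pytest.raises(ValueError):
        compute_rpkm(counts, pd.Series([100], index=counts.index),
                     pd.Series([0], index=["s1"]))


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def test_filter_expressed_is_strictly_greater():
    expr = pd.DataFrame([[0.0] * 7,
                         [1.0] * 7,
                         [0, 0, 0, 0, 0, 0, 7.7]],
                        index=["zero", "const1", "late"],
                        columns=TIMEPOINT_LABELS)
    kept = filter_expressed(expr)
    assert list(kept) == ["late"]  # mean 1.1 in; constant 1.0 excluded (strict >)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mode", ["spline", "poly3"])
def test_constant_series_smooths_to_constant(mode):
    curve = smooth_curve(np.full(7, 3.5), mode=mode)
    assert np.allclose(curve, 3.5, atol=1e-8)


def test_poly3_reproduces_exact_cubic():
    coef = np.array([1.0, -0.5, 0.02, 0.001])
    vals = np.polynomial.polynomial.polyval(TIMEPOINT_HOURS, coef)
    curve = smooth_curve(vals, mode="poly3")
    expected = np.polynomial.polynomial.polyval(EVAL_GRID, coef)
    assert np.allclose(curve, expected, atol=1e-8)


def test_poly3_equals_normal_equations_oracle(rng):
    vals = rng.normal(size=7)
    # independent least-squares oracle: solve (X'X) b = X'y directly
    X = np.vander(TIMEPOINT_HOURS, 4, increasing=True)
    beta = np.linalg.solve(X.T @ X, X.T @ vals)
    expected = np.vander(EVAL_GRID, 4, increasing=True) @ beta
    assert np.allclose(smooth_curve(vals, mode="poly3"), expected, atol=1e-8)


def test_smooth_curve_input_validation():
    with pytest.raises(ValueError):
        smooth_curve([1.0, 2.0, 3.0], mode="poly3",
                     hours=np.array([0.0, 1.0, 2.0]))
    with pytest.raises(ValueError):
        smooth_curve(np.ones(7), mode="nope")


# ---------------------------------------------------------------------------
# SD normalization
# ---------------------------------------------------------------------------

def test_normalize_sd_divides_by_sd():
    curve = np.array([0.0, 4.0, 0.0, 4.0])  # SD 2
    out, sd, flag = normalize_sd(curve)
    assert sd == pytest.approx(2.0)
    assert np.allclose(out, curve / 2.0)
    assert not flag


def test_normalize_sd_leaves_unit_sd_unchanged(rng):
    curve = rng.normal(size=25)
    curve = curve / curve.std()
    out, sd, _ = normalize_sd(curve)
    assert np.allclose(out, curve)


def test_normalize_sd_flags_constant_curves():
    out, sd, flag = normalize_sd(np.full(25, 9.0))
    assert flag and sd == 0.0 and np.allclose(out, 0.0)


def test_normalize_sd_is_idempotent(rng):
    for _ in range(20):
        curve = rng.normal(scale=rng.uniform(0.1, 10), size=25)
        once, _, _ = normalize_sd(curve)
        twice, _, _ = normalize_sd(once)
        assert np.allclose(once, twice, atol=1e-12)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _noiseless_dataset():
    return generate_dataset(SynthConfig(
        seed=5, n_genes_per_species=80, n_clusters=4, regulon_size=4,
        noise_sd=0.0, dispersion_scale=0.0))


def test_kmeans_recovers_noiseless_archetypes_exactly():
    ds = _noiseless_dataset()
    curves = build_curves(ds.expr["A"], mode="spline", center=True)
    result = kmeans_cluster(curves, 4, seed=0)
    truth = ds.cluster_truth["A"].loc[result.labels.index]
    assert adjusted_rand_score(truth, result.labels) == 1.0


def test_kmeans_singleton_clusters_have_zero_wcss(rng):
    expr = pd.DataFrame(rng.uniform(1, 50, size=(6, 7)),
                        index=[f"g{i}" for i in range(6)],
                        columns=TIMEPOINT_LABELS)
    curves = build_curves(expr, mode="poly3")
    result = kmeans_cluster(curves, 6, seed=0)
    assert result.inertia == pytest.approx(0.0, abs=1e-9)
    assert len(set(result.labels)) == 6


def test_kmeans_is_deterministic_for_fixed_seed(rng):
    expr = pd.DataFrame(rng.uniform(1, 50, size=(40, 7)),
                        index=[f"g{i}" for i in range(40)],
                        columns=TIMEPOINT_LABELS)
    curves = build_curves(expr, mode="spline")
    a = kmeans_cluster(curves, 5, seed=7)
    b = kmeans_cluster(curves, 5, seed=7)
    assert (a.labels == b.labels).all()


def test_kmeans_rejects_bad_k(rng):
    expr = pd.DataFrame(rng.uniform(1, 5, size=(4, 7)),
                        columns=TIMEPOINT_LABELS)
    curves = build_curves(expr)
    with pytest.raises(ValueError):
        kmeans_cluster(curves, 0)
    with pytest.raises(ValueError):
        kmeans_cluster(curves, 10)


# ---------------------------------------------------------------------------
# figure of merit
# ---------------------------------------------------------------------------

def test_fom_zero_for_singleton_clusters(rng):
    expr = pd.DataFrame(rng.uniform(1, 50, size=(5, 7)),
                        columns=TIMEPOINT_LABELS)
    curves = build_curves(expr, mode="spline")
    fom = compute_fom(curves, [5], seed=0)
    assert fom[5] == pytest.approx(0.0, abs=1e-9)


def test_fom_prefers_true_cluster_number_on_noiseless_data():
    ds = _noiseless_dataset()
    curves = build_curves(ds.expr["A"].iloc[:40], mode="spline", center=True)
    fom = compute_fom(curves, [1, 4], seed=0)
    assert fom[4] < 0.05
    assert fom[1] > fom[4]


# ---------------------------------------------------------------------------
# co-expression selection
# ---------------------------------------------------------------------------

def _manual_curveset(mat, genes):
    df = pd.DataFrame(mat, index=genes)
    return CurveSet(grid=np.arange(mat.shape[1]), curves=df,
                    sd=pd.Series(1.0, index=genes),
                    constant=pd.Series(False, index=genes), mode="poly3")


def _single_cluster(genes, n_grid):
    return ClusterResult(k=1, labels=pd.Series(0, index=pd.Index(genes)),
                         centroids=np.zeros((1, n_grid)), seed=0, inertia=0.0)


def test_identical_gene_gets_most_negative_z(rng):
    genes = [f"g{i}" for i in range(30)]
    mat = rng.normal(size=(30, 10))
    mat[1] = mat[0]  # g1 identical to the target g0
    curves = _manual_curveset(mat, genes)
    co = select_coexpressed("g0", _single_cluster(genes, 10), curves)
    assert "g1" in co.genes
    assert co.members.loc["g1", "distance"] == pytest.approx(0.0)
    assert co.members["z"].idxmin() == "g1"


def test_threshold_is_strict(rng):
    genes = [f"g{i}" for i in range(30)]
    mat = rng.normal(size=(30, 10))
    curves = _manual_curveset(mat, genes)
    clusters = _single_cluster(genes, 10)
    tcurve = curves.gene_curve("g0")
    d = np.linalg.norm(curves.curves.iloc[1:].to_numpy() - tcurve, axis=1)
    z = (d - d.mean()) / d.std()
    zmin = z.min()
    # a gene whose Z exactly equals the threshold is NOT retained
    co = select_coexpressed("g0", clusters, curves, z_threshold=zmin)
    assert len(co.genes) == 0
    co2 = select_coexpressed("g0", clusters, curves, z_threshold=zmin + 1e-9)
    assert len(co2.genes) == 1


def test_selection_monotone_in_threshold(rng):
    genes = [f"g{i}" for i in range(50)]
    curves = _manual_curveset(rng.normal(size=(50, 10)), genes)
    clusters = _single_cluster(genes, 10)
    low = set(select_coexpressed("g0", clusters, curves, z_threshold=-2.0).genes)
    high = set(select_coexpressed("g0", clusters, curves, z_threshold=-1.0).genes)
    assert low <= high


def test_small_cluster_yields_empty_list(rng):
    genes = ["a", "b"]
    curves = _manual_curveset(rng.normal(size=(2, 10)), genes)
    co = select_coexpressed("a", _single_cluster(genes, 10), curves)
    assert co.genes == []


def test_retained_fraction_matches_normal_tail(rng):
    # distances constructed ~ N(50, 1): the Z rule retains ~Phi(-1.645)
    genes = [f"g{i}" for i in range(1001)]
    mat = np.zeros((1001, 10))
    mat[1:, 0] = rng.normal(50.0, 1.0, size=1000)
    curves = _manual_curveset(mat, genes)
    co = select_coexpressed("g0", _single_cluster(genes, 10), curves)
    frac = len(co.genes) / 1000
    assert frac == pytest.approx(stats.norm.cdf(Z_THRESHOLD), abs=0.02)


# ---------------------------------------------------------------------------
# pathway aggregation
# ---------------------------------------------------------------------------

def test_aggregate_pathways_means_and_missing(rng):
    expr = pd.DataFrame([[2.0] * 7, [4.0] * 7, [9.0] * 7],
                        index=["a", "b", "c"], columns=TIMEPOINT_LABELS)
    bins = pd.Series({"a": "P1", "b": "P1", "c": "P2", "ghost": "P3"})
    out = aggregate_pathways(expr, bins)
    assert np.allclose(out.loc["P1"], 3.0)
    assert np.allclose(out.loc["P2"], 9.0)          # one-gene pathway
    assert out.loc["P3"].isna().all()               # no member present
    # invariant to gene order
    out2 = aggregate_pathways(expr.iloc[::-1], bins)
    pd.testing.assert_frame_equal(out, out2)
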