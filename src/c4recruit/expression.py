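"""Time-series expression processing and co-expression selection.

The experimental design sampled leaf tissue at seven time points during
de-etiolation (0, 0.5, 1, 3, 6, 12 and 24 h of illumination).  Raw counts
are converted to RPKM, lowly expressed genes (mean RPKM <= 1) are dropped,
the seven points are smoothed (interpolating cubic spline, or degree-3
least-squares polynomial) onto a fixed evaluation grid, curves are
normalized by their standard deviation, and genes are clustered with
k-means.  Co-expressed partners of a target gene are the same-cluster
genes whose curve distance to the target is in the extreme lower tail
(Z-score < -1.644853, the 5% quantile of the standard normal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

TIMEPOINT_HOURS = np.array([0.0, 0.5, 1.0, 3.0, 6.0, 12.0, 24.0])
TIMEPOINT_LABELS = ["0h", "0.5h", "1h", "3h", "6h", "12h", "24h"]
#: 5% lower-tail quantile of the standard normal, to the precision used
#: throughout for co-expression selection.
Z_THRESHOLD = -1.644853
EVAL_GRID = np.linspace(0.0, 24.0, 25)


@dataclass
class CurveSet:
    """Smoothed per-gene curves on a fixed evaluation grid."""

    grid: np.ndarray
    curves: pd.DataFrame            # genes x grid points
    sd: pd.Series                   # normalization constant per gene
    constant: pd.Series             # flag: raw curve was constant
    mode: str = "spline"
    normalized: bool = True

    def gene_curve(self, gene: str) -> np.ndarray:
        return self.curves.loc[gene].to_numpy()


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series               # gene -> label in [0, k)
    centroids: np.ndarray           # (k, n_grid)
    seed: int
    inertia: float

    def members(self, label: int) -> pd.Index:
        return self.labels.index[self.labels == label]


@dataclass
class CoexpressionList:
    target: str
    members: pd.DataFrame           # columns: distance, z
    threshold: float

    @property
    def genes(self) -> list[str]:
        return list(self.members.index)


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6f")


def compute_rpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
                 library_sizes: pd.Series) -> pd.DataFrame:
    """RPKM = counts * 1e9 / (gene length in bp * library size in reads)."""
    lengths = gene_lengths.reindex(counts.index)
    libs = library_sizes.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("every sample needs a positive library size")
    return counts.mul(1e9).div(lengths, axis=0).div(libs, axis=1)


def filter_expressed(expr: pd.DataFrame, min_avg: float = 1.0) -> pd.Index:
    """Genes with mean expression strictly greater than ``min_avg``."""
    return expr.index[expr.mean(axis=1) > min_avg]


def smooth_curve(values, mode: str = "spline",
                 hours: np.ndarray = TIMEPOINT_HOURS,
                 grid: np.ndarray = EVAL_GRID) -> np.ndarray:
    """Smooth one gene's time series onto the evaluation grid.

    ``spline`` fits an interpolating natural cubic spline through the
    (hour, value) pairs; ``poly3`` fits a least-squares degree-3
    polynomial.
    """
    values = np.asarray(values, dtype=float)
    if mode == "spline":
        if len(values) < 2:
            raise ValueError("spline smoothing needs at least 2 points")
        return CubicSpline(hours, values, bc_type="natural")(grid)
    if mode == "poly3":
        if len(values) < 4:
            raise ValueError("poly3 smoothing needs at least 4 points")
        coef = np.polynomial.polynomial.polyfit(hours, values, 3)
        return np.polynomial.polynomial.polyval(grid, coef)
    raise ValueError(f"unknown smoothing mode {mode!r}")


def normalize_sd(curve: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Divide a curve by its standard deviation.

    Returns ``(normalized, sd, constant_flag)``; a constant curve maps to
    the zero vector and is flagged (its SD is reported as 0).
    """
    curve = np.asarray(curve, dtype=float)
    sd = float(curve.std())
    if sd < 1e-12:
        return np.zeros_like(curve), 0.0, True
    return curve / sd, sd, False


def build_curves(expr: pd.DataFrame, mode: str = "spline",
                 hours: np.ndarray = TIMEPOINT_HOURS,
                 grid: np.ndarray = EVAL_GRID,
                 normalize: bool = True,
                 center: bool = False) -> CurveSet:
    """Smooth and (optionally) SD-normalize every gene's series.

    With ``center=True`` the normalized curves are additionally mean-
    centered on the grid (unit-SD + zero-mean, i.e. R ``scale()``
    semantics), so Euclidean distances become pure shape (correlation)
    distances, independent of each gene's baseline-to-dynamics ratio.
    """
    rows, sds, flags = [], [], []
    for gene in expr.index:
        c = smooth_curve(expr.loc[gene].to_numpy(), mode=mode, hours=hours, grid=grid)
        if normalize:
            c, sd, flag = normalize_sd(c)
        else:
            sd, flag = float(c.std()), False
        if center:
            c = c - c.mean()
        rows.append(c)
        sds.append(sd)
        flags.append(flag)
    return CurveSet(grid=grid,
                    curves=pd.DataFrame(np.array(rows), index=expr.index),
                    sd=pd.Series(sds, index=expr.index),
                    constant=pd.Series(flags, index=expr.index),
                    mode=mode, normalized=normalize)


def kmeans_cluster(curves: CurveSet, k: int, seed: int = 0,
                   n_restarts: int = 10,
                   drop_constant: bool = True) -> ClusterResult:
    """Euclidean k-means on curves; best of ``n_restarts`` by WCSS."""
    if k < 1:
        raise ValueError("k must be >= 1")
    data = curves.curves
    if drop_constant and curves.constant.any():
        dropped = curves.constant.sum()
        log.info("excluding %d constant-curve genes from clustering", dropped)
        data = data.loc[~curves.constant]
    if len(data) < k:
        raise ValueError("need at least k genes to form k clusters")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(data.to_numpy())
    return ClusterResult(k=k, labels=pd.Series(labels, index=data.index),
                         centroids=km.cluster_centers_, seed=seed,
                         inertia=float(km.inertia_))


def compute_fom(curves: CurveSet, k_values, seed: int = 0,
                n_restarts: int = 3) -> pd.Series:
    """Leave-one-column-out figure of merit per candidate k.

    For each grid column e: cluster genes on the remaining columns, then
    measure the RMS deviation of each gene from its cluster mean in
    column e.  The FOM for k is the mean over left-out columns.  Lower is
    better; singleton clusters give 0.
    """
    data = curves.curves.loc[~curves.constant].to_numpy()
    n_genes, n_cols = data.shape
    out = {}
    for k in k_values:
        devs = []
        for e in range(n_cols):
            rest = np.delete(data, e, axis=1)
            if k >= n_genes:
                labels = np.arange(n_genes)
            else:
                km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
                labels = km.fit_predict(rest)
            col = data[:, e]
            resid = col - pd.Series(col).groupby(labels).transform("mean").to_numpy()
            devs.append(np.sqrt(np.mean(resid ** 2)))
        out[k] = float(np.mean(devs))
    return pd.Series(out, name="FOM")


def select_coexpressed(target: str, clusters: ClusterResult, curves: CurveSet,
                       z_threshold: float = Z_THRESHOLD) -> CoexpressionList:
    """Same-cluster genes unusually close to the target's curve.

    Euclidean distances from the target to the rest of its cluster are
    Z-transformed; genes with Z strictly below the threshold (default the
    5% normal quantile) are retained.
    """
    if target not in clusters.labels.index:
        raise KeyError(f"target {target} has no cluster label")
    label = clusters.labels[target]
    others = [g for g in clusters.members(label) if g != target]
    empty = pd.DataFrame(columns=["distance", "z"])
    if len(others) < 2:
        log.warning("cluster of target %s too small (%d others); "
                    "Z-score undefined", target, len(others))
        return CoexpressionList(target=target, members=empty, threshold=z_threshold)
    tcurve = curves.gene_curve(target)
    dists = np.linalg.norm(curves.curves.loc[others].to_numpy() - tcurve, axis=1)
    sd = dists.std()
    if sd < 1e-12:
        log.warning("all distances identical for target %s", target)
        return CoexpressionList(target=target, members=empty, threshold=z_threshold)
    z = (dists - dists.mean()) / sd
    df = pd.DataFrame({"distance": dists, "z": z}, index=pd.Index(others, name="gene"))
    df = df[df["z"] < z_threshold].sort_values("z")
    return CoexpressionList(target=target, members=df, threshold=z_threshold)


def aggregate_pathways(expr: pd.DataFrame, bins: pd.Series) -> pd.DataFrame:
    """Mean expression per pathway per time point.

    ``bins`` maps gene id -> pathway name for a subset of genes; pathways
    with no gene present in the matrix get a row of NaN.
    """
    pathways = pd.Index(sorted(bins.unique()), name="pathway")
    present = bins[bins.index.isin(expr.index)]
    grouped = expr.loc[present.index].groupby(present).mean()
    return grouped.reindex(pathways)


__all__ = ["TIMEPOINT_HOURS", "TIMEPOINT_LABELS", "Z_THRESHOLD", "EVAL_GRID",
           "CurveSet", "ClusterResult", "CoexpressionList",
           "read_expression_tsv", "write_expression_tsv", "compute_rpkm",
           "filter_expressed", "smooth_curve", "normalize_sd", "build_curves",
           "kmeans_cluster", "compute_fom", "select_coexpressed",
           "aggregate_pathways"]
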