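"""Spatial statistics: variable genes, modules, regions, DEG, gradients.

Spatially variable genes are scored with Moran's I on a row-normalized
k-nearest-neighbor graph over bin centers, with a permutation null (the
published workflow delegates this statistic to an external tool; Moran's I
with an explicit permutation test is this package's documented stand-in,
and the functions below accept any statistic of the same shape).  Groups
of spatially co-expressed genes become modules by average-linkage
clustering of neighborhood-smoothed expression correlations; per-bin
module scores feed k-means to label functional regions; region pairs are
compared by rank-sum differential expression; gradient genes are checked
by Spearman correlation against one lattice axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix, ValidationError


# ---------------------------------------------------------------------------
# graph
# ---------------------------------------------------------------------------


@dataclass
class SpatialGraph:
    """KNN graph over bin centers with row-normalized (1/k) weights."""

    positions: np.ndarray  # (n, 2) bin coordinates
    neighbors: np.ndarray  # (n, k) int indices, no self
    weights: np.ndarray  # (n, k), rows sum to 1

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]

    def to_sparse(self) -> sparse.csr_matrix:
        n, k = self.neighbors.shape
        rows = np.repeat(np.arange(n), k)
        return sparse.csr_matrix(
            (self.weights.ravel(), (rows, self.neighbors.ravel())), shape=(n, n)
        )


def build_knn_graph(positions: np.ndarray, k: int = 15) -> SpatialGraph:
    """k nearest neighbors by Euclidean distance on bin centers.

    Distance ties are broken by (x, y) lexicographic order of the
    candidate neighbor, so the graph is fully deterministic.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if k < 1 or n <= k:
        raise ValidationError("need n > k >= 1")
    d = cdist(pos, pos)
    np.fill_diagonal(d, np.inf)
    # lexicographic tie-break: stable sort on (distance, x, y)
    order_xy = np.lexsort((pos[:, 1], pos[:, 0]))
    rank_xy = np.empty(n, dtype=np.int64)
    rank_xy[order_xy] = np.arange(n)
    neighbors = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        idx = np.lexsort((rank_xy, d[i]))
        neighbors[i] = idx[:k]
    weights = np.full((n, k), 1.0 / k)
    return SpatialGraph(positions=pos, neighbors=neighbors, weights=weights)


# ---------------------------------------------------------------------------
# Moran's I + permutation SVG test
# ---------------------------------------------------------------------------


def morans_i(values: np.ndarray, graph: SpatialGraph) -> float:
    """Moran's I with row-normalized weights.

    ``I = sum_ij w_ij z_i z_j / sum_i z_i^2`` with ``z`` the centered
    values; because every row of W sums to 1 this equals the classical
    (n / S0)-scaled form.  Constant input is an error (the caller should
    skip such genes).
    """
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValidationError("constant values: Moran's I undefined")
    lagged = (z[graph.neighbors] * graph.weights).sum(axis=1)
    return float(z @ lagged / denom)


def normalize_counts(X: np.ndarray) -> np.ndarray:
    """Depth normalization used before every spatial statistic.

    Counts are scaled to the median per-bin total and log1p transformed.
    Empty bins (zero total) are left at zero.
    """
    X = np.asarray(X, dtype=float)
    totals = X.sum(axis=1)
    med = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    scale = np.divide(med, totals, out=np.zeros_like(totals), where=totals > 0)
    return np.log1p(X * scale[:, None])


def svg_test(
    matrix_or_X,
    graph: SpatialGraph,
    n_perm: int = 500,
    seed: int = 0,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Permutation test for spatial autocorrelation, one row per gene.

    Expression is depth-normalized and log1p transformed, then Moran's I
    is compared against ``n_perm`` random relabelings of the bins (one
    shared set of permutations across genes).  The one-sided p-value uses
    +1 smoothing; q-values are Benjamini-Hochberg across testable genes.
    Constant genes are flagged ``testable = False``.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if isinstance(matrix_or_X, CountMatrix):
        _, genes, X = matrix_or_X.to_dense()
    else:
        X = np.asarray(matrix_or_X, dtype=float)
        if genes is None:
            genes = [f"g{i}" for i in range(X.shape[1])]
    n = X.shape[0]
    if n != graph.n:
        raise ValidationError("matrix bins and graph size disagree")
    Xn = normalize_counts(X)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    W = graph.to_sparse()
    rows = []
    for j, g in enumerate(genes):
        v = Xn[:, j]
        z = v - v.mean()
        denom = float(z @ z)
        if denom == 0:
            rows.append((g, np.nan, np.nan, np.nan, False))
            continue
        i_obs = float(z @ (W @ z) / denom)
        P = z[perms]  # (n_perm, n)
        i_perm = np.einsum("pi,pi->p", P, (W @ P.T).T) / denom
        mu, sd = i_perm.mean(), i_perm.std(ddof=1)
        zscore = (i_obs - mu) / sd if sd > 0 else np.nan
        p = (1 + np.sum(i_perm >= i_obs)) / (n_perm + 1)
        rows.append((g, i_obs, zscore, p, True))
    out = pd.DataFrame(rows, columns=["gene", "moran_i", "z", "p", "testable"])
    out["q"] = np.nan
    testable = out["testable"].to_numpy()
    if testable.any():
        out.loc[testable, "q"] = multipletests(
            out.loc[testable, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return out


# ---------------------------------------------------------------------------
# modules and scores
# ---------------------------------------------------------------------------


@dataclass
class GeneModuleSet:
    """Disjoint gene modules plus an unassigned pool."""

    modules: dict[int, list[str]]
    unassigned: list[str] = field(default_factory=list)

    def labels(self) -> dict[str, int]:
        """gene -> module id (unassigned genes omitted)."""
        return {g: m for m, gs in self.modules.items() for g in gs}


def detect_modules(
    svg_genes: list[str],
    matrix_or_X,
    graph: SpatialGraph,
    n_modules: int | None = None,
    threshold: float = 0.3,
    min_size: int = 2,
    genes: list[str] | None = None,
) -> GeneModuleSet:
    """Group spatially variable genes by correlated expression patterns.

    Expression is neighborhood-smoothed (average of a bin with its graph
    neighbors) before computing pairwise Pearson correlations; modules are
    average-linkage clusters of ``1 - r`` cut either to ``n_modules`` or
    at correlation ``threshold``.  Modules smaller than ``min_size`` fall
    into the unassigned pool.  Module ids are 1..M by decreasing size.
    """
    if len(svg_genes) < 2:
        raise ValidationError("need at least two significant genes")
    if isinstance(matrix_or_X, CountMatrix):
        _, genes, X = matrix_or_X.to_dense()
    else:
        X = np.asarray(matrix_or_X, dtype=float)
        if genes is None:
            raise ValidationError("gene names required with a raw array")
    gene_idx = {g: i for i, g in enumerate(genes)}
    missing = [g for g in svg_genes if g not in gene_idx]
    if missing:
        raise ValidationError(f"genes not in matrix: {missing[:5]}")
    Xn = normalize_counts(X)[:, [gene_idx[g] for g in svg_genes]]
    W = graph.to_sparse()
    smooth = 0.5 * (Xn + W @ Xn)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(smooth.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    Z = linkage(dist, method="average")
    if n_modules is not None:
        lab = fcluster(Z, t=n_modules, criterion="maxclust")
    else:
        lab = fcluster(Z, t=1.0 - threshold, criterion="distance")
    groups: dict[int, list[str]] = {}
    for g, c in zip(svg_genes, lab):
        groups.setdefault(int(c), []).append(g)
    kept = sorted(
        (gs for gs in groups.values() if len(gs) >= min_size),
        key=lambda gs: (-len(gs), gs[0]),
    )
    unassigned = sorted(
        g for gs in groups.values() if len(gs) < min_size for g in gs
    )
    return GeneModuleSet(
        modules={i + 1: sorted(gs) for i, gs in enumerate(kept)}, unassigned=unassigned
    )


def module_scores(
    matrix_or_X, modules: GeneModuleSet, genes: list[str] | None = None
) -> pd.DataFrame:
    """Bins x modules score table.

    Per module: mean over member genes of the per-gene z-score (across
    bins) of normalized expression, re-standardized so every column has
    mean 0 and unit variance.
    """
    if not modules.modules:
        raise ValidationError("no modules supplied")
    if isinstance(matrix_or_X, CountMatrix):
        _, genes, X = matrix_or_X.to_dense()
    else:
        X = np.asarray(matrix_or_X, dtype=float)
        if genes is None:
            raise ValidationError("gene names required with a raw array")
    gene_idx = {g: i for i, g in enumerate(genes)}
    Xn = normalize_counts(X)
    cols = {}
    for mid, members in modules.modules.items():
        idx = [gene_idx[g] for g in members if g in gene_idx]
        if not idx:
            raise ValidationError(f"module {mid} has no measured genes")
        sub = Xn[:, idx]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        score = ((sub - mu) / sd).mean(axis=1)
        s_sd = score.std()
        cols[mid] = (score - score.mean()) / (s_sd if s_sd > 0 else 1.0)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------


@dataclass
class RegionLabels:
    labels: np.ndarray  # per bin, 1..k by decreasing cluster size
    percentages: pd.Series  # cluster -> % of bins
    correlations: pd.DataFrame | None  # k x k Pearson of cluster-mean profiles
    inertia: float


def kmeans_regions(
    score_matrix: pd.DataFrame | np.ndarray,
    k: int = 10,
    seed: int = 0,
    n_init: int = 10,
    expression: np.ndarray | None = None,
) -> RegionLabels:
    """k-means on the module score matrix, relabeled by descending size.

    ``expression`` (bins x genes, normalized) optionally supplies the
    profiles for the k x k cluster correlation table; otherwise the score
    matrix itself is used.
    """
    S = np.asarray(score_matrix, dtype=float)
    n = len(S)
    if k < 1 or k > n:
        raise ValidationError("need 1 <= k <= n bins")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(S)
    sizes = pd.Series(raw).value_counts()
    remap = {old: rank + 1 for rank, old in enumerate(sizes.index)}
    labels = np.array([remap[c] for c in raw])
    percentages = (
        pd.Series(labels).value_counts(normalize=True).sort_index() * 100.0
    )
    profile_src = expression if expression is not None else S
    prof = np.vstack(
        [profile_src[labels == c].mean(axis=0) for c in range(1, k + 1)]
    )
    if k >= 2 and prof.shape[1] >= 2:
        corr = pd.DataFrame(
            np.corrcoef(prof), index=range(1, k + 1), columns=range(1, k + 1)
        )
    else:
        corr = None
    return RegionLabels(
        labels=labels,
        percentages=percentages,
        correlations=corr,
        inertia=float(km.inertia_),
    )


# ---------------------------------------------------------------------------
# differential expression and gradients
# ---------------------------------------------------------------------------


def deg_between(
    matrix_or_X,
    labels: np.ndarray,
    cluster_a: int,
    cluster_b: int,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DEG table between two region clusters.

    Positive log2 fold change (pseudocount 1 on cluster-mean normalized
    expression) means higher in ``cluster_a``.  Sorted by q then |lfc|.
    """
    if isinstance(matrix_or_X, CountMatrix):
        _, genes, X = matrix_or_X.to_dense()
    else:
        X = np.asarray(matrix_or_X, dtype=float)
        if genes is None:
            raise ValidationError("gene names required with a raw array")
    labels = np.asarray(labels)
    in_a = labels == cluster_a
    in_b = labels == cluster_b
    if in_a.sum() < 3 or in_b.sum() < 3:
        raise ValidationError("each cluster needs >= 3 bins")
    Xn = normalize_counts(X)
    A, B = Xn[in_a], Xn[in_b]
    rows = []
    for j, g in enumerate(genes):
        a, b = A[:, j], B[:, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        lfc = float(np.log2((a.mean() + 1.0) / (b.mean() + 1.0)))
        rows.append((g, p, lfc))
    out = pd.DataFrame(rows, columns=["gene", "p", "log2fc"])
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["abs_lfc"] = out["log2fc"].abs()
    out = (
        out.sort_values(["q", "abs_lfc"], ascending=[True, False])
        .drop(columns="abs_lfc")
        .reset_index(drop=True)
    )
    return out


def gradient_check(
    matrix_or_X,
    gene: str,
    axis: str = "y",
    positions: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    genes: list[str] | None = None,
) -> dict:
    """Monotone-trend statistic along one axis for a single gene.

    Spearman correlation of per-bin normalized expression against the
    axis coordinate; two-sided permutation p-value.  Positive rho means
    expression increases toward high coordinates (distal for +y).
    """
    if isinstance(matrix_or_X, CountMatrix):
        bins, genes, X = matrix_or_X.to_dense()
        positions = bins[["x", "y"]].to_numpy()
    else:
        X = np.asarray(matrix_or_X, dtype=float)
        if genes is None or positions is None:
            raise ValidationError("gene names and positions required with a raw array")
    if gene not in genes:
        raise ValidationError(f"gene {gene!r} not measured")
    if axis not in ("x", "y"):
        raise ValidationError("axis must be 'x' or 'y'")
    coord = np.asarray(positions, dtype=float)[:, 0 if axis == "x" else 1]
    v = normalize_counts(X)[:, list(genes).index(gene)]
    # Spearman = Pearson on (tie-averaged) ranks; permuting values permutes
    # their ranks, so the whole null can be done with one matrix product.
    rv = stats.rankdata(v) - (len(v) + 1) / 2.0
    rc = stats.rankdata(coord) - (len(coord) + 1) / 2.0
    norm = np.sqrt((rv @ rv) * (rc @ rc))
    if norm == 0:
        return {"gene": gene, "axis": axis, "rho": float("nan"), "p": float("nan")}
    rho = float(rv @ rc / norm)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(len(v)) for _ in range(n_perm)])
    rho_perm = (rv[perms] @ rc) / norm
    p = (1 + int(np.sum(np.abs(rho_perm) >= abs(rho)))) / (n_perm + 1)
    return {"gene": gene, "axis": axis, "rho": rho, "p": p}
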