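"""PCA biplots, principal-axis side-preference tests and hierarchical clustering.

The biplot treats samples as observations and genes as standardized variables
(correlation-mode PCA): each gene is centered and scaled to unit variance
across the samples, so genes spanning four orders of magnitude of FPKM
contribute equally rather than the plot being dominated by a few very highly
expressed genes.  Sample scores and gene coordinates (loadings scaled by the
singular values) live on the same pair of axes.

Raw SVD output has an arbitrary sign per component.  PC1 is oriented so that
gene PC1 coordinates correlate non-negatively with raw mean expression —
"right of the plot" then always reads as "elevated overall expression", and
downstream side counts are reproducible.  Higher components get their sign
fixed by making the largest-magnitude gene coordinate positive (first such
gene in input order on ties).

The side-preference question — do the items of a labelled subset fall on one
side of PC1 more often than chance? — is answered with an exact binomial test
at p0 = 0.5 by direct pmf summation (two-sided: all outcomes with pmf no
larger than the observed one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.stats import binom

logger = logging.getLogger(__name__)

_LINKAGES = {"ward", "single", "complete", "average", "centroid", "median",
             "weighted"}


@dataclass
class BiplotResult:
    """Joint sample/gene coordinates on principal axes."""

    sample_scores: pd.DataFrame        # samples × PCs
    gene_coords: pd.DataFrame          # genes × PCs (loadings × singular values)
    explained_variance_ratio: np.ndarray
    dropped_genes: tuple[str, ...]     # zero-variance genes removed
    standardized: bool
    orientation: str = "PC1 sign: corr(gene coords, gene mean expression) >= 0"


@dataclass
class SideCounts:
    n_left: int
    n_right: int
    n_zero: int                        # zero coordinates, counted right, flagged

    @property
    def n(self) -> int:
        return self.n_left + self.n_right


@dataclass
class BinomialTestResult:
    """Exact binomial side-preference test at p0 = 0.5."""

    n: int
    k: int
    p0: float
    sidedness: str                     # one-sided-ge | one-sided-le | two-sided
    p_value: float


@dataclass
class ClusterAssignment:
    """Flat partition from agglomerative clustering."""

    labels: pd.Series                  # item id -> cluster id (1-based)
    method: str
    criterion: str                     # "maxclust" or "distance"
    threshold: float

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def pca_biplot(
    matrix: pd.DataFrame,
    genes: Sequence[str] | None = None,
    samples: Sequence[str] | None = None,
    n_components: int = 2,
    standardize: bool = True,
) -> BiplotResult:
    """Correlation-mode PCA biplot of samples against a gene set.

    ``matrix`` is genes × samples FPKM.  Zero-variance genes are dropped with
    a log entry; at least two genes and two samples must remain.
    ``standardize=False`` switches to covariance-mode (centered only).
    """
    sub = matrix
    if genes is not None:
        missing = [g for g in genes if g not in matrix.index]
        if missing:
            raise ValueError(f"genes not in matrix: {missing[:5]}")
        sub = sub.loc[list(genes)]
    if samples is not None:
        sub = sub[list(samples)]
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = sub.T.to_numpy(dtype=float)          # samples × genes
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = tuple(np.asarray(sub.index)[~keep])
    if dropped:
        logger.info("pca_biplot: dropped %d zero-variance gene(s)", len(dropped))
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes with non-zero variance")
    X = X[:, keep]
    gene_ids = list(np.asarray(sub.index)[keep])
    raw_means = sub.to_numpy(dtype=float)[keep].mean(axis=1)
    Z = X - X.mean(axis=0)
    if standardize:
        Z = Z / sd[keep]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    n_components = min(n_components, len(S))
    var_ratio = S ** 2 / (S ** 2).sum()

    scores = U[:, :n_components] * S[:n_components]
    coords = Vt[:n_components].T * S[:n_components]
    # deterministic orientation, component by component
    for j in range(n_components):
        if j == 0:
            c = np.corrcoef(coords[:, 0], raw_means)[0, 1]
            flip = c < 0
        else:
            lead = np.argmax(np.abs(coords[:, j]))
            flip = coords[lead, j] < 0
        if flip:
            scores[:, j] *= -1
            coords[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    return BiplotResult(
        sample_scores=pd.DataFrame(scores, index=sub.columns, columns=pcs),
        gene_coords=pd.DataFrame(coords, index=gene_ids, columns=pcs),
        explained_variance_ratio=var_ratio,
        dropped_genes=dropped,
        standardized=standardize,
    )


def side_counts(coordinates: pd.Series,
                items: Sequence[str] | None = None) -> SideCounts:
    """Count items left (negative) / right (positive) of zero on one axis.

    Exact zeros — a measure-zero event on real data — are counted right and
    flagged in ``n_zero``.
    """
    coords = coordinates if items is None else coordinates.loc[list(items)]
    if len(coords) == 0:
        raise ValueError("empty item subset")
    vals = coords.to_numpy(dtype=float)
    n_zero = int((vals == 0).sum())
    if n_zero:
        logger.warning("side_counts: %d zero coordinate(s) counted as right",
                       n_zero)
    return SideCounts(n_left=int((vals < 0).sum()),
                      n_right=int((vals >= 0).sum()), n_zero=n_zero)


def binomial_side_test(n: int, k: int,
                       sidedness: str = "two-sided") -> BinomialTestResult:
    """Exact binomial test of k successes in n trials at p0 = 0.5.

    Direct pmf summation: ``one-sided-ge`` sums the upper tail, ``one-sided-le``
    the lower, and ``two-sided`` all outcomes whose pmf does not exceed the
    observed one (within a 1e-12 relative tolerance for floating ties).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    pmf = binom.pmf(np.arange(n + 1), n, 0.5)
    if sidedness == "one-sided-ge":
        p = pmf[k:].sum()
    elif sidedness == "one-sided-le":
        p = pmf[: k + 1].sum()
    elif sidedness == "two-sided":
        p = pmf[pmf <= pmf[k] * (1 + 1e-12)].sum()
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return BinomialTestResult(n=n, k=k, p0=0.5, sidedness=sidedness,
                              p_value=float(min(p, 1.0)))


def side_preference_tests(counts: SideCounts) -> list[BinomialTestResult]:
    """Both standard reports for a side count: the two-sided test on the
    right-side count and the one-sided (ge) test on the majority side."""
    two = binomial_side_test(counts.n, counts.n_right, "two-sided")
    k_major = max(counts.n_left, counts.n_right)
    one = binomial_side_test(counts.n, k_major, "one-sided-ge")
    return [two, one]


def ahc_cluster(
    matrix: pd.DataFrame,
    genes: Sequence[str] | None = None,
    n_clusters: int | None = None,
    height: float | None = None,
    method: str = "ward",
    standardize: bool = True,
) -> ClusterAssignment:
    """Agglomerative clustering of gene profiles (Euclidean, Ward by default).

    Cut either at ``n_clusters`` or at ``height``; exactly one must be given.
    Profiles are standardized per gene unless ``standardize=False``.
    scipy's linkage is deterministic for a given input order; ties merge the
    lowest-index pair first.
    """
    if method not in _LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; choose from "
                         f"{sorted(_LINKAGES)}")
    if (n_clusters is None) == (height is None):
        raise ValueError("give exactly one of n_clusters or height")
    sub = matrix if genes is None else matrix.loc[list(genes)]
    if len(sub) < 2:
        raise ValueError("need at least 2 items to cluster")
    X = sub.to_numpy(dtype=float)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    Z = scipy_linkage(X, method=method, metric="euclidean")
    if n_clusters is not None:
        flat = fcluster(Z, t=n_clusters, criterion="maxclust")
        crit, thr = "maxclust", float(n_clusters)
    else:
        flat = fcluster(Z, t=height, criterion="distance")
        crit, thr = "distance", float(height)
    return ClusterAssignment(
        labels=pd.Series(flat, index=sub.index, name="cluster"),
        method=method, criterion=crit, threshold=thr,
    )
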