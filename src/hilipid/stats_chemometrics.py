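"""Group statistics and multivariate structure of intraclass lipid profiles.

Ratios are compared across cell lines with a post hoc Tukey HSD test
(studentized-range distribution after one-way ANOVA).  Intraclass relative
abundance matrices (samples x species) are autoscaled (z-scored per species),
then summarized by PCA (SVD of the centered matrix, with per-group 95%
confidence ellipses in the PC1/PC2 plane) and by hierarchical clustering
(UPGMA on Euclidean distances) with heatmap export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import DataError

log = logging.getLogger(__name__)

#: chi-square quantile (2 df, 95%) sizing the confidence ellipses
CHI2_95_2DF = float(stats.chi2.ppf(0.95, 2))

#: significance thresholds and their star annotations
STAR_LEVELS = ((0.001, "***"), (0.005, "**"), (0.01, "*"))


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_LEVELS:
        if p < threshold:
            return stars
    return ""


# --------------------------------------------------------------------------
# Autoscaling
# --------------------------------------------------------------------------

def autoscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to sample standard deviation 1.

    Constant columns carry no information after scaling and are dropped with
    a warning.
    """
    if len(matrix) < 2:
        raise DataError("autoscaling needs at least two rows")
    sd = matrix.std(axis=0, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        log.warning("dropping %d constant column(s): %s", len(constant), list(constant))
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(constant)
    return (matrix - matrix.mean(axis=0)) / sd


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class ConfidenceEllipse:
    """95% ellipse of one group's scores in the PC1/PC2 plane."""

    center: np.ndarray          # (2,)
    axes: np.ndarray            # semi-axis lengths, descending
    directions: np.ndarray      # (2, 2) unit axis directions (columns)
    covariance: np.ndarray      # (2, 2) group score covariance

    def boundary(self, n: int = 360) -> np.ndarray:
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        return (self.center[:, None] + self.directions @ (self.axes[:, None] * circle)).T

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points) - self.center
        inv = np.linalg.inv(self.covariance)
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return d2 <= CHI2_95_2DF


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fractions: np.ndarray
    ellipses: dict[str, ConfidenceEllipse]


def run_pca(matrix: pd.DataFrame, groups: Mapping[str, str] | pd.Series | None = None) -> PcaResult:
    """PCA by SVD of the (re)centered autoscaled matrix.

    The sign of each component is fixed so that its largest-magnitude loading
    is positive, making outputs deterministic.  ``groups`` maps row label ->
    group label; groups with >= 2 rows get a 95% confidence ellipse from their
    2-D score covariance scaled by the chi-square(2 df) quantile.
    """
    if len(matrix) < 2:
        raise DataError("PCA needs at least two samples")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for k in range(s.size):  # deterministic sign convention
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    names = [f"PC{i + 1}" for i in range(s.size)]
    scores = pd.DataFrame(u * s, index=matrix.index, columns=names)
    loadings = pd.DataFrame(vt.T, index=matrix.columns, columns=names)
    total = float((s ** 2).sum())
    fractions = (s ** 2) / total if total > 0 else np.zeros_like(s)

    ellipses: dict[str, ConfidenceEllipse] = {}
    if groups is not None:
        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        for label in groups.unique():
            members = scores.loc[groups[groups == label].index, ["PC1", "PC2"]]
            if len(members) < 2:
                continue
            cov = np.cov(members.to_numpy().T, ddof=1)
            evals, evecs = np.linalg.eigh(cov)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            ellipses[str(label)] = ConfidenceEllipse(
                center=members.mean().to_numpy(),
                axes=np.sqrt(np.maximum(evals, 0) * CHI2_95_2DF),
                directions=evecs,
                covariance=cov,
            )
    return PcaResult(scores=scores, loadings=loadings,
                     variance_fractions=fractions, ellipses=ellipses)


def ellipses_disjoint(a: ConfidenceEllipse, b: ConfidenceEllipse, n: int = 720) -> bool:
    """Numeric disjointness check: no boundary point of one inside the other."""
    if a.contains(b.center[None, :]).any() or b.contains(a.center[None, :]).any():
        return False
    return not (b.contains(a.boundary(n)).any() or a.contains(b.boundary(n)).any())


# --------------------------------------------------------------------------
# Hierarchical clustering (UPGMA, Euclidean)
# --------------------------------------------------------------------------

@dataclass
class HcaResult:
    labels: list[str]
    linkage: np.ndarray            # scipy merge list
    cophenetic: pd.DataFrame       # labels x labels ultrametric distances
    leaf_order: list[str]

    def cut(self, n_clusters: int) -> pd.Series:
        assignment = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(assignment, index=self.labels, name="cluster")

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            return (
                f"({render(left)}:{node.dist - left.dist:.6g},"
                f"{render(right)}:{node.dist - right.dist:.6g})"
            )

        return render(tree) + ";"


def run_hca(matrix: pd.DataFrame, axis: str = "samples") -> HcaResult:
    """Agglomerative clustering with unweighted average linkage (UPGMA)."""
    if axis == "variables":
        matrix = matrix.T
    elif axis != "samples":
        raise DataError(f"unknown HCA axis {axis!r}")
    if len(matrix) < 2:
        raise DataError("HCA needs at least two items")
    x = matrix.to_numpy(dtype=float)
    dists = pdist(x, metric="euclidean")
    if np.any(~np.isfinite(dists)):
        raise DataError("non-finite distances in HCA input")
    linkage = hierarchy.linkage(dists, method="average")
    coph = squareform(hierarchy.cophenet(linkage))
    labels = [str(lbl) for lbl in matrix.index]
    leaf_order = [labels[i] for i in hierarchy.leaves_list(linkage)]
    return HcaResult(
        labels=labels,
        linkage=linkage,
        cophenetic=pd.DataFrame(coph, index=labels, columns=labels),
        leaf_order=leaf_order,
    )


def heatmap_frame(matrix: pd.DataFrame, samples: HcaResult, variables: HcaResult) -> pd.DataFrame:
    """Autoscaled values reordered by both dendrograms' leaf orders."""
    return matrix.loc[samples.leaf_order, variables.leaf_order]


def export_heatmap_png(frame: pd.DataFrame, path: str | Path) -> None:
    """Optional image export with a symmetric color scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    span = float(np.nanmax(np.abs(frame.to_numpy()))) or 1.0
    fig, ax = plt.subplots(figsize=(max(6, 0.18 * frame.shape[1]), max(4, 0.3 * frame.shape[0])))
    im = ax.imshow(frame.to_numpy(), cmap="RdBu_r", vmin=-span, vmax=span, aspect="auto")
    ax.set_yticks(range(frame.shape[0]), frame.index, fontsize=7)
    ax.set_xticks(range(frame.shape[1]), frame.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="autoscaled abundance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# --------------------------------------------------------------------------
# Tukey HSD
# --------------------------------------------------------------------------

def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All-pairs Tukey HSD; returns group pair, mean difference, p, stars.

    With zero pooled within-group variance and unequal means the studentized
    range statistic diverges; those p-values are reported as 1e-12 (< 1e-10).
    """
    names = list(groups)
    arrays = [np.asarray(groups[name], dtype=float) for name in names]
    if len(arrays) < 2:
        raise DataError("Tukey HSD needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise DataError("every group needs at least two values")
    mse = np.sum([(a - a.mean()) ** 2 for a in arrays]) / (
        sum(a.size for a in arrays) - len(arrays)
    )
    rows = []
    if mse > 0:
        result = stats.tukey_hsd(*arrays)
        for i, j in combinations(range(len(arrays)), 2):
            p = float(result.pvalue[i, j])
            rows.append((names[i], names[j], float(arrays[i].mean() - arrays[j].mean()), p))
    else:
        for i, j in combinations(range(len(arrays)), 2):
            diff = float(arrays[i].mean() - arrays[j].mean())
            rows.append((names[i], names[j], diff, 1.0 if diff == 0 else 1e-12))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_difference", "p_value"])
    out["stars"] = out["p_value"].map(significance_stars)
    return out
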