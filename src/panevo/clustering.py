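"""Genome clustering and ordination: 1 - gANI and binary-Jaccard distance
matrices, group-average (UPGMA) hierarchical clustering with elbow-method
selection of the cluster count, principal coordinates analysis, a
permutation Z-score for the influence of individual genes on the PCoA
axes, and Fisher-exact enrichment of cluster labels against categorical
metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact, norm

from panevo.io import PresenceAbsenceMatrix, SquareDistanceMatrix
from panevo.cooccur import bh_adjust

logger = logging.getLogger("panevo")

__all__ = [
    "ClusteringResult",
    "PCoAResult",
    "ani_to_distance",
    "jaccard_distance",
    "hca_cluster",
    "choose_k_elbow",
    "pcoa",
    "gene_influence",
    "categorical_enrichment",
]

DUAL_P_THRESHOLD = 1e-5
DUAL_FDR_THRESHOLD = 0.05


@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray  # per-item cluster assignment in 1..k
    wcss_curve: np.ndarray  # medoid WCSS for k = 1..k_max
    linkage: str
    distance_source: str


@dataclass
class PCoAResult:
    """Classical-scaling coordinates; eigenvalues sorted descending, only
    positive-eigenvalue axes retained."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray


def ani_to_distance(labels: Sequence[str],
                    gani: np.ndarray) -> SquareDistanceMatrix:
    """Convert a square genome-identity matrix to distances d = 1 - gANI.

    Percent-scale inputs (diagonal 100) are normalised to fractions first.
    """
    gani = np.asarray(gani, dtype=float)
    if not np.allclose(gani, gani.T, atol=1e-6):
        raise ValueError("identity matrix asymmetric beyond 1e-6")
    scale = float(np.median(np.diag(gani)))
    if scale > 1.5:  # percent input
        gani = gani / 100.0
        scale /= 100.0
    if abs(scale - 1.0) > 1e-6:
        raise ValueError(
            f"identity diagonal is {scale:g}, expected the scale maximum")
    dist = 1.0 - gani
    np.fill_diagonal(dist, 0.0)
    return SquareDistanceMatrix(list(labels), dist)


def jaccard_distance(matrix: PresenceAbsenceMatrix) -> SquareDistanceMatrix:
    """Pairwise Jaccard distances between genome gene sets:
    d(i, j) = 1 - |intersection| / |union|, and 0 when both sets are
    empty."""
    v = matrix.values.astype(np.int64)
    inter = v @ v.T
    sizes = v.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - inter / union
    dist[union == 0] = 0.0
    np.fill_diagonal(dist, 0.0)
    # exact symmetry despite float division order
    dist = (dist + dist.T) / 2.0
    return SquareDistanceMatrix(list(matrix.genome_ids), dist)


def _medoid_wcss(dist: np.ndarray, labels: np.ndarray) -> float:
    """Sum over clusters of squared distances to the cluster medoid (the
    member minimising that sum)."""
    total = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        sq = dist[np.ix_(idx, idx)] ** 2
        total += float(sq.sum(axis=0).min())
    return total


def hca_cluster(dist: SquareDistanceMatrix, k_max: int,
                k: Optional[int] = None,
                distance_source: str = "precomputed") -> ClusteringResult:
    """Group-average (UPGMA) agglomeration on the given distances.

    Distances are used as-is (no re-standardisation).  For each candidate
    cluster count the tree is cut and the within-cluster sum of squared
    distances to the cluster medoid computed; when ``k`` is not supplied it
    is chosen by :func:`choose_k_elbow` on that curve.
    """
    n = len(dist.labels)
    if not 2 <= k_max < n:
        raise ValueError("k_max must satisfy 2 <= k_max < n items")
    if k is not None and k > n:
        raise ValueError("k exceeds the number of items")
    Z = linkage(squareform(dist.values, checks=False), method="average")
    wcss = np.empty(k_max)
    cuts = {}
    for kk in range(1, k_max + 1):
        lab = fcluster(Z, t=kk, criterion="maxclust")
        cuts[kk] = lab
        wcss[kk - 1] = _medoid_wcss(dist.values, lab)
    if k is None:
        k = choose_k_elbow(wcss)
    labels = cuts.get(k)
    if labels is None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    k_eff = len(np.unique(labels))
    if k_eff != k:
        logger.warning("requested %d clusters, cut produced %d (ties in the "
                       "dendrogram)", k, k_eff)
        k = k_eff
    # relabel to 1..k in order of first appearance
    remap = {}
    out = np.empty_like(labels)
    for i, l in enumerate(labels):
        out[i] = remap.setdefault(l, len(remap) + 1)
    return ClusteringResult(k=k, labels=out, wcss_curve=wcss,
                            linkage="average", distance_source=distance_source)


def choose_k_elbow(wcss_curve: Sequence[float]) -> int:
    """Elbow point of a non-increasing WCSS curve for k = 1..k_max: the k
    maximising the perpendicular distance from (k, WCSS_k) to the chord
    joining the first and last points; ties break toward smaller k."""
    w = np.asarray(wcss_curve, dtype=float)
    if len(w) < 3:
        raise ValueError("WCSS curve needs at least 3 points")
    if (np.diff(w) > 1e-9 * max(1.0, abs(w[0]))).any():
        raise ValueError("WCSS curve must be non-increasing")
    ks = np.arange(1, len(w) + 1, dtype=float)
    x1, y1 = ks[0], w[0]
    x2, y2 = ks[-1], w[-1]
    chord = np.hypot(x2 - x1, y2 - y1)
    if chord == 0:
        return 2
    d = np.abs((y2 - y1) * ks - (x2 - x1) * w + x2 * y1 - y2 * x1) / chord
    interior = d[1:-1]
    if np.allclose(interior, interior.max()):
        # flat (e.g. exactly linear curve): smallest interior k
        return 2
    return int(np.argmax(d[1:-1]) + 2)


def pcoa(dist: SquareDistanceMatrix, n_axes: int = 3) -> PCoAResult:
    """Classical scaling (principal coordinates analysis).

    Double-centres -1/2 d**2, eigendecomposes, and returns eigenvectors
    scaled by the square root of their (positive) eigenvalues.  Negative
    eigenvalues are dropped from the variance-explained denominator and
    logged.  If fewer positive eigenvalues than ``n_axes`` exist, fewer
    axes are returned with a warning.
    """
    if n_axes < 2:
        raise ValueError("n_axes must be >= 2")
    D2 = dist.values.astype(float) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-8 * max(1.0, float(abs(eigval[0])))
    pos = eigval > tol
    n_neg = int((eigval < -tol).sum())
    if n_neg:
        logger.info("PCoA: %d negative eigenvalue(s) dropped from the "
                    "variance-explained denominator", n_neg)
    n_pos = int(pos.sum())
    if n_pos < n_axes:
        logger.warning("PCoA: only %d positive eigenvalue(s); returning "
                       "%d axes instead of %d", n_pos, n_pos, n_axes)
    keep = min(n_axes, n_pos)
    lam = eigval[:keep]
    coords = eigvec[:, :keep] * np.sqrt(lam)
    total_pos = float(eigval[pos].sum())
    return PCoAResult(coordinates=coords, eigenvalues=lam,
                      variance_explained=lam / total_pos)


def gene_influence(pcoa_result: PCoAResult,
                   matrix: PresenceAbsenceMatrix,
                   n_permutations: int = 1000,
                   seed: Optional[int] = None) -> pd.DataFrame:
    """Permutation Z-score of each gene's influence on each PCoA axis.

    The observed statistic is the difference between the mean axis
    coordinate of carrier and non-carrier genomes; the null redistributes
    the gene's presence labels at random.  Two-sided p-values come from
    the standard-normal tail of the permutation Z; Benjamini-Hochberg
    adjustment runs across all gene x axis tests.  Genes without variation
    (prevalence 0 or 1) are skipped.

    Returns a tidy frame (cog_id, axis, z_score, p_value, p_bh,
    significant, significant_any).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations < 100 gives an unstable null")
    coords = pcoa_result.coordinates
    n, n_axes = coords.shape
    if matrix.n_genomes != n:
        raise ValueError("matrix rows do not align with PCoA coordinates")
    rng = np.random.default_rng(seed)
    axis_mean = coords.mean(axis=0)

    rows = []
    for j, cog in enumerate(matrix.cog_ids):
        carrier = matrix.values[:, j].astype(bool)
        k = int(carrier.sum())
        if k == 0 or k == n:
            continue
        obs = coords[carrier].mean(axis=0) - coords[~carrier].mean(axis=0)
        # null: means over random k-subsets; difference of means is a
        # linear function of the carrier-subset sum
        u = rng.random((n_permutations, n))
        sel = np.argpartition(u, k - 1, axis=1)[:, :k]
        sums = coords[sel].sum(axis=1)  # (n_perm, n_axes)
        null = sums / k - (n * axis_mean - sums) / (n - k)
        mu = null.mean(axis=0)
        sd = null.std(axis=0, ddof=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (obs - mu) / sd,
                         np.where(np.isclose(obs, mu), 0.0, np.inf))
        p = 2.0 * norm.sf(np.abs(z))
        for a in range(n_axes):
            rows.append((cog, a + 1, float(z[a]), float(p[a])))

    out = pd.DataFrame(rows, columns=["cog_id", "axis", "z_score", "p_value"])
    if out.empty:
        out["p_bh"] = out["significant"] = out["significant_any"] = []
        return out
    out["p_bh"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["p_bh"] < 0.05
    any_sig = out.groupby("cog_id")["significant"].transform("any")
    out["significant_any"] = any_sig
    return out


def categorical_enrichment(labels_a: Sequence, labels_b: Sequence
                           ) -> pd.DataFrame:
    """One-vs-rest Fisher exact tests for every (A-level, B-level) pair.

    Returns a frame with odds ratio, two-sided p, Benjamini-Hochberg p over
    all pairs, and a significance flag at the dual threshold
    p < 1e-5 AND p_bh < 0.05.  Levels covering all items (empty complement)
    are excluded with a warning.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must cover the same items")
    rows = []
    for la in np.unique(a):
        in_a = a == la
        if in_a.all():
            logger.warning("category %r covers all items; excluded from "
                           "enrichment testing", la)
            continue
        for lb in np.unique(b):
            in_b = b == lb
            if in_b.all():
                logger.warning("category %r covers all items; excluded from "
                               "enrichment testing", lb)
                continue
            table = [[int((in_a & in_b).sum()), int((in_a & ~in_b).sum())],
                     [int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())]]
            odds, p = fisher_exact(table, alternative="two-sided")
            rows.append((la, lb, float(odds), float(p)))
    out = pd.DataFrame(rows, columns=["level_a", "level_b", "odds_ratio",
                                      "p_value"])
    if out.empty:
        out["p_bh"] = out["significant"] = []
        return out
    out["p_bh"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = ((out["p_value"] < DUAL_P_THRESHOLD)
                          & (out["p_bh"] < DUAL_FDR_THRESHOLD))
    return out
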