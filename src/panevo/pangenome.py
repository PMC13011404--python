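"""Pangenome structure: prevalence partition (core / soft-core / shell /
cloud), permutation-averaged gene-accumulation curves, Heaps'-law fitting
of the new-gene decay, and species-exclusive soft-core COG discovery.

The openness criterion follows the Tettelin convention: the expected number
of novel gene clusters contributed by the N-th genome is modelled as
n_new(N) = kappa * N**(-alpha), fitted by ordinary least squares on the
log-log curve; the pangenome is called closed iff alpha > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from panevo.io import PresenceAbsenceMatrix

logger = logging.getLogger("panevo")

__all__ = [
    "PangenomePartition",
    "AccumulationCurves",
    "HeapsFit",
    "partition_pangenome",
    "accumulation_curves",
    "fit_heaps",
    "find_species_specific_cogs",
]


@dataclass
class PangenomePartition:
    """Disjoint COG classes by prevalence (fraction of genomes carrying the
    COG): core >= core_min, soft_core >= soft_min, shell >= cloud_max,
    cloud below."""

    core: set[str]
    soft_core: set[str]
    shell: set[str]
    cloud: set[str]
    prevalence: pd.Series

    def class_of(self) -> pd.Series:
        out = pd.Series("cloud", index=self.prevalence.index, dtype=object)
        out[list(self.shell)] = "shell"
        out[list(self.soft_core)] = "soft_core"
        out[list(self.core)] = "core"
        return out


@dataclass
class AccumulationCurves:
    """Permutation-averaged pangenome growth.

    ``mean_pangenome_size[N-1]`` is the expected number of distinct COGs
    after N genomes; ``mean_new_genes[N-1]`` the expected number of novel
    COGs contributed by the N-th genome.
    """

    n_permutations: int
    mean_pangenome_size: np.ndarray
    mean_new_genes: np.ndarray
    sd_pangenome_size: np.ndarray
    sd_new_genes: np.ndarray
    seed: Optional[int] = None


@dataclass
class HeapsFit:
    """Fitted new-gene decay law n_new(N) = kappa * N**(-alpha)."""

    kappa: float
    alpha: float
    r_squared: float
    verdict: str  # "closed" iff alpha > 1, else "open"


def partition_pangenome(matrix: PresenceAbsenceMatrix,
                        core_min: float = 0.99,
                        soft_min: float = 0.95,
                        cloud_max: float = 0.15) -> PangenomePartition:
    """Partition COGs by prevalence.

    Boundary convention: prevalence exactly ``core_min`` is core, exactly
    ``soft_min`` is soft-core, exactly ``cloud_max`` is shell.
    """
    if not 0 < cloud_max < soft_min < core_min <= 1:
        raise ValueError("thresholds must satisfy 0 < cloud_max < soft_min "
                         "< core_min <= 1")
    if matrix.n_genomes == 0 or matrix.n_cogs == 0:
        raise ValueError("empty presence/absence matrix")
    counts = matrix.values.sum(axis=0).astype(np.int64)
    n = matrix.n_genomes
    prevalence = pd.Series(counts / n, index=matrix.cog_ids)
    # integer comparisons against threshold counts avoid float-boundary slips
    eps = 1e-9
    core = counts >= core_min * n - eps
    soft = (~core) & (counts >= soft_min * n - eps)
    cloud = counts < cloud_max * n - eps
    shell = ~(core | soft | cloud)
    ids = np.array(matrix.cog_ids)
    return PangenomePartition(
        core=set(ids[core]), soft_core=set(ids[soft]),
        shell=set(ids[shell]), cloud=set(ids[cloud]),
        prevalence=prevalence,
    )


def accumulation_curves(matrix: PresenceAbsenceMatrix,
                        n_permutations: int = 1000,
                        seed: Optional[int] = None) -> AccumulationCurves:
    """Average the gene-accumulation curve over random genome orderings.

    For each permutation, genomes are added one at a time; the cumulative
    number of distinct COGs and the per-step novel-COG count are recorded,
    and means and standard deviations across permutations returned.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    vals = matrix.values.astype(bool)
    G = matrix.n_genomes
    sum_size = np.zeros(G)
    sumsq_size = np.zeros(G)
    sum_new = np.zeros(G)
    sumsq_new = np.zeros(G)
    for _ in range(n_permutations):
        order = rng.permutation(G)
        seen = np.logical_or.accumulate(vals[order], axis=0)
        sizes = seen.sum(axis=1).astype(float)
        new = np.diff(sizes, prepend=0.0)
        sum_size += sizes
        sumsq_size += sizes**2
        sum_new += new
        sumsq_new += new**2
    m = float(n_permutations)
    mean_size = sum_size / m
    mean_new = sum_new / m
    sd_size = np.sqrt(np.maximum(sumsq_size / m - mean_size**2, 0.0))
    sd_new = np.sqrt(np.maximum(sumsq_new / m - mean_new**2, 0.0))
    return AccumulationCurves(n_permutations, mean_size, mean_new,
                              sd_size, sd_new, seed)


def fit_heaps(curves: AccumulationCurves, skip_first: int = 1) -> HeapsFit:
    """Fit log(mean_new_genes) on log(N) by ordinary least squares.

    The first ``skip_first`` points (the first genome contributes its whole
    gene complement, not a discovery-law point) and any zero values are
    excluded.  alpha = -slope, kappa = exp(intercept); verdict is closed
    iff alpha > 1.
    """
    new = np.asarray(curves.mean_new_genes, dtype=float)
    N = np.arange(1, len(new) + 1, dtype=float)
    usable = (N > skip_first) & (new > 0)
    if usable.sum() < 3:
        raise ValueError("curve too short or saturated: fewer than 3 usable "
                         "points for the Heaps fit")
    x = np.log(N[usable])
    y = np.log(new[usable])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean())**2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    alpha = -float(slope)
    return HeapsFit(kappa=float(np.exp(intercept)), alpha=alpha,
                    r_squared=r2,
                    verdict="closed" if alpha > 1 else "open")


def find_species_specific_cogs(multi_matrix: PresenceAbsenceMatrix,
                               species_labels: Mapping[str, str],
                               focal: str,
                               soft_min: float = 0.95,
                               other_max: float = 0.0) -> set[str]:
    """COGs in the focal species' soft-core that every other species lacks.

    Returns COGs with prevalence >= soft_min among focal genomes and
    prevalence <= other_max within each other species.
    """
    labels = np.array([species_labels[g] for g in multi_matrix.genome_ids])
    species = sorted(set(labels))
    if focal not in species:
        raise ValueError(f"focal species {focal!r} has no genomes")
    eps = 1e-9
    keep = np.ones(multi_matrix.n_cogs, dtype=bool)
    for sp in species:
        rows = multi_matrix.values[labels == sp]
        if rows.shape[0] == 0:
            raise ValueError(f"species {sp!r} has zero genomes")
        prev = rows.sum(axis=0) / rows.shape[0]
        if sp == focal:
            keep &= prev >= soft_min - eps
        else:
            keep &= prev <= other_max + eps
    ids = np.array(multi_matrix.cog_ids)
    return set(ids[keep])
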