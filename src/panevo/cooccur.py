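"""Co-occurrence analysis of taxon abundance tables: per-taxon
prevalence/abundance summaries, Spearman correlation of focal taxa against
all partners with Benjamini-Hochberg FDR control and a dual significance
threshold (p < 1e-5 AND FDR < 0.05), optionally stratified by a metadata
key such as geographic region.

Zeros are genuine observations (absence) and enter the ranks with average
tie handling; they are never treated as missing.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from panevo.io import AbundanceTable

logger = logging.getLogger("panevo")

__all__ = [
    "taxon_summaries",
    "spearman_network",
    "bh_adjust",
    "correlation_counts",
]

DUAL_P_THRESHOLD = 1e-5
DUAL_FDR_THRESHOLD = 0.05
EXACT_PERMUTATION_MAX_N = 11
MIN_STRATUM_SAMPLES = 20


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorts ascending, takes q_i = min_{j >= i} (m * p_j / j) clipped at 1,
    and restores the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def taxon_summaries(table: AbundanceTable,
                    group_by: Optional[str] = None) -> pd.DataFrame:
    """Mean abundance (zeros included), SD, and prevalence per taxon,
    overall (stratum "all") and per level of ``group_by`` when given."""
    if table.values.size == 0:
        raise ValueError("empty abundance table")
    frames = [("all", np.ones(len(table.sample_ids), dtype=bool))]
    if group_by is not None:
        if group_by not in table.metadata.columns:
            raise ValueError(f"unknown metadata key {group_by!r}")
        col = table.metadata[group_by].to_numpy()
        frames += [(str(level), col == level)
                   for level in pd.unique(col) if not pd.isna(level)]
    rows = []
    for stratum, mask in frames:
        vals = table.values[mask]
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros(
            vals.shape[1])
        prev = (vals > 0).mean(axis=0)
        for t, m_, s_, p_ in zip(table.taxon_ids, mean, sd, prev):
            rows.append((stratum, t, float(m_), float(s_), float(p_)))
    return pd.DataFrame(rows, columns=["stratum", "taxon_id",
                                       "mean_abundance", "sd_abundance",
                                       "prevalence"])


def _spearman_rho(x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    sx = x_ranks.std()
    sy = y_ranks.std()
    if sx == 0 or sy == 0:
        return math.nan
    return float(((x_ranks - x_ranks.mean())
                  * (y_ranks - y_ranks.mean())).mean() / (sx * sy))


def _spearman_p(rho: float, n: int, y: np.ndarray,
                x_ranks: np.ndarray) -> float:
    """Two-sided p for a Spearman rho: exact permutation for small n,
    otherwise the large-sample t approximation."""
    if math.isnan(rho):
        return math.nan
    if n < 12:
        y_ranks = stats.rankdata(y)
        count = total = 0
        for perm in itertools.permutations(y_ranks):
            r = _spearman_rho(x_ranks, np.array(perm))
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return count / total
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_network(table: AbundanceTable,
                     focal: Sequence[str],
                     min_prevalence: float = 0.05,
                     strata: Optional[str] = None) -> pd.DataFrame:
    """Spearman co-occurrence of each focal taxon against all partners.

    Partners below ``min_prevalence`` in a stratum are excluded there.
    The analysis runs on the pooled data (stratum "all") and, when
    ``strata`` names a metadata key, within each of its levels (levels
    with fewer than 20 samples are skipped with a warning).  BH adjustment
    is applied within each (focal, stratum) family; significance uses the
    dual threshold p < 1e-5 AND p_bh < 0.05.  Pooled-significant pairs are
    annotated with the strata in which they are independently significant.
    """
    for f in focal:
        if f not in table.taxon_ids:
            raise ValueError(f"focal taxon {f!r} not in table")
    groups: list[tuple[str, np.ndarray]] = [
        ("all", np.ones(len(table.sample_ids), dtype=bool))]
    if strata is not None:
        if strata not in table.metadata.columns:
            raise ValueError(f"unknown metadata key {strata!r}")
        col = table.metadata[strata].to_numpy()
        for level in pd.unique(col):
            if pd.isna(level):
                continue
            mask = col == level
            if mask.sum() < MIN_STRATUM_SAMPLES:
                logger.warning("stratum %r has %d samples (< %d); skipped",
                               level, int(mask.sum()), MIN_STRATUM_SAMPLES)
                continue
            groups.append((str(level), mask))

    taxa = np.array(table.taxon_ids)
    blocks = []
    for stratum, mask in groups:
        vals = table.values[mask]
        n = vals.shape[0]
        prev = (vals > 0).mean(axis=0)
        ranks = np.apply_along_axis(stats.rankdata, 0, vals)
        for f in focal:
            fi = int(np.flatnonzero(taxa == f)[0])
            x_ranks = ranks[:, fi]
            rows = []
            for j, partner in enumerate(taxa):
                if partner == f:
                    continue
                if prev[j] < min_prevalence:
                    continue
                rho = _spearman_rho(x_ranks, ranks[:, j])
                if math.isnan(rho):
                    continue
                p = _spearman_p(rho, n, vals[:, j], x_ranks)
                rows.append((f, partner, stratum, rho, p))
            if not rows:
                continue
            block = pd.DataFrame(rows, columns=["focal_taxon",
                                                "partner_taxon", "stratum",
                                                "rho", "p_value"])
            block["p_bh"] = bh_adjust(block["p_value"].to_numpy())
            blocks.append(block)
    if not blocks:
        return pd.DataFrame(columns=["focal_taxon", "partner_taxon",
                                     "stratum", "rho", "p_value", "p_bh",
                                     "significant", "sign",
                                     "significant_strata"])
    out = pd.concat(blocks, ignore_index=True)
    out["significant"] = ((out["p_value"] < DUAL_P_THRESHOLD)
                          & (out["p_bh"] < DUAL_FDR_THRESHOLD))
    out["sign"] = np.where(out["rho"] >= 0, "positive", "negative")

    # annotate pooled-significant pairs with their independently
    # significant strata
    sig_strata = (
        out[(out["stratum"] != "all") & out["significant"]]
        .groupby(["focal_taxon", "partner_taxon"])["stratum"]
        .apply(lambda s: ",".join(sorted(s)))
    )
    def _lookup(row):
        if row["stratum"] != "all" or not row["significant"]:
            return ""
        return sig_strata.get((row["focal_taxon"], row["partner_taxon"]), "")
    out["significant_strata"] = out.apply(_lookup, axis=1)
    return out


def correlation_counts(network: pd.DataFrame) -> pd.DataFrame:
    """Per (focal, stratum) tally of significant correlations: total,
    positive, and negative (total = positive + negative by
    construction)."""
    sig = network[network["significant"]]
    rows = []
    for (f, s), grp in sig.groupby(["focal_taxon", "stratum"]):
        pos = int((grp["sign"] == "positive").sum())
        neg = int((grp["sign"] == "negative").sum())
        rows.append((f, s, pos + neg, pos, neg))
    return pd.DataFrame(rows, columns=["focal_taxon", "stratum",
                                       "correlations", "positive",
                                       "negative"])
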