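"""Codon-usage screen for horizontally transferred genes.

Per-gene RSCU (relative synonymous codon usage), Wright's effective number
of codons (ENC), the codon adaptation index (CAI) against a highly
expressed reference set, and GC content; per-genome dynamic percentile
thresholds (nearest-rank 90th for GC / RSCU deviation / ENC, 10th for CAI);
conjunction of the four flags into high-confidence horizontally transferred
gene (hcHTG) calls; and mobile-element context annotation within a 2,000-nt
window of transposase-labelled genes.

The scalar "RSCU deviation" thresholded by the screen is the mean absolute
difference between a gene's RSCU vector and the genome-average RSCU
(computed from pooled codon counts), over codons whose synonymous family is
observed in the gene.  Stop codons and the single-codon families Met and
Trp are excluded from all RSCU-derived statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from panevo.io import GeneRecord
from panevo.simulate import AA_TO_CODONS, CODON_TO_AA, SENSE_CODONS

logger = logging.getLogger("panevo")

__all__ = [
    "CodonProfile",
    "GenomeThresholds",
    "HGTFlags",
    "codon_metrics",
    "call_hchtg",
    "mobile_context",
    "nearest_rank_percentile",
]

MIN_GENES_FOR_THRESHOLDS = 50
DEFAULT_REFERENCE_LABEL = "ribosomal protein"

# synonymous families eligible for RSCU/ENC (size >= 2)
_FAMILIES: dict[str, list[str]] = {
    aa: codons for aa, codons in AA_TO_CODONS.items() if len(codons) >= 2
}
_DEGENERATE_CODONS = sorted(c for fam in _FAMILIES.values() for c in fam)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_FAMILY_SIZES = sorted({len(v) for v in _FAMILIES.values()})  # 2, 3, 4, 6


@dataclass
class CodonProfile:
    """Per-gene codon-usage metrics."""

    gene_id: str
    codon_counts: np.ndarray  # aligned with SENSE_CODONS
    rscu: dict[str, float]
    rscu_deviation: float
    enc: float
    cai: float
    gc: float


@dataclass
class GenomeThresholds:
    """Per-genome dynamic percentile cutoffs for the four-factor screen."""

    genome_id: str
    gc_p90: float
    rscu_dev_p90: float
    enc_p90: float
    cai_p10: float
    n_genes_used: int


@dataclass
class HGTFlags:
    gene_id: str
    flag_gc: bool
    flag_rscu: bool
    flag_enc: bool
    flag_cai: bool
    is_hchtg: bool
    near_transposase: Optional[bool] = None


def nearest_rank_percentile(values: Sequence[float], p: float) -> float:
    """Nearest-rank percentile: the smallest value whose cumulative
    fraction is >= p."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("no values")
    rank = max(1, math.ceil(p * v.size))
    return float(v[rank - 1])


def _codon_counts(seq: str) -> tuple[Optional[np.ndarray], Optional[str]]:
    """Count sense codons of a CDS; the terminal stop codon (if any) is
    ignored.  Returns (counts, reason) where reason explains exclusion."""
    if len(seq) % 3 != 0:
        return None, "length not divisible by 3"
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons and CODON_TO_AA.get(codons[-1]) is None and codons[-1] in {
            "TAA", "TAG", "TGA"}:
        codons = codons[:-1]
    counts = np.zeros(len(SENSE_CODONS))
    for i, c in enumerate(codons):
        if c in _CODON_INDEX:
            counts[_CODON_INDEX[c]] += 1
        elif c in {"TAA", "TAG", "TGA"}:
            return None, f"internal stop codon at codon {i + 1}"
        # codons with ambiguous bases are skipped silently
    if counts.sum() == 0:
        return None, "no countable codons"
    return counts, None


def _rscu(counts: np.ndarray) -> dict[str, float]:
    """RSCU_c = x_c * n_family / sum over the family; NaN for unobserved
    families."""
    out: dict[str, float] = {}
    for aa, codons in _FAMILIES.items():
        idx = [_CODON_INDEX[c] for c in codons]
        tot = counts[idx].sum()
        for c, i in zip(codons, idx):
            out[c] = counts[i] * len(codons) / tot if tot > 0 else math.nan
    return out


def _enc(counts: np.ndarray) -> float:
    """Wright's effective number of codons.

    F = (n * sum(p^2) - 1) / (n - 1) per family with n >= 2 codons used;
    families with undefined or zero F are excluded from their size-class
    mean; a missing 3-fold mean is imputed as the average of the 2- and
    4-fold means; the result is capped to [20, 61].
    """
    f_by_size: dict[int, list[float]] = {m: [] for m in _FAMILY_SIZES}
    for aa, codons in _FAMILIES.items():
        idx = [_CODON_INDEX[c] for c in codons]
        n = counts[idx].sum()
        if n < 2:
            continue
        p = counts[idx] / n
        f = (n * (p**2).sum() - 1.0) / (n - 1.0)
        if f > 0:
            f_by_size[len(codons)].append(float(f))
    fbar = {m: (sum(v) / len(v) if v else math.nan)
            for m, v in f_by_size.items()}
    if math.isnan(fbar[3]):
        if math.isnan(fbar[2]) or math.isnan(fbar[4]):
            return math.nan
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if any(math.isnan(fbar[m]) for m in (2, 4, 6)):
        return math.nan
    enc = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    return float(min(max(enc, 20.0), 61.0))


def _reference_weights(ref_counts: np.ndarray) -> dict[str, float]:
    """Relative adaptiveness w_c = RSCU_ref,c / max over the family, from
    reference codon counts with a +0.5 pseudocount."""
    counts = ref_counts + 0.5
    rscu = _rscu(counts)
    weights: dict[str, float] = {}
    for aa, codons in _FAMILIES.items():
        mx = max(rscu[c] for c in codons)
        for c in codons:
            weights[c] = rscu[c] / mx
    return weights


def _cai(counts: np.ndarray, weights: dict[str, float]) -> float:
    """Geometric mean of relative adaptiveness over the gene's degenerate
    codons."""
    log_sum = 0.0
    n = 0.0
    for c in _DEGENERATE_CODONS:
        x = counts[_CODON_INDEX[c]]
        if x > 0:
            log_sum += x * math.log(weights[c])
            n += x
    if n == 0:
        return math.nan
    return float(math.exp(log_sum / n))


def _gc(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s) if s else math.nan


def codon_metrics(genes: Sequence[GeneRecord],
                  reference_gene_ids: Optional[Iterable[str]] = None,
                  genome_id: str = "genome"
                  ) -> tuple[list[CodonProfile], Optional[GenomeThresholds]]:
    """Compute per-gene codon-usage metrics and the genome's dynamic
    percentile thresholds.

    Genes whose CDS length is not divisible by 3 or that contain internal
    stop codons are excluded with a logged warning.  The CAI reference set
    defaults to genes whose product label contains "ribosomal protein";
    when fewer than 20 such genes exist, the 5% of genes with the lowest
    ENC are used instead.  Thresholds are returned only when at least 50
    genes are usable (otherwise None, with a warning).
    """
    if not genes:
        raise ValueError("empty gene set")
    usable: list[tuple[GeneRecord, np.ndarray]] = []
    for g in genes:
        counts, reason = _codon_counts(g.cds_sequence)
        if counts is None:
            logger.warning("gene %s excluded from codon analyses: %s",
                           g.gene_id, reason)
            continue
        usable.append((g, counts))
    if not usable:
        raise ValueError("no genes usable for codon analyses")

    pooled = np.sum([c for _, c in usable], axis=0)
    genome_rscu = _rscu(pooled)

    enc_by_gene = {g.gene_id: _enc(c) for g, c in usable}

    # resolve the CAI reference set
    if reference_gene_ids is not None:
        ref_ids = set(reference_gene_ids)
        if not ref_ids & {g.gene_id for g, _ in usable}:
            raise ValueError("none of the supplied reference_gene_ids are "
                             "usable genes")
    else:
        ref_ids = {g.gene_id for g, _ in usable
                   if any(DEFAULT_REFERENCE_LABEL in lbl.lower()
                          for lbl in g.product_labels)}
        if len(ref_ids) < 20:
            ranked = sorted((g.gene_id for g, _ in usable
                             if not math.isnan(enc_by_gene[g.gene_id])),
                            key=lambda gid: enc_by_gene[gid])
            n_ref = max(1, int(0.05 * len(ranked)))
            if not ranked:
                raise ValueError(
                    "no CAI reference genes: no 'ribosomal protein' "
                    "annotations and the lowest-ENC fallback found no genes "
                    "with a defined ENC")
            logger.info("CAI reference: %d 'ribosomal protein' genes found "
                        "(< 20); falling back to the %d lowest-ENC genes",
                        len(ref_ids), n_ref)
            ref_ids = set(ranked[:n_ref])
    ref_counts = np.sum([c for g, c in usable if g.gene_id in ref_ids],
                        axis=0)
    weights = _reference_weights(np.asarray(ref_counts, dtype=float))

    profiles: list[CodonProfile] = []
    for g, counts in usable:
        rscu = _rscu(counts)
        diffs = [abs(rscu[c] - genome_rscu[c]) for c in _DEGENERATE_CODONS
                 if not math.isnan(rscu[c]) and not math.isnan(genome_rscu[c])]
        dev = float(np.mean(diffs)) if diffs else math.nan
        profiles.append(CodonProfile(
            gene_id=g.gene_id, codon_counts=counts, rscu=rscu,
            rscu_deviation=dev, enc=enc_by_gene[g.gene_id],
            cai=_cai(counts, weights), gc=_gc(g.cds_sequence)))

    thresholds: Optional[GenomeThresholds] = None
    scored = [p for p in profiles
              if not any(math.isnan(v)
                         for v in (p.gc, p.rscu_deviation, p.enc, p.cai))]
    if len(scored) < MIN_GENES_FOR_THRESHOLDS:
        logger.warning("genome %s: only %d scorable genes (< %d); "
                       "percentile thresholds skipped", genome_id,
                       len(scored), MIN_GENES_FOR_THRESHOLDS)
    else:
        thresholds = GenomeThresholds(
            genome_id=genome_id,
            gc_p90=nearest_rank_percentile([p.gc for p in scored], 0.90),
            rscu_dev_p90=nearest_rank_percentile(
                [p.rscu_deviation for p in scored], 0.90),
            enc_p90=nearest_rank_percentile([p.enc for p in scored], 0.90),
            cai_p10=nearest_rank_percentile([p.cai for p in scored], 0.10),
            n_genes_used=len(scored),
        )
    return profiles, thresholds


def call_hchtg(profiles: Sequence[CodonProfile],
               thresholds: GenomeThresholds,
               mode: str = "raw_tail",
               genome_id: str = "genome") -> list[HGTFlags]:
    """Apply the four-factor screen.

    ``raw_tail`` (the default) flags genes above the genome's 90th
    percentile for GC, RSCU deviation, and ENC and below the 10th
    percentile for CAI; a gene with all four flags TRUE is an hcHTG.
    ``abs_deviation`` replaces raw GC with |gc - genome median gc| before
    the percentile, so low-GC outliers can be flagged too.
    """
    if mode not in {"raw_tail", "abs_deviation"}:
        raise ValueError(f"unknown mode {mode!r}")
    if thresholds is None:
        raise ValueError("no thresholds (genome below the minimum gene "
                         "count)")
    if thresholds.genome_id != genome_id:
        raise ValueError(
            f"profiles from genome {genome_id!r} but thresholds from "
            f"{thresholds.genome_id!r}: mixed-genome input")
    gcs = np.array([p.gc for p in profiles])
    if mode == "abs_deviation":
        med = float(np.median(gcs[~np.isnan(gcs)]))
        gc_vals = np.abs(gcs - med)
        gc_cut = nearest_rank_percentile(gc_vals[~np.isnan(gc_vals)], 0.90)
    else:
        gc_vals = gcs
        gc_cut = thresholds.gc_p90
    out: list[HGTFlags] = []
    for p, gv in zip(profiles, gc_vals):
        f_gc = bool(gv > gc_cut) if not math.isnan(gv) else False
        f_rscu = (bool(p.rscu_deviation > thresholds.rscu_dev_p90)
                  if not math.isnan(p.rscu_deviation) else False)
        f_enc = bool(p.enc > thresholds.enc_p90) if not math.isnan(p.enc) else False
        f_cai = bool(p.cai < thresholds.cai_p10) if not math.isnan(p.cai) else False
        out.append(HGTFlags(p.gene_id, f_gc, f_rscu, f_enc, f_cai,
                            f_gc and f_rscu and f_enc and f_cai))
    return out


def _boundary_gap(a: GeneRecord, b: GeneRecord) -> int:
    """Nucleotides strictly between the nearest boundaries of two features
    on the same contig; 0 when they overlap or abut."""
    if a.end < b.start:
        return b.start - a.end - 1
    if b.end < a.start:
        return a.start - b.end - 1
    return 0


def mobile_context(flags: Sequence[HGTFlags],
                   annotation: Sequence[GeneRecord],
                   window_nt: int = 2000,
                   markers: Iterable[str] = ("transposase",)
                   ) -> list[HGTFlags]:
    """Annotate each flagged gene with its mobile-element context.

    ``near_transposase`` becomes True iff a gene on the same contig whose
    product label contains one of the (case-insensitive) marker terms lies
    within ``window_nt`` nucleotides of the focal gene's nearest boundary
    (boundary-inclusive; overlap counts as gap 0).  Genes lacking
    coordinates keep ``near_transposase=None``.
    """
    markers = [m.lower() for m in markers]
    by_id = {g.gene_id: g for g in annotation}
    marker_genes: dict[str, list[GeneRecord]] = {}
    for g in annotation:
        if any(m in lbl.lower() for lbl in g.product_labels for m in markers):
            marker_genes.setdefault(g.contig_id, []).append(g)
    for fl in flags:
        focal = by_id.get(fl.gene_id)
        if focal is None:
            fl.near_transposase = None
            continue
        near = any(
            mg.gene_id != focal.gene_id
            and _boundary_gap(focal, mg) <= window_nt
            for mg in marker_genes.get(focal.contig_id, ())
        )
        fl.near_transposase = near
    return list(flags)
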