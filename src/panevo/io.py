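"""Readers and writers for the external formats the pipeline touches.

Pangenome gene presence/absence matrices (Roary ``gene_presence_absence.csv``
and ``.Rtab``), annotated CDS collections (GFF3 + FASTA), rooted Newick
trees, square identity/distance matrices (TSV), and sample-by-taxon relative
abundance tables with per-sample metadata.

Coordinates are 1-based inclusive throughout (the GFF3 convention); gaps
between features are counted on the nucleotides strictly between the nearest
feature boundaries.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("panevo")

__all__ = [
    "PresenceAbsenceMatrix",
    "GeneRecord",
    "SquareDistanceMatrix",
    "AbundanceTable",
    "parse_presence_absence",
    "write_presence_absence",
    "parse_genome_annotation",
    "parse_tree",
    "parse_square_matrix",
    "write_square_matrix",
    "parse_abundance_table",
    "write_report",
]

# Leading non-genome columns of Roary's gene_presence_absence.csv.
ROARY_FIXED_COLUMNS = 14

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class PresenceAbsenceMatrix:
    """Binary genomes x gene-cluster (COG) incidence table.

    ``values[i, j]`` is 1 when COG ``cog_ids[j]`` is present in genome
    ``genome_ids[i]``.  Identifiers are unique; every column has at least one
    presence (all-zero columns are dropped with a logged warning at
    construction).
    """

    genome_ids: list[str]
    cog_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.genome_ids), len(self.cog_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genome_ids)} genomes x {len(self.cog_ids)} COGs"
            )
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise ValueError(
                f"non-binary entry {self.values[tuple(bad)]!r} at genome "
                f"{self.genome_ids[bad[0]]!r}, COG {self.cog_ids[bad[1]]!r}"
            )
        self.values = self.values.astype(np.int8)
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("duplicate genome identifiers")
        if len(set(self.cog_ids)) != len(self.cog_ids):
            raise ValueError("duplicate COG identifiers")
        empty = self.values.sum(axis=0) == 0
        if empty.any():
            dropped = [c for c, e in zip(self.cog_ids, empty) if e]
            logger.warning(
                "dropping %d all-zero COG column(s): %s",
                len(dropped), ", ".join(dropped[:10]),
            )
            keep = ~empty
            self.cog_ids = [c for c, k in zip(self.cog_ids, keep) if k]
            self.values = self.values[:, keep]

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_cogs(self) -> int:
        return len(self.cog_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_ids,
                            columns=self.cog_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PresenceAbsenceMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())


@dataclass
class GeneRecord:
    """One annotated CDS: coordinates, strand, labels, and the coding
    sequence oriented so that codon 1 is the initiator."""

    contig_id: str
    gene_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    product_labels: list[str] = field(default_factory=list)
    cds_sequence: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SquareDistanceMatrix:
    """Symmetric pairwise distance matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix is not square over its labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix asymmetric beyond 1e-9")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")
        self.values = np.clip(self.values, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances in percent, plus per-sample
    metadata (at least a ``region`` column, optionally ``age_class``)."""

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError("abundance table shape mismatch")
        if (self.values < 0).any():
            raise ValueError("negative abundances")
        if (self.values.sum(axis=1) > 100 + 1e-6).any():
            raise ValueError("per-sample abundance sums exceed 100%")
        self.metadata = self.metadata.reindex(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.taxon_ids)


# ---------------------------------------------------------------------------
# Presence/absence parsing
# ---------------------------------------------------------------------------

def parse_presence_absence(path: str | Path,
                           dialect: str = "rtab") -> PresenceAbsenceMatrix:
    """Read a gene presence/absence matrix.

    ``dialect="rtab"`` expects Roary's tab-separated ``.Rtab`` (rows = gene
    clusters, columns = genomes, entries 0/1).  ``dialect="roary_csv"``
    expects ``gene_presence_absence.csv`` where any non-empty locus-tag cell
    (including multi-locus paralog cells) counts as presence.
    """
    path = Path(path)
    if dialect == "rtab":
        return _parse_rtab(path)
    if dialect == "roary_csv":
        return _parse_roary_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_rtab(path: Path) -> PresenceAbsenceMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if not header or len(header) < 2:
            raise ValueError(f"{path}: Rtab header missing genome columns")
        genomes = header[1:]
        if len(set(genomes)) != len(genomes):
            dup = sorted({g for g in genomes if genomes.count(g) > 1})
            raise ValueError(f"{path}: duplicate genome column(s) {dup}")
        cogs: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: {len(row)} fields, "
                    f"expected {len(header)}"
                )
            cogs.append(row[0])
            parsed = []
            for col, cell in zip(genomes, row[1:]):
                if cell not in {"0", "1"}:
                    raise ValueError(
                        f"{path}: line {lineno}, genome {col!r}: "
                        f"entry {cell!r} is not 0/1"
                    )
                parsed.append(int(cell))
            rows.append(parsed)
    values = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(genomes), 0), np.int8)
    return PresenceAbsenceMatrix(genomes, cogs, values)


def _parse_roary_csv(path: Path) -> PresenceAbsenceMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or len(header) <= ROARY_FIXED_COLUMNS:
            raise ValueError(
                f"{path}: Roary CSV header has no genome columns after the "
                f"{ROARY_FIXED_COLUMNS} fixed leading columns"
            )
        genomes = header[ROARY_FIXED_COLUMNS:]
        if len(set(genomes)) != len(genomes):
            dup = sorted({g for g in genomes if genomes.count(g) > 1})
            raise ValueError(f"{path}: duplicate genome column(s) {dup}")
        cogs: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: {len(row)} fields, "
                    f"expected {len(header)}"
                )
            cogs.append(row[0])
            rows.append([1 if cell.strip() else 0
                         for cell in row[ROARY_FIXED_COLUMNS:]])
    values = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(genomes), 0), np.int8)
    return PresenceAbsenceMatrix(genomes, cogs, values)


def write_presence_absence(matrix: PresenceAbsenceMatrix,
                           path: str | Path) -> None:
    """Write a matrix in Rtab layout (genes as rows, genomes as columns)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["Gene", *matrix.genome_ids])
        for j, cog in enumerate(matrix.cog_ids):
            writer.writerow([cog, *matrix.values[:, j].tolist()])


# ---------------------------------------------------------------------------
# GFF3 + FASTA
# ---------------------------------------------------------------------------

def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def parse_genome_annotation(gff_path: str | Path,
                            fasta_path: str | Path) -> list[GeneRecord]:
    """Read CDS features from a GFF3 file and extract their coding
    sequences from the companion FASTA.

    Minus-strand CDS are returned reverse-complemented so codon 1 is the
    initiator.  CDS whose length is not divisible by 3 are kept (they still
    carry coordinates) but flagged in the log; downstream codon analyses
    exclude them.
    """
    import gffutils

    gff_path, fasta_path = Path(gff_path), Path(fasta_path)
    contigs = _read_fasta(fasta_path)
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes: list[GeneRecord] = []
    for i, feat in enumerate(db.features_of_type("CDS"), start=1):
        if feat.seqid not in contigs:
            raise ValueError(
                f"{gff_path}: CDS on missing contig {feat.seqid!r}")
        contig = contigs[feat.seqid]
        if feat.start < 1 or feat.end > len(contig):
            raise ValueError(
                f"{gff_path}: coordinates {feat.start}..{feat.end} out of "
                f"range for contig {feat.seqid!r} (length {len(contig)})")
        gene_id = (feat.attributes.get("ID", [None])[0]
                   or feat.attributes.get("locus_tag", [None])[0]
                   or f"cds_{i}")
        products = [p.strip()
                    for p in ",".join(feat.attributes.get("product",
                                                          [])).split(",")
                    if p.strip()]
        seq = contig[feat.start - 1:feat.end]
        if feat.strand == "-":
            seq = _revcomp(seq)
        if len(seq) % 3 != 0:
            logger.warning(
                "gene %s: CDS length %d not divisible by 3; excluded from "
                "codon analyses", gene_id, len(seq))
        genes.append(GeneRecord(feat.seqid, gene_id, feat.start, feat.end,
                                feat.strand, products, seq))
    return genes


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def parse_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; tips must be uniquely labelled.

    Missing branch lengths default to 1 (logged).
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises its own hierarchy
        if "Duplicate taxon" in str(exc):
            raise ValueError(f"{path}: duplicate tip label(s)") from exc
        raise ValueError(f"{path}: malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"{path}: duplicate tip label(s) {dup}")
    defaulted = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 1.0
            defaulted += 1
    if defaulted:
        logger.info("%s: %d branch length(s) missing, defaulted to 1",
                    path, defaulted)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Square matrices, abundance tables, reports
# ---------------------------------------------------------------------------

def parse_square_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a square TSV matrix with a label header row and column.

    Returns raw labels and values without distance validation (identity
    matrices pass through here too).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in frame.index]
    if labels != [str(x) for x in frame.columns]:
        raise ValueError(f"{path}: row and column labels differ")
    return labels, frame.to_numpy(dtype=float)


def write_square_matrix(labels: Sequence[str], values: np.ndarray,
                        path: str | Path) -> None:
    pd.DataFrame(values, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", index_label="")


def parse_abundance_table(table_path: str | Path,
                          metadata_path: str | Path) -> AbundanceTable:
    """Read a samples x taxa percent-abundance TSV plus a metadata TSV with
    a ``sample`` index column and at least a ``region`` column."""
    frame = pd.read_csv(table_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    missing = set(frame.index) - set(meta.index)
    if missing:
        raise ValueError(
            f"{metadata_path}: metadata missing for sample(s) "
            f"{sorted(missing)[:5]}"
        )
    return AbundanceTable([str(s) for s in frame.index],
                          [str(t) for t in frame.columns],
                          frame.to_numpy(dtype=float),
                          meta.loc[frame.index])


def write_report(frame: pd.DataFrame, path: str | Path,
                 params: Mapping[str, object] | None = None,
                 index: bool = False) -> None:
    """Write a TSV report preceded by a '#' header recording the tool
    version, seed, and parameters used."""
    from panevo import __version__

    items = dict(params or {})
    header = " ".join(f"{k}={v}" for k, v in items.items())
    with open(path, "w") as fh:
        fh.write(f"# panevo {__version__} {header}\n".rstrip() + "\n")
        frame.to_csv(fh, sep="\t", index=index)
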