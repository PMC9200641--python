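"""Readers and writers for the external formats the pipeline touches.

Conventions are fixed package-wide: coordinates are 0-based half-open
internally (the only 1-based surface is VCF, converted on read/write); gap
``-`` and ``N`` both count as missing for statistics but are preserved
distinctly on round-trip; alignments are assumed reference-oriented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: DNA alphabet used everywhere; anything else is mapped to N on read.
DNA_CHARS = frozenset("ACGT-")

# Integer encoding used by the numeric kernels: A,C,G,T -> 0..3, missing -> 255.
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
MISSING = np.uint8(255)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Region:
    """Half-open reference interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class MultiAlignment:
    """A multi-sequence DNA alignment, optionally anchored to reference coordinates.

    Rows are equal-length strings over ``{A,C,G,T,N,-}``; ``region`` gives the
    0-based half-open reference interval the columns project onto (one column
    per reference base for stitched, reference-projected blocks).
    """

    taxon_labels: list[str]
    rows: list[str]
    ref_taxon: Optional[str] = None
    region: Optional[Region] = None

    def __post_init__(self) -> None:
        if len(self.taxon_labels) != len(self.rows):
            raise FormatError("label/row count mismatch")
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            dupes = {t for t in self.taxon_labels if self.taxon_labels.count(t) > 1}
            raise FormatError(f"duplicate taxon labels: {sorted(dupes)}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        """Encode as a (taxa x columns) uint8 matrix; A,C,G,T -> 0..3, N/- -> 255."""
        if not self.rows:
            return np.empty((0, 0), dtype=np.uint8)
        raw = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        return _ENCODE[raw].reshape(self.n_taxa, self.n_columns)

    @classmethod
    def from_array(
        cls,
        labels: Sequence[str],
        arr: np.ndarray,
        ref_taxon: Optional[str] = None,
        region: Optional[Region] = None,
    ) -> "MultiAlignment":
        """Decode a uint8 matrix (0..3 bases, 255 missing) back into string rows."""
        out = np.full(arr.shape, ord("N"), dtype=np.uint8)
        valid = arr < 4
        out[valid] = _DECODE[arr[valid]]
        rows = [bytes(r).decode("ascii") for r in out]
        return cls(list(labels), rows, ref_taxon=ref_taxon, region=region)

    def subset_columns(self, start: int, stop: int) -> "MultiAlignment":
        """Column slice [start, stop); the region, when present, shifts with it."""
        region = None
        if self.region is not None:
            region = Region(self.region.chrom, self.region.start + start, self.region.start + stop)
        return MultiAlignment(
            list(self.taxon_labels),
            [r[start:stop] for r in self.rows],
            ref_taxon=self.ref_taxon,
            region=region,
        )


@dataclass(frozen=True)
class SnpSite:
    """One biallelic site; ``freqs`` holds per-taxon derived(ALT)-allele frequency
    in [0, 1] or None for missing."""

    chrom: str
    pos: int  # 0-based internally
    ref: str
    alt: str
    freqs: dict[str, Optional[float]]


@dataclass
class SnpTable:
    """Biallelic SNP table with per-taxon allele frequencies.

    Positions are 0-based internally and strictly increasing within each
    chromosome; ``n_skipped_multiallelic`` records how many VCF records were
    dropped for having more than one ALT allele.
    """

    taxa: list[str]
    sites: list[SnpSite]
    n_skipped_multiallelic: int = 0

    def __post_init__(self) -> None:
        last: dict[str, int] = {}
        for s in self.sites:
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise FormatError(f"positions not strictly increasing on {s.chrom} at {s.pos}")
            last[s.chrom] = s.pos


@dataclass
class PresenceAbsenceMatrix:
    """Binary cluster x accession occurrence matrix for pan-genome analyses."""

    cluster_ids: list[str]
    accession_ids: list[str]
    values: np.ndarray  # (clusters, accessions) uint8 in {0,1}
    n_dropped_empty: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.cluster_ids), len(self.accession_ids)):
            raise FormatError("matrix shape does not match ids")
        if not np.isin(self.values, (0, 1)).all():
            raise FormatError("matrix cells must be 0/1")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def occupancy(self) -> np.ndarray:
        """Per-cluster number of accessions carrying the cluster."""
        return self.values.sum(axis=1).astype(int)


# ---------------------------------------------------------------------------
# FASTA alignments


def read_alignment(
    path,
    ref_taxon: Optional[str] = None,
    region: Optional[Region] = None,
) -> MultiAlignment:
    """Read a multi-FASTA alignment.

    Rows are upper-cased; characters outside ``{A,C,G,T,-}`` become ``N``.
    Unequal row lengths or duplicate labels raise :class:`FormatError`.
    """
    labels, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        seq = "".join(c if c in DNA_CHARS else "N" for c in seq)
        labels.append(rec.id)
        rows.append(seq)
    if not labels:
        raise FormatError(f"no FASTA records in {path}")
    return MultiAlignment(labels, rows, ref_taxon=ref_taxon, region=region)


def write_alignment(aln: MultiAlignment, path) -> None:
    with open(path, "w") as fh:
        for label, row in zip(aln.taxon_labels, aln.rows):
            fh.write(f">{label}\n{row}\n")


# ---------------------------------------------------------------------------
# VCF


def read_snp_table(path) -> SnpTable:
    """Read biallelic SNPs with GT fields from a VCF (plain text or bgzipped).

    Multiallelic records are skipped and counted. Diploid genotypes collapse to
    derived-allele frequencies per taxon (0, 0.5, 1); missing calls stay None.
    VCF's 1-based POS becomes 0-based internally.
    """
    import pysam

    sites: list[SnpSite] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        taxa = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_skipped += 1
                continue
            freqs: dict[str, Optional[float]] = {}
            for name in taxa:
                gt = rec.samples[name].get("GT")
                if gt is None or any(a is None for a in gt):
                    freqs[name] = None
                else:
                    freqs[name] = float(sum(gt)) / len(gt)
            sites.append(SnpSite(rec.chrom, rec.pos - 1, rec.ref, alts[0], freqs))
    if n_skipped:
        logger.info("read_snp_table: skipped %d multiallelic records", n_skipped)
    return SnpTable(taxa, sites, n_skipped_multiallelic=n_skipped)


# ---------------------------------------------------------------------------
# Trees (newick via dendropy)


def read_tree(path) -> dendropy.Tree:
    """Read a single newick tree; internal node labels are treated as support."""
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse newick in {path}: {exc}") from exc


def read_trees(path) -> list[dendropy.Tree]:
    """Read a newick list file (one tree per line), sharing one taxon namespace."""
    try:
        tl = dendropy.TreeList.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise FormatError(f"cannot parse newick in {path}: {exc}") from exc
    return list(tl)


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


def write_trees(trees: Sequence[dendropy.Tree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(tree_to_newick(t) + "\n")


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths to 10 significant digits."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip()


def parse_tree(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise FormatError(f"cannot parse newick string: {exc}") from exc


# ---------------------------------------------------------------------------
# Presence/absence matrix (TSV)


def read_matrix(path, drop_empty: bool = True) -> PresenceAbsenceMatrix:
    """Read a cluster x accession TSV; counts > 0 collapse to presence 1.

    Header row carries accession names, first column cluster IDs. All-zero
    clusters are dropped (with a logged count) because occupancy 0 has no
    pan-genome category.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot read matrix {path}: {exc}") from exc
    try:
        numeric = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    if numeric.isna().any().any():
        raise FormatError(f"missing/ragged cells in {path}")
    values = (numeric.to_numpy() > 0).astype(np.uint8)
    cluster_ids = [str(c) for c in df.index]
    accession_ids = [str(a) for a in df.columns]
    n_dropped = 0
    if drop_empty:
        keep = values.sum(axis=1) > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("read_matrix: dropped %d all-zero clusters", n_dropped)
        values = values[keep]
        cluster_ids = [c for c, k in zip(cluster_ids, keep) if k]
    logger.info("read_matrix: %d clusters x %d accessions", len(cluster_ids), len(accession_ids))
    return PresenceAbsenceMatrix(cluster_ids, accession_ids, values, n_dropped_empty=n_dropped)


def write_matrix(mat: PresenceAbsenceMatrix, path) -> None:
    pd.DataFrame(
        mat.values, index=mat.cluster_ids, columns=mat.accession_ids
    ).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[Region]:
    """Read a 3+ column BED file into half-open :class:`Region` records."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 BED columns")
            try:
                regions.append(Region(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return regions


def write_bed(regions: Sequence[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
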