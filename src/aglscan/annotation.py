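"""Nearest-gene annotation of significant SNPs.

A SNP inside a gene is reported as "in" that gene; otherwise the nearest
gene boundary within a window (default 1 Mb) decides the candidate, and the
SNP is labelled upstream/downstream of it.  With a known strand, upstream
means the gene's 5' side; with unknown strand (or in genomic mode), the
genomic-left side counts as upstream.  Rendered as e.g. ``SHBG (9664 bp u)``.

Coordinates are 1-based inclusive (GFF3 convention); BED input is converted
from its 0-based half-open intervals on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "GeneFeature",
    "SnpAnnotation",
    "annotate_snp",
    "annotate_table",
    "format_annotation",
    "read_gff3",
    "read_bed",
]

Relation = Literal["in", "upstream", "downstream", "none"]


@dataclass(frozen=True)
class GeneFeature:
    """One gene interval, 1-based inclusive, strand '+'/'-'/'unknown'."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"gene {self.name}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SnpAnnotation:
    snp_id: str
    gene_name: str  # "" when no gene within the window
    relation: Relation
    distance_bp: int

    def __post_init__(self) -> None:
        if self.relation == "in" and self.distance_bp != 0:
            raise ValueError("relation 'in' requires distance 0")
        if self.distance_bp < 0:
            raise ValueError("distance must be non-negative")


def format_annotation(ann: SnpAnnotation) -> str:
    """Render in the table style: gene name, ``GENE (9664 bp u)``, or ''."""
    if ann.relation == "none":
        return ""
    if ann.relation == "in":
        return ann.gene_name
    side = "u" if ann.relation == "upstream" else "d"
    return f"{ann.gene_name} ({ann.distance_bp} bp {side})"


def _relation_for(gene: GeneFeature, pos: int, strand_aware: bool) -> tuple[Relation, int]:
    if gene.start <= pos <= gene.end:
        return "in", 0
    if pos < gene.start:
        dist, left = gene.start - pos, True
    else:
        dist, left = pos - gene.end, False
    if strand_aware and gene.strand == "-":
        return ("downstream" if left else "upstream"), dist
    return ("upstream" if left else "downstream"), dist


def annotate_snp(
    snp_id: str,
    chrom: str,
    pos: int,
    genes: Iterable[GeneFeature],
    max_dist: int = 1_000_000,
    strand_aware: bool = True,
) -> SnpAnnotation:
    """Annotate one SNP against a gene set.

    Genes on the SNP's chromosome are scanned for containment first, then
    for the smallest boundary distance within ``max_dist``; ties go to the
    first gene in input order.  A chromosome absent from the gene set
    produces relation ``none`` with a warning.
    """
    chrom = str(chrom)
    on_chrom = [g for g in genes if g.chrom == chrom]
    if not on_chrom:
        warnings.warn(
            f"SNP {snp_id}: no genes on chromosome {chrom!r}", stacklevel=2
        )
        return SnpAnnotation(snp_id, "", "none", 0)
    best: Optional[tuple[int, Relation, GeneFeature]] = None
    for g in on_chrom:
        rel, dist = _relation_for(g, int(pos), strand_aware)
        if rel == "in":
            return SnpAnnotation(snp_id, g.name, "in", 0)
        if dist <= max_dist and (best is None or dist < best[0]):
            best = (dist, rel, g)
    if best is None:
        return SnpAnnotation(snp_id, "", "none", 0)
    dist, rel, g = best
    return SnpAnnotation(snp_id, g.name, rel, dist)


def annotate_table(
    snps: pd.DataFrame,
    genes: Sequence[GeneFeature],
    max_dist: int = 1_000_000,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Annotate a table with columns snp, chr, pos; returns a copy with
    candidate_gene, relation, distance_bp and a rendered label column."""
    out = snps.copy()
    anns = [
        annotate_snp(str(r.snp), str(r.chr), int(r.pos), genes, max_dist, strand_aware)
        for r in snps.itertuples()
    ]
    out["candidate_gene"] = [a.gene_name for a in anns]
    out["relation"] = [a.relation for a in anns]
    out["distance_bp"] = [a.distance_bp for a in anns]
    out["candidate_gene_label"] = [format_annotation(a) for a in anns]
    return out


def _gff3_attr(attrs: str, keys: tuple[str, ...]) -> Optional[str]:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for key in keys:
        if key in fields:
            value = fields[key]
            return value.split(":", 1)[1] if value.startswith("gene:") else value
    return None


def read_gff3(
    path: Union[str, Path], feature_types: tuple[str, ...] = ("gene",)
) -> list[GeneFeature]:
    """Read gene features from a GFF3 file (gene-level records only).

    The gene name comes from the Name attribute, falling back to ID, then
    gene_id.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            if ftype not in feature_types:
                continue
            name = _gff3_attr(attrs, ("Name", "ID", "gene_id")) or f"gene_{lineno}"
            genes.append(
                GeneFeature(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in ("+", "-") else "unknown",
                    name=name,
                )
            )
    return genes


def read_bed(path: Union[str, Path]) -> list[GeneFeature]:
    """Read 4+-column BED (chrom, start, end, name[, score, strand]);
    0-based half-open intervals become 1-based inclusive."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "unknown"
            genes.append(
                GeneFeature(
                    chrom=parts[0],
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                    strand=strand,
                    name=parts[3],
                )
            )
    return genes
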