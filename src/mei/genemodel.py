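"""Gene models and count-matrix I/O.

A gene is represented by the union of its exons across all annotated
transcripts; introns are the complementary gaps inside the gene span, so a
position is "intronic" only if no transcript places an exon there.  All
internal coordinates are 0-based half-open; GTF (1-based, closed) is
converted at the parser boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "MatchedCounts",
    "GtfParseError",
    "merge_intervals",
    "gene_model_from_exons",
    "parse_gtf",
    "read_count_matrix",
    "write_count_matrix",
    "align_matrices",
]


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end} (start must be < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Exon-union / intron partition of a gene.

    ``exons`` are merged, sorted and pairwise disjoint; ``introns`` are the
    gaps between consecutive merged exons.  Together they tile ``span``
    exactly.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    introns: tuple[GenomicInterval, ...] = field(default=())

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and non-overlapping.

    Touching intervals ([a,b) and [b,c)) are merged into one.
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def gene_model_from_exons(
    gene_id: str,
    chrom: str,
    strand: str,
    exons: Iterable[tuple[int, int]],
) -> GeneModel:
    """Build a :class:`GeneModel` from raw (possibly overlapping) exon intervals."""
    merged = merge_intervals(exons)
    if not merged:
        raise ValueError(f"gene {gene_id}: no exons")
    exon_ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in merged)
    intron_ivs = tuple(
        GenomicInterval(chrom, merged[i][1], merged[i + 1][0], strand)
        for i in range(len(merged) - 1)
    )
    return GeneModel(gene_id, chrom, strand, exon_ivs, intron_ivs)


def _parse_gtf_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, value = parts
        out[key] = value.strip().strip('"')
    return out


def parse_gtf(path: str | Path, feature_filter: str = "exon") -> list[GeneModel]:
    """Parse a GTF file into per-gene exon-union models.

    Only features equal to ``feature_filter`` are used.  GTF coordinates
    (1-based, closed) are converted to 0-based half-open.  Genes whose
    exons span multiple chromosomes or strands are excluded with a warning
    rather than repaired.
    """
    per_gene: dict[str, list[tuple[str, str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != feature_filter:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            attr_map = _parse_gtf_attributes(attrs, lineno)
            if "gene_id" not in attr_map:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            # GTF is 1-based closed; internal convention is 0-based half-open.
            per_gene.setdefault(attr_map["gene_id"], []).append(
                (chrom, strand, start_i - 1, end_i)
            )

    models: list[GeneModel] = []
    for gene_id, rows in per_gene.items():
        chroms = {r[0] for r in rows}
        strands = {r[1] for r in rows}
        if len(chroms) > 1 or len(strands) > 1:
            warnings.warn(
                f"gene {gene_id} has exons on multiple chromosomes/strands; excluded",
                stacklevel=2,
            )
            continue
        models.append(
            gene_model_from_exons(
                gene_id, rows[0][0], rows[0][1], [(s, e) for _, _, s, e in rows]
            )
        )
    return models


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

REGION_TYPES = ("exon", "intron")


def read_count_matrix(path: str | Path, region_type: str) -> pd.DataFrame:
    """Read a genes x samples TSV count matrix.

    First column is ``gene_id``; remaining columns are samples.  Raw
    matrices must be integer-valued and non-negative; duplicate gene or
    sample labels are rejected.  The region type ("exon" or "intron") is
    recorded in ``df.attrs``.
    """
    if region_type not in REGION_TYPES:
        raise ValueError(f"region_type must be one of {REGION_TYPES}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene ids: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample ids: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if (numeric.values < 0).any():
        r, c = np.argwhere(numeric.values < 0)[0]
        raise ValueError(
            f"negative count at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    numeric.attrs["region_type"] = region_type
    numeric.attrs["calibrated"] = False
    numeric.index.name = "gene_id"
    return numeric


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


@dataclass
class MatchedCounts:
    """Paired exon and intron count matrices over identical gene and sample axes."""

    exon: pd.DataFrame
    intron: pd.DataFrame
    calibrated: bool = False

    def __post_init__(self) -> None:
        if not self.exon.index.equals(self.intron.index):
            raise ValueError("exon and intron matrices have different gene indices")
        if not self.exon.columns.equals(self.intron.columns):
            raise ValueError("exon and intron matrices have different sample columns")

    @property
    def genes(self) -> pd.Index:
        return self.exon.index

    @property
    def samples(self) -> pd.Index:
        return self.exon.columns

    def subset_samples(self, samples: Sequence[str]) -> "MatchedCounts":
        return replace(
            self, exon=self.exon[list(samples)], intron=self.intron[list(samples)]
        )

    def subset_genes(self, genes: Sequence[str]) -> "MatchedCounts":
        return replace(
            self, exon=self.exon.loc[list(genes)], intron=self.intron.loc[list(genes)]
        )


def align_matrices(
    exon: pd.DataFrame, intron: pd.DataFrame
) -> tuple[MatchedCounts, list[str]]:
    """Restrict two count matrices to their shared genes and samples.

    Returns the matched counts and the list of genes dropped from either
    matrix.  Ordering follows the exon matrix.
    """
    shared_genes = exon.index.intersection(intron.index)
    shared_samples = exon.columns.intersection(intron.columns)
    if len(shared_genes) == 0:
        raise ValueError("no genes shared between exon and intron matrices")
    if len(shared_samples) == 0:
        raise ValueError("no samples shared between exon and intron matrices")
    dropped = sorted(
        set(exon.index).symmetric_difference(intron.index)
    )
    mc = MatchedCounts(
        exon=exon.loc[shared_genes, shared_samples],
        intron=intron.loc[shared_genes, shared_samples],
        calibrated=bool(exon.attrs.get("calibrated", False)),
    )
    return mc, dropped
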