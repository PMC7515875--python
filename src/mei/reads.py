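"""Singular exon/intron counting from read alignments.

"Singular" counts keep the count model-free: a read contributes only when
it maps with high confidence (MAPQ >= 40) and overlaps exactly one gene,
and a gene's counts are kept only when lower-quality alternatives stay at
or below 1% of its total — otherwise the gene is dropped rather than its
reads redistributed.  Reads touching both exonic and intronic bases are
exonic (junction reads evidence the exon); strand is ignored (unstranded
libraries); paired mates, if present, count as independent placements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .genemodel import GeneModel, GenomicInterval, MatchedCounts

__all__ = [
    "ReadPlacement",
    "GeneCountAudit",
    "SampleCounts",
    "classify_read",
    "count_sample",
    "build_matrices",
    "read_sam",
    "read_tsv_alignments",
    "write_sam",
]

DEFAULT_MAPQ_MIN = 40
DEFAULT_ALT_FRAC_MAX = 0.01


@dataclass(frozen=True)
class ReadPlacement:
    """A gapped single-end alignment: sorted non-overlapping blocks on one chromosome."""

    read_id: str
    chrom: str
    blocks: tuple[GenomicInterval, ...]
    mapq: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("read with no aligned blocks")
        prev_end = -1
        for b in self.blocks:
            if b.chrom != self.chrom:
                raise ValueError("all blocks must share the read's chromosome")
            if b.start < prev_end:
                raise ValueError("blocks must be sorted and non-overlapping")
            prev_end = b.end


@dataclass
class GeneCountAudit:
    """Per-gene quality audit backing the singular-count decision."""

    gene_id: str
    high_q_exon: int = 0
    high_q_intron: int = 0
    low_q_total: int = 0
    singular: bool = False

    @property
    def total(self) -> int:
        return self.high_q_exon + self.high_q_intron + self.low_q_total

    def finalize(self, alt_frac_max: float) -> None:
        high_q = self.high_q_exon + self.high_q_intron
        self.singular = high_q > 0 and self.low_q_total <= alt_frac_max * self.total


@dataclass
class SampleCounts:
    sample_id: str
    exon: dict[str, int]
    intron: dict[str, int]
    audits: list[GeneCountAudit]
    unassigned: int = 0
    processed: int = 0
    dropped_duplicated: list[str] = field(default_factory=list)


def classify_read(read: ReadPlacement, model: GeneModel) -> str:
    """Assign a read to {exonic, intronic, outside} relative to one gene.

    Exonic if any block overlaps any exonic base (exon priority: boundary
    and junction reads are exonic); intronic if every block lies within
    the gene span yet none touches an exon; outside otherwise.
    """
    if read.chrom != model.chrom:
        return "outside"
    span = model.span
    for block in read.blocks:
        for exon in model.exons:
            if block.start < exon.end and exon.start < block.end:
                return "exonic"
    for block in read.blocks:
        if block.start < span.start or block.end > span.end:
            return "outside"
    return "intronic"


def _index_models(models: list[GeneModel]) -> dict[str, IntervalTree]:
    by_chrom: dict[str, IntervalTree] = {}
    for i, m in enumerate(models):
        span = m.span
        by_chrom.setdefault(m.chrom, IntervalTree()).addi(span.start, span.end, i)
    return by_chrom


def count_sample(
    reads: Iterable[ReadPlacement],
    models: list[GeneModel],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    alt_frac_max: float = DEFAULT_ALT_FRAC_MAX,
    sample_id: str = "",
) -> SampleCounts:
    """Accumulate singular exon/intron counts for one sample.

    Each read lands on exactly one gene or none: reads overlapping two or
    more genes are discarded (tallied as unassigned), as are reads on
    unknown chromosomes or outside every gene.  Reads with
    mapq >= ``mapq_min`` increment exon or intron counts; lower-quality
    reads hitting a gene increment its ``low_q_total``.  Genes whose
    low-quality fraction exceeds ``alt_frac_max`` fail the singular audit.

    Duplicated gene ids (same id annotated at several loci) are audited
    per locus; the gene is kept only when exactly one locus is singular.
    """
    trees = _index_models(models)
    audits = [GeneCountAudit(m.gene_id) for m in models]
    unassigned = 0
    processed = 0
    for read in reads:
        processed += 1
        tree = trees.get(read.chrom)
        if tree is None:
            unassigned += 1
            continue
        hits: list[tuple[int, str]] = []
        seen: set[int] = set()
        for block in read.blocks:
            for iv in tree.overlap(block.start, block.end):
                if iv.data in seen:
                    continue
                seen.add(iv.data)
                cls = classify_read(read, models[iv.data])
                if cls != "outside":
                    hits.append((iv.data, cls))
        if len(hits) != 1:  # ambiguous (>=2 genes) or no gene
            unassigned += 1
            continue
        idx, cls = hits[0]
        audit = audits[idx]
        if read.mapq >= mapq_min:
            if cls == "exonic":
                audit.high_q_exon += 1
            else:
                audit.high_q_intron += 1
        else:
            audit.low_q_total += 1

    for audit in audits:
        audit.finalize(alt_frac_max)

    # resolve duplicated gene ids: keep iff exactly one locus is singular
    by_gene: dict[str, list[GeneCountAudit]] = {}
    for a in audits:
        by_gene.setdefault(a.gene_id, []).append(a)
    exon: dict[str, int] = {}
    intron: dict[str, int] = {}
    dropped_dup: list[str] = []
    for gene_id, gene_audits in by_gene.items():
        singular = [a for a in gene_audits if a.singular]
        if len(gene_audits) > 1 and len(singular) != 1:
            dropped_dup.append(gene_id)
            for a in gene_audits:
                a.singular = False
            continue
        if len(singular) == 1:
            exon[gene_id] = singular[0].high_q_exon
            intron[gene_id] = singular[0].high_q_intron
    return SampleCounts(
        sample_id=sample_id,
        exon=exon,
        intron=intron,
        audits=audits,
        unassigned=unassigned,
        processed=processed,
        dropped_duplicated=sorted(dropped_dup),
    )


def build_matrices(per_sample: dict[str, SampleCounts]) -> MatchedCounts:
    """Assemble matched matrices over genes singular in *every* sample."""
    if len(per_sample) < 2:
        raise ValueError("need at least 2 samples to build matrices")
    singular_sets = []
    for sc in per_sample.values():
        singular_sets.append({a.gene_id for a in sc.audits if a.singular})
    shared = set.intersection(*singular_sets)
    if not shared:
        raise ValueError(
            "no gene is singular in every sample; consider relaxing mapq_min "
            "or alt_frac_max"
        )
    genes = sorted(shared)
    samples = list(per_sample)
    exon = pd.DataFrame(
        {s: [per_sample[s].exon[g] for g in genes] for s in samples}, index=genes
    )
    intron = pd.DataFrame(
        {s: [per_sample[s].intron[g] for g in genes] for s in samples}, index=genes
    )
    exon.index.name = intron.index.name = "gene_id"
    exon.attrs["region_type"] = "exon"
    intron.attrs["region_type"] = "intron"
    return MatchedCounts(exon=exon, intron=intron, calibrated=False)


# ---------------------------------------------------------------------------
# Alignment readers / writer
# ---------------------------------------------------------------------------

_REF_CONSUMING = {0, 7, 8, 2}  # M, =, X, D extend the current block
_BLOCK_SPLITTING = {3}  # N splits blocks (spliced alignment)


def _blocks_from_cigar(chrom: str, pos: int, cigartuples) -> tuple[GenomicInterval, ...]:
    blocks: list[GenomicInterval] = []
    start = pos
    cur = pos
    for op, length in cigartuples:
        if op in _REF_CONSUMING:
            cur += length
        elif op in _BLOCK_SPLITTING:
            if cur > start:
                blocks.append(GenomicInterval(chrom, start, cur))
            cur += length
            start = cur
        # I, S, H, P consume no reference
    if cur > start:
        blocks.append(GenomicInterval(chrom, start, cur))
    return tuple(blocks)


def read_sam(path: str | Path, sample_id: str = "") -> Iterator[ReadPlacement]:
    """Stream placements from a SAM/BAM file (unmapped records skipped)."""
    sample = sample_id or Path(path).stem
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            yield ReadPlacement(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                blocks=_blocks_from_cigar(
                    rec.reference_name, rec.reference_start, rec.cigartuples
                ),
                mapq=rec.mapping_quality,
                sample_id=sample,
            )


_CIGAR_OPS = "MIDNSHP=X"


def read_tsv_alignments(path: str | Path) -> Iterator[ReadPlacement]:
    """Read the simplified tabular alignment format.

    Columns (tab-separated, with header): read_id, chrom, start (0-based),
    cigar, mapq, sample.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    for row in df.itertuples(index=False):
        cig = [
            (_CIGAR_OPS.index(op), int(n))
            for n, op in re.findall(r"(\d+)([MIDNSHP=X])", row.cigar)
        ]
        yield ReadPlacement(
            read_id=str(row.read_id),
            chrom=row.chrom,
            blocks=_blocks_from_cigar(row.chrom, int(row.start), cig),
            mapq=int(row.mapq),
            sample_id=row.sample,
        )


def write_sam(
    reads: Iterable[ReadPlacement], path: str | Path, chrom_lengths: dict[str, int]
) -> None:
    """Write placements to a plain-text SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.read_id
            rec.reference_name = read.chrom
            rec.reference_start = read.blocks[0].start
            rec.mapping_quality = read.mapq
            rec.flag = 0
            cigar = []
            prev_end = None
            total_m = 0
            for b in read.blocks:
                if prev_end is not None:
                    cigar.append((3, b.start - prev_end))  # N gap
                cigar.append((0, len(b)))
                total_m += len(b)
                prev_end = b.end
            rec.cigartuples = cigar
            rec.query_sequence = "A" * total_m
            out.write(rec)
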