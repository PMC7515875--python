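"""Read classification and the singular-count rules (MAPQ >= 40, 1% audit)."""

import numpy as np
import pytest

from mei.genemodel import GenomicInterval, gene_model_from_exons
from mei.reads import (
    ReadPlacement,
    build_matrices,
    classify_read,
    count_sample,
    read_sam,
    read_tsv_alignments,
    write_sam,
)
from mei.synthetic import make_gene_models, make_multigene_reads, simulate_alignments


def read_at(chrom, start, end, mapq=60, rid="r", blocks=None):
    blocks = blocks or [(start, end)]
    return ReadPlacement(
        read_id=rid,
        chrom=chrom,
        blocks=tuple(GenomicInterval(chrom, s, e) for s, e in blocks),
        mapq=mapq,
        sample_id="s1",
    )


class TestClassifyRead:
    def test_block_inside_exon(self, three_exon_gene):
        assert classify_read(read_at("chr1", 150, 180), three_exon_gene) == "exonic"

    def test_block_inside_intron(self, three_exon_gene):
        assert classify_read(read_at("chr1", 310, 350), three_exon_gene) == "intronic"

    def test_boundary_straddling_read_is_exonic(self, three_exon_gene):
        # overlaps intron [300,399) and exon [399,500): exon priority
        assert classify_read(read_at("chr1", 380, 420), three_exon_gene) == "exonic"

    def test_read_outside_span(self, three_exon_gene):
        assert classify_read(read_at("chr1", 600, 650), three_exon_gene) == "outside"

    def test_wrong_chromosome_is_outside(self, three_exon_gene):
        assert classify_read(read_at("chr2", 150, 180), three_exon_gene) == "outside"

    def test_agrees_with_per_base_coverage_oracle(self, rng):
        """Random reads/models vs a brute-force per-base classification."""
        for _ in range(300):
            n_ex = rng.integers(1, 5)
            exons = []
            p = int(rng.integers(0, 50))
            for _ in range(n_ex):
                q = p + int(rng.integers(5, 60))
                exons.append((p, q))
                p = q + int(rng.integers(5, 60))
            model = gene_model_from_exons("G", "chr1", "+", exons)
            s = int(rng.integers(0, p + 40))
            e = s + int(rng.integers(1, 50))
            read = read_at("chr1", s, e)
            span = model.span
            base_is_exon = np.zeros(span.end, dtype=bool)
            for ex in model.exons:
                base_is_exon[ex.start : ex.end] = True
            bases = np.arange(s, e)
            inside = bases[(bases >= span.start) & (bases < span.end)]
            if inside.size and base_is_exon[inside].any():
                expected = "exonic"
            elif s >= span.start and e <= span.end:
                expected = "intronic"
            else:
                expected = "outside"
            assert classify_read(read, model) == expected


class TestCountSample:
    def test_clean_gene_is_singular(self, three_exon_gene):
        reads = [read_at("chr1", 150, 180, rid=f"r{i}") for i in range(100)]
        sc = count_sample(reads, [three_exon_gene])
        assert sc.exon["GENE1"] == 100
        assert sc.audits[0].singular

    def test_one_percent_rule_fails_contaminated_gene(self, three_exon_gene):
        reads = [read_at("chr1", 150, 180, rid=f"r{i}") for i in range(99)]
        reads += [read_at("chr1", 150, 180, mapq=10, rid=f"lq{i}") for i in range(2)]
        sc = count_sample(reads, [three_exon_gene])
        audit = sc.audits[0]
        assert audit.low_q_total == 2 and not audit.singular  # 2/101 > 1%
        assert "GENE1" not in sc.exon

    def test_multi_gene_read_counts_for_neither(self):
        models, _ = make_gene_models(n_genes=2)
        reads = make_multigene_reads(models, 1)
        sc = count_sample(reads, models)
        assert sc.unassigned == 1
        assert all(a.total == 0 for a in sc.audits)

    def test_unknown_chromosome_is_unassigned(self, three_exon_gene):
        sc = count_sample([read_at("chrZ", 0, 50)], [three_exon_gene])
        assert sc.unassigned == 1 and sc.processed == 1

    def test_read_conservation(self, rng):
        """Every processed read lands in exactly one tally."""
        models, _ = make_gene_models(n_genes=4)
        reads = simulate_alignments(
            models,
            exon_reads={m.gene_id: 30 for m in models},
            intron_reads={m.gene_id: 10 for m in models},
            lowq_reads={m.gene_id: 3 for m in models},
        )
        reads += make_multigene_reads(models, 5)
        reads += [read_at("chrZ", 0, 50, rid="z")]
        sc = count_sample(reads, models)
        tallied = sum(a.total for a in sc.audits) + sc.unassigned
        assert tallied == sc.processed == len(reads)

    def test_mapq_monotonicity(self):
        models, _ = make_gene_models(n_genes=3)
        reads = simulate_alignments(
            models,
            exon_reads={m.gene_id: 20 for m in models},
            lowq_reads={m.gene_id: 5 for m in models},
            mapq_low=35,
        )
        lo = count_sample(reads, models, mapq_min=30)
        hi = count_sample(reads, models, mapq_min=40)
        for g in [m.gene_id for m in models]:
            assert hi.exon.get(g, 0) <= lo.exon[g]

    def test_alt_frac_monotonicity(self):
        models, _ = make_gene_models(n_genes=3)
        reads = simulate_alignments(
            models,
            exon_reads={m.gene_id: 200 for m in models},
            lowq_reads={"G000": 1, "G001": 3, "G002": 10},
        )
        loose = {a.gene_id for a in count_sample(reads, models, alt_frac_max=0.05).audits if a.singular}
        strict = {a.gene_id for a in count_sample(reads, models, alt_frac_max=0.01).audits if a.singular}
        assert strict <= loose

    def test_duplicated_gene_kept_only_with_one_singular_locus(self):
        locus_a = gene_model_from_exons("DUP", "chr1", "+", [(0, 100)])
        locus_b = gene_model_from_exons("DUP", "chr1", "+", [(10_000, 10_100)])
        reads = [read_at("chr1", 10, 60, rid=f"a{i}") for i in range(50)]
        sc = count_sample(reads, [locus_a, locus_b])
        assert sc.exon["DUP"] == 50  # locus B has no counts -> not singular
        reads += [read_at("chr1", 10_010, 10_060, rid=f"b{i}") for i in range(50)]
        sc2 = count_sample(reads, [locus_a, locus_b])
        assert "DUP" not in sc2.exon and sc2.dropped_duplicated == ["DUP"]


class TestBuildMatrices:
    def test_gene_must_be_singular_in_every_sample(self):
        models, _ = make_gene_models(n_genes=2)
        clean = simulate_alignments(models, {m.gene_id: 50 for m in models})
        dirty = simulate_alignments(
            models, {m.gene_id: 50 for m in models}, lowq_reads={"G001": 5}
        )
        mc = build_matrices(
            {
                "s1": count_sample(clean, models, sample_id="s1"),
                "s2": count_sample(dirty, models, sample_id="s2"),
            }
        )
        assert list(mc.genes) == ["G000"]

    def test_all_singular_gives_full_matrix(self):
        models, _ = make_gene_models(n_genes=3)
        reads = simulate_alignments(
            models, {m.gene_id: 50 for m in models}, {m.gene_id: 20 for m in models}
        )
        per = {
            s: count_sample(reads, models, sample_id=s) for s in ("s1", "s2")
        }
        mc = build_matrices(per)
        assert mc.exon.shape == (3, 2)
        assert (mc.exon.values == 50).all() and (mc.intron.values == 20).all()

    def test_single_sample_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_matrices({"s1": None})


class TestAlignmentIO:
    def test_sam_round_trip(self, tmp_path):
        models, chrom_lengths = make_gene_models(n_genes=2)
        reads = simulate_alignments(
            models, {m.gene_id: 5 for m in models}, {m.gene_id: 2 for m in models}
        ) + make_multigene_reads(models, 1)
        path = tmp_path / "t.sam"
        write_sam(reads, path, chrom_lengths)
        back = list(read_sam(path, "s1"))
        assert len(back) == len(reads)
        orig = {(r.read_id, tuple((b.start, b.end) for b in r.blocks), r.mapq) for r in reads}
        rt = {(r.read_id, tuple((b.start, b.end) for b in r.blocks), r.mapq) for r in back}
        assert orig == rt

    def test_tsv_alignment_format(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text(
            "read_id\tchrom\tstart\tcigar\tmapq\tsample\n"
            "r1\tchr1\t100\t30M20N20M\t60\ts1\n"
            "r2\tchr1\t500\t50M\t10\ts1\n"
        )
        reads = list(read_tsv_alignments(path))
        assert [(b.start, b.end) for b in reads[0].blocks] == [(100, 130), (150, 170)]
        assert reads[1].mapq == 10
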