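"""Format layer: GFF3 gene models, CIGAR block construction, event table."""

import numpy as np
import pytest

from splicevents import formats_io
from splicevents.as_detector import ASEvent
from splicevents.formats_io import (
    AlignmentRecord,
    GFF3ParseError,
    GeneModel,
    GeneModelValidationError,
    blocks_from_cigar,
    read_alignments,
    read_event_table,
    read_gene_models,
    write_event_table,
)

GFF3_SIMPLE = """##gff-version 3
chr1\tt\tgene\t1\t300\t.\t+\t.\tID=gA
chr1\tt\tmRNA\t1\t300\t.\t+\t.\tID=gA.1;Parent=gA
chr1\tt\texon\t1\t100\t.\t+\t.\tID=gA.1.e1;Parent=gA.1
chr1\tt\texon\t201\t300\t.\t+\t.\tID=gA.1.e2;Parent=gA.1
chr1\tt\tCDS\t51\t100\t.\t+\t0\tID=gA.1.c1;Parent=gA.1
chr1\tt\tCDS\t201\t250\t.\t+\t0\tID=gA.1.c2;Parent=gA.1
chr1\tt\tgene\t500\t600\t.\t-\t.\tID=gB
chr1\tt\tmRNA\t500\t600\t.\t-\t.\tID=gB.1;Parent=gB
chr1\tt\texon\t500\t600\t.\t-\t.\tID=gB.1.e1;Parent=gB.1
"""

GFF3_TWO_ISOFORMS = """##gff-version 3
chr1\tt\tgene\t1\t500\t.\t+\t.\tID=gC
chr1\tt\tmRNA\t1\t500\t.\t+\t.\tID=gC.1;Parent=gC
chr1\tt\texon\t1\t100\t.\t+\t.\tID=e1;Parent=gC.1
chr1\tt\texon\t201\t500\t.\t+\t.\tID=e2;Parent=gC.1
chr1\tt\tmRNA\t1\t500\t.\t+\t.\tID=gC.2;Parent=gC
chr1\tt\texon\t1\t120\t.\t+\t.\tID=e3;Parent=gC.2
chr1\tt\texon\t401\t500\t.\t+\t.\tID=e4;Parent=gC.2
"""


class TestReadGeneModels:
    def test_coordinate_conversion_and_introns(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF3_SIMPLE)
        genes = {g.gene_id: g for g in read_gene_models(p)}
        gA = genes["gA"]
        assert gA.exons == ((0, 100), (200, 300))
        assert gA.annotated_introns == ((100, 200),)
        assert gA.cds_span == (50, 250)
        assert gA.utr_regions() == [(0, 50), (250, 300)]

    def test_single_exon_gene_has_no_introns(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF3_SIMPLE)
        gB = {g.gene_id: g for g in read_gene_models(p)}["gB"]
        assert gB.annotated_introns == ()
        assert gB.strand == "-"

    def test_multi_isoform_collapses_to_exon_union(self, tmp_path):
        p = tmp_path / "c.gff3"
        p.write_text(GFF3_TWO_ISOFORMS)
        (gC,) = read_gene_models(p)
        assert gC.exons == ((0, 120), (200, 500))
        assert gC.annotated_introns == ((120, 200),)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nchr1\tt\tgene\t1\n")
        with pytest.raises(GFF3ParseError, match="line 2"):
            read_gene_models(p)

    def test_exon_outside_gene_span_rejected(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tt\tgene\t100\t200\t.\t+\t.\tID=g\n"
            "chr1\tt\texon\t50\t200\t.\t+\t.\tID=e;Parent=g\n"
        )
        with pytest.raises(GeneModelValidationError):
            read_gene_models(p)

    def test_gff3_roundtrip_preserves_exon_coordinates(self, tmp_path, small_scenario):
        from splicevents.simulate import write_gff3

        p = tmp_path / "rt.gff3"
        write_gff3(small_scenario.genes, p)
        back = read_gene_models(p)
        assert [(g.gene_id, g.exons, g.strand) for g in back] == [
            (g.gene_id, g.exons, g.strand)
            for g in sorted(small_scenario.genes, key=lambda g: g.span)
        ]


class TestCigarBlocks:
    @pytest.mark.parametrize(
        "pos,cigar,expected",
        [
            (99, [(0, 20), (3, 50), (0, 30)], ((99, 119), (169, 199))),
            (0, [(0, 85)], ((0, 85),)),
            # soft clip ignored, deletion merges into the block
            (9, [(4, 5), (0, 30), (2, 10), (0, 10)], ((9, 59),)),
            (0, [(0, 10), (1, 5), (0, 10)], ((0, 20),)),  # insertion: no ref
            (5, [(7, 10), (3, 30), (8, 10)], ((5, 15), (45, 55))),  # =/X
        ],
    )
    def test_block_semantics(self, pos, cigar, expected):
        assert blocks_from_cigar(pos, cigar) == expected

    def test_unknown_op_is_hard_error(self):
        with pytest.raises(ValueError, match="unknown CIGAR"):
            blocks_from_cigar(0, [(0, 10), (11, 5)])

    def test_matches_per_base_walk_on_random_cigars(self):
        """Block construction equals a brute-force per-base CIGAR walk."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            pos = int(rng.integers(0, 1000))
            cigar = _random_cigar(rng)
            assert blocks_from_cigar(pos, cigar) == _walk_cigar(pos, cigar), cigar


def _random_cigar(rng):
    ops = [(0, int(rng.integers(1, 60)))]
    for _ in range(int(rng.integers(0, 6))):
        op = int(rng.choice([0, 1, 2, 3, 7, 8]))
        ops.append((op, int(rng.integers(1, 80))))
        ops.append((0, int(rng.integers(1, 60))))
    if rng.random() < 0.3:
        ops.insert(0, (4, int(rng.integers(1, 10))))
    if rng.random() < 0.3:
        ops.append((4, int(rng.integers(1, 10))))
    return ops


def _walk_cigar(pos, cigar):
    """Independent oracle: advance one base at a time, recording which
    reference bases are inside an aligned block."""
    covered = []
    ref = pos
    for op, ln in cigar:
        for _ in range(ln):
            if op in (0, 2, 7, 8):  # M, D, =, X extend the block footprint
                covered.append(ref)
                ref += 1
            elif op == 3:
                covered.append(None)  # block break
                ref += 1
    blocks = []
    start = prev = None
    for c in covered:
        if c is None:
            if start is not None:
                blocks.append((start, prev + 1))
            start = None
            continue
        if start is None:
            start = c
        prev = c
    if start is not None:
        blocks.append((start, prev + 1))
    return tuple(blocks)


SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"


class TestReadAlignments:
    def _parse(self, tmp_path, body):
        p = tmp_path / "r.sam"
        p.write_text(SAM_HEADER + body)
        return list(read_alignments(p, "s1"))

    def test_spliced_read_fields(self, tmp_path):
        recs = self._parse(
            tmp_path, "r1\t0\tchr1\t100\t60\t20M50N30M\t*\t0\t0\t*\t*\tNM:i:2\tNH:i:1\n"
        )
        (r,) = recs
        assert r.blocks == ((99, 119), (169, 199))
        assert r.mismatches == 2 and r.is_unique and r.sample_id == "s1"

    def test_nh_tag_marks_multimappers(self, tmp_path):
        recs = self._parse(
            tmp_path,
            "r1\t0\tchr1\t100\t60\t85M\t*\t0\t0\t*\t*\tNH:i:3\n"
            "r2\t0\tchr1\t100\t60\t85M\t*\t0\t0\t*\t*\tNH:i:1\n",
        )
        assert [r.is_unique for r in recs] == [False, True]

    def test_mapq_fallback_without_nh(self, tmp_path):
        recs = self._parse(
            tmp_path,
            "r1\t0\tchr1\t100\t3\t85M\t*\t0\t0\t*\t*\n"
            "r2\t0\tchr1\t100\t60\t85M\t*\t0\t0\t*\t*\n",
        )
        assert [r.is_unique for r in recs] == [False, True]

    def test_missing_cigar_skipped(self, tmp_path):
        recs = self._parse(
            tmp_path,
            "r1\t4\tchr1\t0\t0\t*\t*\t0\t0\t*\t*\n"
            "r2\t0\tchr1\t100\t60\t85M\t*\t0\t0\t*\t*\n",
        )
        assert len(recs) == 1


class TestEventTable:
    def _events(self):
        return [
            ASEvent(
                gene_id="g1", chrom="chr1", strand="+", event_type="ES",
                alt_interval=(100, 400), const_intervals=((100, 200), (300, 400)),
                alt_support=5, const_support=20, aer=0.25,
                sample_ids=frozenset({"a", "b", "c"}),
            ),
            ASEvent(
                gene_id="g2", chrom="chr1", strand="-", event_type="IR",
                alt_interval=(50, 90), const_intervals=((50, 90),),
                alt_support=3.5, const_support=20, aer=0.175,
                sample_ids=frozenset({"a", "b", "d"}),
            ),
            ASEvent(
                gene_id="g2", chrom="chr1", strand="-", event_type="Alt5",
                alt_interval=(50, 80), const_intervals=((50, 90),),
                alt_support=2, const_support=20, aer=0.1,
                sample_ids=frozenset({"a", "b", "c", "d"}),
                shift_distance=10, in_frame=False,
            ),
        ]

    def test_roundtrip_identity(self, tmp_path):
        p = tmp_path / "ev.tsv"
        events = self._events()
        write_event_table(events, p)
        assert set(read_event_table(p)) == set(events)

    def test_header_and_empty_table(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_event_table([], p)
        lines = p.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        assert lines[-1].startswith("#gene_id\t")
        assert read_event_table(p) == []

    def test_coordinates_emitted_one_based_closed(self, tmp_path):
        p = tmp_path / "ev.tsv"
        write_event_table(self._events()[:1], p)
        row = [l for l in p.read_text().splitlines() if not l.startswith("#")][0]
        f = row.split("\t")
        assert (f[4], f[5]) == ("101", "400")  # alt interval (100,400) 0-based
        assert (f[6], f[7]) == ("101,301", "200,400")
        assert f[14] == "3"
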