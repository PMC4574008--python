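"""Six-type event detection: definitions, precedence, strand symmetry."""

import itertools

import numpy as np
import pytest

from splicevents.as_detector import (
    classify_novel_junction,
    detect_all,
    detect_alt_sites,
    detect_antisense,
    detect_cryptic_intron,
    detect_exon_skipping,
    detect_intron_retention,
)
from splicevents.formats_io import GeneModel
from splicevents.junctions import SpliceJunction


def j(start, end, support=10, novelty="novel", antisense=False,
      motif="GT-AG", motif_strand="+", chrom="c"):
    return SpliceJunction(
        chrom=chrom, start=start, end=end, support=support, motif=motif,
        motif_strand=motif_strand, novelty=novelty, antisense=antisense,
        location="genic", sample_id="s1",
    )


def flat_depth(gene, value):
    s, e = gene.span
    return np.full(e - s, value, dtype=np.int64)


class TestAltSites:
    def gene(self, strand="+"):
        return GeneModel("g", "c", strand, ((900, 1000), (1200, 1300)))

    def test_shifted_acceptor_on_plus_is_alt3(self):
        junctions = [j(1000, 1200, 40, novelty="annotated"), j(1000, 1190, 2)]
        (ev,) = detect_alt_sites(self.gene("+"), junctions)
        assert ev.event_type == "Alt3"
        assert ev.shift_distance == 10 and ev.in_frame is False
        assert ev.aer == pytest.approx(2 / 40)

    def test_same_shift_on_minus_is_alt5(self):
        junctions = [j(1000, 1200, 40, novelty="annotated"), j(1000, 1190, 2)]
        (ev,) = detect_alt_sites(self.gene("-"), junctions)
        assert ev.event_type == "Alt5"  # the high-coordinate side is the donor

    def test_shifted_donor_in_frame(self):
        junctions = [j(1000, 1200, 40, novelty="annotated"), j(1003, 1200, 2)]
        (ev,) = detect_alt_sites(self.gene("+"), junctions)
        assert ev.event_type == "Alt5"
        assert ev.shift_distance == 3 and ev.in_frame is True

    def test_unsupported_annotated_intron_blocks_call(self):
        # the constitutive form must be transcribed too
        assert detect_alt_sites(self.gene("+"), [j(1000, 1190, 2)]) == []


class TestExonSkipping:
    gene = GeneModel("g", "c", "+", ((0, 100), (200, 300), (400, 500)))

    def test_single_exon_skip(self):
        junctions = [
            j(100, 200, 10, novelty="annotated"),
            j(300, 400, 12, novelty="annotated"),
            j(100, 400, 5),
        ]
        (ev,) = detect_exon_skipping(self.gene, junctions)
        assert ev.const_intervals == ((100, 200), (300, 400))
        assert ev.const_support == 22
        assert ev.aer == pytest.approx(5 / 22)

    def test_unsupported_flanking_intron_blocks_call(self):
        junctions = [j(100, 200, 10, novelty="annotated"), j(100, 400, 5)]
        assert detect_exon_skipping(self.gene, junctions) == []

    def test_multi_exon_skip_matches_brute_force_enumeration(self):
        """Every (donor of intron i, acceptor of intron k>i) junction — and
        only those — is an ES call, verified against enumerating all exon
        combinations of a 5-exon gene."""
        gene = GeneModel(
            "g", "c", "+",
            tuple((i * 200, i * 200 + 100) for i in range(5)),
        )
        introns = gene.annotated_introns
        ann = [j(s, e, 10, novelty="annotated") for s, e in introns]
        candidates = []
        for s in range(0, 1000, 50):
            for e in range(s + 100, 1100, 50):
                candidates.append(j(s, e, 3))
        events = detect_exon_skipping(gene, ann + candidates)
        got = {ev.alt_interval for ev in events}
        expected = {
            (introns[a][0], introns[b][1])
            for a, b in itertools.combinations(range(len(introns)), 2)
        }
        # brute force: a junction is ES iff it spans >=1 complete exon and
        # both ends sit on distinct annotated intron boundaries
        assert got == {
            (s, e) for (s, e) in expected
            if any(s <= x0 and x1 <= e for x0, x1 in gene.exons)
        } == expected


class TestIntronRetention:
    gene = GeneModel("g", "c", "+", ((0, 100), (200, 300)))

    def test_complete_coverage_with_junction_support(self):
        depth = flat_depth(self.gene, 4)
        (ev,) = detect_intron_retention(
            self.gene, [j(100, 200, 20, novelty="annotated")], depth)
        assert ev.event_type == "IR"
        assert ev.alt_support == 4.0 and ev.aer == pytest.approx(4 / 20)

    def test_one_uncovered_base_blocks_call(self):
        depth = flat_depth(self.gene, 4)
        depth[150] = 0
        assert detect_intron_retention(
            self.gene, [j(100, 200, 20, novelty="annotated")], depth) == []

    def test_unobserved_junction_blocks_call(self):
        # full coverage without the excising junction could be mis-annotation
        depth = flat_depth(self.gene, 4)
        assert detect_intron_retention(self.gene, [], depth) == []

    def test_even_length_median(self):
        depth = flat_depth(self.gene, 2)
        depth[100:150] = 4  # half the intron deeper: median (2+4)/2 = 3
        (ev,) = detect_intron_retention(
            self.gene, [j(100, 200, 6, novelty="annotated")], depth)
        assert ev.alt_support == 3.0 and ev.aer == pytest.approx(0.5)


class TestCrypticIntron:
    gene = GeneModel("g", "c", "+", ((0, 100), (200, 300)))

    def test_strictly_interior_junction(self):
        depth = flat_depth(self.gene, 5)
        (ev,) = detect_cryptic_intron(self.gene, [j(230, 270, 4)], depth)
        assert ev.event_type == "IRc"
        assert ev.const_support == 5.0 and ev.aer == pytest.approx(4 / 5)

    @pytest.mark.parametrize("interval", [(200, 270), (230, 300), (150, 250)])
    def test_boundary_touching_or_crossing_is_not_irc(self, interval):
        depth = flat_depth(self.gene, 5)
        assert detect_cryptic_intron(self.gene, [j(*interval, 4)], depth) == []


class TestAntisense:
    gene = GeneModel("g", "c", "+", ((0, 100), (200, 300)))

    def test_opposite_motif_with_sense_support(self):
        junctions = [
            j(100, 200, 30, novelty="annotated"),
            j(220, 260, 3, motif_strand="-", antisense=True),
        ]
        (ev,) = detect_antisense(self.gene, junctions)
        assert ev.const_support == 30 and ev.aer == pytest.approx(0.1)

    def test_unknown_motif_never_antisense(self):
        junctions = [
            j(100, 200, 30, novelty="annotated"),
            j(220, 260, 3, motif="other", motif_strand="unknown"),
        ]
        assert detect_antisense(self.gene, junctions) == []

    def test_no_sense_support_drops_event(self):
        junctions = [j(220, 260, 3, motif_strand="-", antisense=True)]
        assert detect_antisense(self.gene, junctions) == []


class TestPrecedenceAndSymmetry:
    def test_endpoint_patterns_are_mutually_exclusive(self):
        """ES needs both ends on annotated boundaries, Alt exactly one, IRc
        none (interior): no junction can satisfy two patterns."""
        gene = GeneModel("g", "c", "+", ((0, 100), (200, 300), (400, 500)))
        boundary_points = [0, 50, 100, 150, 200, 225, 250, 275, 300, 350,
                           400, 425, 475, 500]
        seen = set()
        for s in boundary_points:
            for e in boundary_points:
                if e - s < 25:
                    continue
                cls = classify_novel_junction(gene, (s, e))
                seen.add(cls)
                # recompute the pattern independently
                starts = {iv[0]: iv for iv in gene.annotated_introns}
                ends = {iv[1]: iv for iv in gene.annotated_introns}
                hit_s, hit_e = s in starts, e in ends
                if hit_s and hit_e and starts[s] == ends[e]:
                    # the annotated intron itself: constitutive, not an event
                    assert cls == "unclassified"
                elif hit_s and hit_e:
                    assert cls == "ES"
                elif hit_s or hit_e:
                    assert cls == "Alt"
                elif any(x0 < s and e < x1 for x0, x1 in gene.exons):
                    assert cls == "IRc"
                else:
                    assert cls == "unclassified"
        assert seen == {"ES", "Alt", "IRc", "unclassified"}

    def _all_pattern_inputs(self, strand):
        gene = GeneModel("g", "c", strand, ((0, 100), (200, 300), (400, 500)))
        junctions = [
            j(100, 200, 20, novelty="annotated"),
            j(300, 400, 20, novelty="annotated"),
            j(100, 190, 2),                      # Alt (acceptor side on +)
            j(103, 200, 2),                      # Alt (donor side on +)
            j(100, 400, 2),                      # ES
            j(230, 270, 2),                      # IRc
            j(240, 280, 2, motif_strand="-" if strand == "+" else "+",
              antisense=True),                   # Antisense
        ]
        depth = flat_depth(gene, 5)
        return gene, junctions, depth

    def test_exclusivity_each_junction_at_most_one_event(self):
        gene, junctions, depth = self._all_pattern_inputs("+")
        events = detect_all(gene, junctions, depth)
        alt_ivs = [ev.alt_interval for ev in events if ev.event_type != "IR"]
        assert len(alt_ivs) == len(set(alt_ivs))
        assert all(ev.alt_support > 0 and ev.const_support > 0 for ev in events)
        assert {ev.event_type for ev in events} == {
            "Alt3", "Alt5", "ES", "IRc", "Antisense", "IR"}

    def test_strand_flip_swaps_alt5_alt3_only(self):
        """Reversing the locus strand (gene strand plus junction motif
        orientations) swaps Alt5 <-> Alt3 and changes nothing else."""
        gene_p, junc_p, depth = self._all_pattern_inputs("+")
        gene_m, junc_m, _ = self._all_pattern_inputs("-")
        ev_p = detect_all(gene_p, junc_p, depth)
        ev_m = detect_all(gene_m, junc_m, depth)
        swap = {"Alt5": "Alt3", "Alt3": "Alt5"}
        key_p = sorted((swap.get(e.event_type, e.event_type), e.alt_interval,
                        e.aer) for e in ev_p)
        key_m = sorted((e.event_type, e.alt_interval, e.aer) for e in ev_m)
        assert key_p == key_m

    def test_constitutive_only_gene_yields_nothing(self):
        gene = GeneModel("g", "c", "+", ((0, 100), (200, 300)))
        junctions = [j(100, 200, 30, novelty="annotated")]
        depth = flat_depth(gene, 0)
        depth[0:100] = 10
        depth[200:300] = 10
        assert detect_all(gene, junctions, depth) == []
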