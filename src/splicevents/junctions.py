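"""Splice-junction extraction, filtering and classification.

A junction is the intron interval excised between a donor and an acceptor
splice site, evidenced by the N gaps of spliced read alignments.  Reads
contribute support only if they pass the quality filters (unique mapping,
mismatch cap, minimum overhang on the shorter side) and the gap is at least
the minimum intron length; shorter gaps are treated as alignment artifacts
and the read is kept as unspliced evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from intervaltree import IntervalTree

from .formats_io import AlignmentRecord, GeneModel, Interval

logger = logging.getLogger(__name__)

MOTIF_GT_AG = "GT-AG"
MOTIF_GC_AG = "GC-AG"
MOTIF_AT_AC = "AT-AC"
MOTIF_OTHER = "other"

# (first two intronic bases, last two intronic bases) -> (motif class, strand)
_MOTIF_TABLE: dict[tuple[str, str], tuple[str, str]] = {
    ("GT", "AG"): (MOTIF_GT_AG, "+"),
    ("CT", "AC"): (MOTIF_GT_AG, "-"),
    ("GC", "AG"): (MOTIF_GC_AG, "+"),
    ("CT", "GC"): (MOTIF_GC_AG, "-"),
    ("AT", "AC"): (MOTIF_AT_AC, "+"),
    ("GT", "AT"): (MOTIF_AT_AC, "-"),
}


@dataclass
class SpliceJunction:
    """An intron interval with its read support and classification."""

    chrom: str
    start: int  # first intronic base, 0-based
    end: int  # one past the last intronic base
    support: int = 0
    motif: str = MOTIF_OTHER
    motif_strand: str = "unknown"
    sample_id: str = ""
    novelty: str = "novel"  # 'annotated' | 'novel'
    location: str = "intergenic"  # 'genic' | 'intergenic'
    region: str = "none"  # 'UTR' | 'UTR-CDS' | 'CDS' | 'none'
    antisense: bool = False
    gene_id: Optional[str] = None
    ambiguous: bool = False  # overlaps >=2 genes with no resolvable assignment

    @property
    def interval(self) -> Interval:
        return self.start, self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FilterStats:
    """Counts of reads removed by each alignment-quality filter."""

    n_records: int = 0
    n_multi_mapped: int = 0
    n_mismatch_excess: int = 0
    n_short_overhang_gaps: int = 0
    n_subminimal_gaps: int = 0
    n_junction_observations: int = 0


def extract_junctions(
    alignments: Iterable[AlignmentRecord],
    min_intron: int = 25,
    max_mismatches: int = 8,
    min_overhang: int = 8,
    require_unique: bool = True,
    stats: FilterStats | None = None,
) -> dict[tuple[str, int, int], SpliceJunction]:
    """Count junction support from one sample's alignments.

    Each inter-block gap of length >= ``min_intron`` in a read passing the
    uniqueness and mismatch filters adds 1 to that junction's support,
    provided the aligned length on the gap's shorter side is at least
    ``min_overhang``.  A read spanning several junctions supports each one,
    with the overhang measured to the nearest read end.
    """
    stats = stats if stats is not None else FilterStats()
    junctions: dict[tuple[str, int, int], SpliceJunction] = {}
    sample_id = ""
    for rec in alignments:
        stats.n_records += 1
        sample_id = rec.sample_id or sample_id
        if require_unique and not rec.is_unique:
            stats.n_multi_mapped += 1
            continue
        if rec.mismatches > max_mismatches:
            stats.n_mismatch_excess += 1
            continue
        if len(rec.blocks) < 2:
            continue
        lengths = [e - s for s, e in rec.blocks]
        total = sum(lengths)
        left = 0
        for i in range(len(rec.blocks) - 1):
            left += lengths[i]
            gap_start = rec.blocks[i][1]
            gap_end = rec.blocks[i + 1][0]
            if gap_end - gap_start < min_intron:
                stats.n_subminimal_gaps += 1
                continue
            if min(left, total - left) < min_overhang:
                stats.n_short_overhang_gaps += 1
                continue
            key = (rec.chrom, gap_start, gap_end)
            j = junctions.get(key)
            if j is None:
                j = SpliceJunction(
                    chrom=rec.chrom,
                    start=gap_start,
                    end=gap_end,
                    sample_id=rec.sample_id,
                )
                junctions[key] = j
            j.support += 1
            stats.n_junction_observations += 1
    for j in junctions.values():
        if not j.sample_id:
            j.sample_id = sample_id
    return junctions


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome sequence as an uppercase string from a dict of contig
    strings or any object with a pysam/pyfaidx-style indexable interface."""
    if isinstance(genome, Mapping):
        seq = genome[chrom][start:end]
    elif hasattr(genome, "fetch"):  # pysam.FastaFile
        seq = genome.fetch(chrom, start, end)
    else:  # pyfaidx.Fasta and similar
        seq = str(genome[chrom][start:end])
    return str(seq).upper()


def contig_length(genome, chrom: str) -> int:
    if isinstance(genome, Mapping):
        return len(genome[chrom])
    if hasattr(genome, "get_reference_length"):
        return genome.get_reference_length(chrom)
    return len(genome[chrom])


def classify_motif(
    junction: SpliceJunction, genome
) -> tuple[str, str]:
    """Classify the splice-site dinucleotides of one junction.

    Reads the first two and last two intronic bases; canonical pairs imply
    both the motif class and the transcription strand (a GT..AG intron on the
    minus strand appears as CT..AC on the forward genome).  Anything outside
    the canonical table is (other, unknown).
    """
    if junction.end > contig_length(genome, junction.chrom):
        raise ValueError(
            f"junction {junction.chrom}:{junction.start}-{junction.end} "
            "extends beyond the contig"
        )
    donor = fetch_sequence(genome, junction.chrom, junction.start, junction.start + 2)
    acceptor = fetch_sequence(genome, junction.chrom, junction.end - 2, junction.end)
    motif, strand = _MOTIF_TABLE.get((donor, acceptor), (MOTIF_OTHER, "unknown"))
    junction.motif = motif
    junction.motif_strand = strand
    return motif, strand


def build_gene_tree(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        s, e = g.span
        trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
    return trees


def classify_location(
    junction: SpliceJunction,
    gene_trees: dict[str, IntervalTree],
) -> SpliceJunction:
    """Fill novelty, location, region, antisense and gene assignment.

    A junction is genic iff its intron interval lies within some gene's span;
    annotated iff it equals one of that gene's annotated introns.  When the
    intron is contained in several genes, it goes to the gene whose annotated
    splicing pattern it matches, else to the gene with the larger span
    overlap; unresolvable ties are flagged ambiguous (excluded from event
    calling).  Region classing uses the junction borders: the last exonic
    base before the donor and the first after the acceptor.
    """
    tree = gene_trees.get(junction.chrom)
    candidates = []
    if tree is not None:
        for iv in tree.overlap(junction.start, junction.end):
            g: GeneModel = iv.data
            if g.span[0] <= junction.start and junction.end <= g.span[1]:
                candidates.append(g)
    if not candidates:
        junction.location = "intergenic"
        junction.region = "none"
        junction.gene_id = None
        junction.novelty = "novel"
        junction.antisense = False
        return junction

    junction.location = "genic"
    gene = None
    if len(candidates) == 1:
        gene = candidates[0]
    else:
        matching = [
            g for g in candidates if junction.interval in set(g.annotated_introns)
        ]
        if len(matching) == 1:
            gene = matching[0]
        elif not matching:
            # containment makes span overlap equal for all candidates; fall
            # back to the smaller gene (tighter locus), ties stay ambiguous
            candidates.sort(key=lambda g: (g.span[1] - g.span[0], g.gene_id))
            if (candidates[0].span[1] - candidates[0].span[0]) < (
                candidates[1].span[1] - candidates[1].span[0]
            ):
                gene = candidates[0]
    if gene is None:
        junction.ambiguous = True
        junction.gene_id = None
        junction.novelty = "novel"
        junction.region = "none"
        return junction

    junction.gene_id = gene.gene_id
    junction.novelty = (
        "annotated" if junction.interval in set(gene.annotated_introns) else "novel"
    )
    junction.antisense = (
        junction.motif_strand in "+-" and junction.motif_strand != gene.strand
    )
    left = gene.coding_class(junction.start - 1)
    right = gene.coding_class(junction.end)
    junction.region = left if left == right else "UTR-CDS"
    return junction


def classify_junctions(
    junctions: Iterable[SpliceJunction],
    genome,
    genes: Iterable[GeneModel],
) -> list[SpliceJunction]:
    """Run motif then location classification over a junction set."""
    trees = build_gene_tree(genes)
    out = []
    for j in junctions:
        classify_motif(j, genome)
        classify_location(j, trees)
        out.append(j)
    return out


def junction_report(
    junctions_by_sample: Mapping[str, Iterable[SpliceJunction]],
) -> pd.DataFrame:
    """Per-sample junction summary: totals, novelty, location, gene-region
    breakdown (as fractions of genic junctions) and motif-class fractions.

    Empty samples yield a zero row flagged ``empty=True`` with percentages 0.
    """
    rows = []
    for sample in sorted(junctions_by_sample):
        js = list(junctions_by_sample[sample])
        n = len(js)
        n_genic = sum(j.location == "genic" for j in js)
        n_region = {
            r: sum(j.region == r for j in js) for r in ("UTR", "UTR-CDS", "CDS")
        }
        def pct(k: float, d: float) -> float:
            return 100.0 * k / d if d else 0.0

        rows.append(
            {
                "sample": sample,
                "n_sj": n,
                "empty": n == 0,
                "pct_novel": pct(sum(j.novelty == "novel" for j in js), n),
                "pct_genic": pct(n_genic, n),
                "pct_intergenic": pct(n - n_genic, n),
                "pct_utr": pct(n_region["UTR"], n_genic),
                "pct_utr_cds": pct(n_region["UTR-CDS"], n_genic),
                "pct_cds": pct(n_region["CDS"], n_genic),
                "pct_gt_ag": pct(sum(j.motif == MOTIF_GT_AG for j in js), n),
                "pct_gc_ag": pct(sum(j.motif == MOTIF_GC_AG for j in js), n),
                "pct_at_ac": pct(sum(j.motif == MOTIF_AT_AC for j in js), n),
                "pct_other_motif": pct(sum(j.motif == MOTIF_OTHER for j in js), n),
            }
        )
    return pd.DataFrame(rows)


def write_junction_bed(
    junctions: Iterable[SpliceJunction], path
) -> None:
    """BED-like export: chrom, start, end, support, motif, strand (0-based
    half-open)."""
    with open(path, "w") as fh:
        for j in sorted(junctions, key=lambda j: (j.chrom, j.start, j.end)):
            strand = j.motif_strand if j.motif_strand in "+-" else "."
            fh.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.support}\t{j.motif}\t{strand}\n"
            )
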