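"""Synthetic genomes, gene models and spliced alignments with planted AS.

The generator emulates the study setting the detector targets: 85 bp reads
aligned over multi-exon genes, constitutive junctions at full coverage,
alternative junctions at a low relative fraction, canonical splice motifs
drawn at the plant-genome mixture GT-AG : GC-AG : AT-AC = 94 % : 2.1 % :
0.7 % (remainder non-canonical).  Reads are emitted as already-aligned
records (SAM with N-gapped CIGARs, NM=0, NH=1), so no aligner or download is
needed, and a machine-readable truth table records every planted event with
its expected Alternative Event Ratio.

Alternative read counts are planted deterministically (``round(fraction *
coverage)`` reads per planted sample); only read placement within exons is
random.  Depth-based expectations (IR, IRc) are computed from the actually
planted read layout, so the truth table is exact per sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .coverage import coverage_array
from .formats_io import AlignmentRecord, GeneModel, Interval

logger = logging.getLogger(__name__)

DEFAULT_MOTIF_FRACTIONS = (0.94, 0.021, 0.007)  # GT-AG, GC-AG, AT-AC
_MOTIF_CLASSES = ("GT-AG", "GC-AG", "AT-AC", "other")

# genomic (donor, acceptor) dinucleotides per motif class and gene strand
_SENSE_DINUCS = {
    ("GT-AG", "+"): ("GT", "AG"),
    ("GT-AG", "-"): ("CT", "AC"),
    ("GC-AG", "+"): ("GC", "AG"),
    ("GC-AG", "-"): ("CT", "GC"),
    ("AT-AC", "+"): ("AT", "AC"),
    ("AT-AC", "-"): ("GT", "AT"),
    ("other", "+"): ("AA", "TT"),
    ("other", "-"): ("AA", "TT"),
}

EVENT_CYCLE = ("IR", "Alt3", "Alt5", "ES", "IRc", "Antisense")


@dataclass
class TruthRecord:
    """Ground truth for one planted alternative-splicing event."""

    gene_id: str
    event_type: str
    alt_interval: Interval
    const_intervals: tuple[Interval, ...]
    planted_alt_fraction: float
    planted_samples: tuple[str, ...]
    expected_aer: float = float("nan")
    expected_aer_by_sample: dict = field(default_factory=dict)
    shift_distance: Optional[int] = None

    @property
    def key(self) -> tuple[str, str, Interval]:
        return (self.gene_id, self.event_type, self.alt_interval)


@dataclass
class Scenario:
    """A fully generated study: genome, annotation, reads and truth."""

    genome: dict[str, str]
    genes: list[GeneModel]
    truth: list[TruthRecord]
    reads_by_sample: dict[str, list[AlignmentRecord]]
    motif_counts: dict[str, int]
    intron_motifs: dict[str, list[str]]
    seed: int
    coverage: int
    read_len: int

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.reads_by_sample)


# ---------------------------------------------------------------------------
# genome + gene layout


def _plant(seq: np.ndarray, pos: int, dinuc: str) -> None:
    seq[pos] = dinuc[0]
    seq[pos + 1] = dinuc[1]


def _plant_intron_motif(
    seq: np.ndarray, intron: Interval, motif_class: str, strand: str
) -> None:
    d, a = _SENSE_DINUCS[(motif_class, strand)]
    _plant(seq, intron[0], d)
    _plant(seq, intron[1] - 2, a)


def make_genome_and_genes(
    n_genes: int,
    exons_per_gene: tuple[int, int] = (3, 7),
    seed: int = 0,
    motif_fractions: Sequence[float] = DEFAULT_MOTIF_FRACTIONS,
    exon_len: tuple[int, int] = (120, 240),
    intron_len: tuple[int, int] = (60, 140),
    intergenic_gap: tuple[int, int] = (200, 400),
    chrom: str = "chr1",
) -> tuple[dict[str, str], list[GeneModel], dict[str, list[str]], dict[str, int]]:
    """Generate a random genome and union-exon gene models.

    Genes alternate pseudo-randomly between strands; annotated introns are
    at least the 25 nt splicing floor and carry splice-site dinucleotides
    drawn per ``motif_fractions`` (GT-AG, GC-AG, AT-AC; remainder
    non-canonical).  A CDS spanning the gene interior leaves UTR at both
    ends.  Fully deterministic under ``seed``.

    Returns ``(genome, genes, intron_motifs, motif_counts)`` where
    ``intron_motifs[gene_id][i]`` is the class planted for intron i.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if exon_len[0] < 100:
        raise ValueError("exons shorter than 100 nt cannot host the read layout")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    layout: list[tuple[str, list[Interval], str]] = []
    pos = int(rng.integers(*intergenic_gap))
    for i in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[Interval] = []
        for k in range(n_ex):
            if k:
                pos += int(rng.integers(intron_len[0], intron_len[1] + 1))
            L = int(rng.integers(exon_len[0], exon_len[1] + 1))
            exons.append((pos, pos + L))
            pos += L
        gene_id = f"G{i + 1:05d}"
        layout.append((gene_id, exons, strand))
        pos += int(rng.integers(*intergenic_gap))
    total_len = pos + int(rng.integers(*intergenic_gap))

    seq = rng.choice(np.array(list("ACGT")), size=total_len)
    intron_motifs: dict[str, list[str]] = {}
    motif_counts = {m: 0 for m in _MOTIF_CLASSES}
    p = list(motif_fractions) + [1.0 - sum(motif_fractions)]
    for gene_id, exons, strand in layout:
        introns = [
            (exons[k][1], exons[k + 1][0]) for k in range(len(exons) - 1)
        ]
        classes = [
            _MOTIF_CLASSES[int(c)]
            for c in rng.choice(4, size=len(introns), p=p)
        ]
        intron_motifs[gene_id] = classes
        for iv, cls in zip(introns, classes):
            _plant_intron_motif(seq, iv, cls, strand)
            motif_counts[cls] += 1
        span = (exons[0][0], exons[-1][1])
        cds = (
            (exons[0][0] + min(40, (exons[0][1] - exons[0][0]) // 2),
             exons[-1][1] - min(40, (exons[-1][1] - exons[-1][0]) // 2))
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                cds_span=cds,
            )
        )
    genome = {chrom: "".join(seq.tolist())}
    return genome, genes, intron_motifs, motif_counts


# ---------------------------------------------------------------------------
# event planning


def _plan_event(
    gene: GeneModel,
    etype: str,
    alt_fraction: float,
    samples: tuple[str, ...],
    rng: np.random.Generator,
    seq: np.ndarray,
) -> TruthRecord:
    introns = gene.annotated_introns
    if etype in ("Alt5", "Alt3"):
        iv = introns[int(rng.integers(len(introns)))]
        shift = int(rng.integers(4, 13))
        # shift the type-appropriate boundary inward (into the intron)
        donor_side = (etype == "Alt5")
        shift_start = donor_side if gene.strand == "+" else not donor_side
        if shift_start:
            alt = (iv[0] + shift, iv[1])
            d, _ = _SENSE_DINUCS[("GT-AG", gene.strand)]
            _plant(seq, alt[0], d)
        else:
            alt = (iv[0], iv[1] - shift)
            _, a = _SENSE_DINUCS[("GT-AG", gene.strand)]
            _plant(seq, alt[1] - 2, a)
        return TruthRecord(gene.gene_id, etype, alt, (iv,), alt_fraction,
                           samples, shift_distance=shift)
    if etype == "ES":
        m = int(rng.integers(1, gene.n_exons - 1))  # interior exon index
        alt = (introns[m - 1][0], introns[m][1])
        return TruthRecord(gene.gene_id, "ES", alt,
                           (introns[m - 1], introns[m]), alt_fraction, samples)
    if etype == "IR":
        iv = introns[int(rng.integers(len(introns)))]
        return TruthRecord(gene.gene_id, "IR", iv, (iv,), alt_fraction, samples)
    if etype in ("IRc", "Antisense"):
        # inner junction strictly inside the widest exon
        exon = max(gene.exons, key=lambda x: x[1] - x[0])
        ilen = int(rng.integers(30, 46))
        margin_max = (exon[1] - exon[0]) - ilen - 10
        x = exon[0] + int(rng.integers(10, margin_max + 1))
        alt = (x, x + ilen)
        cls_strand = gene.strand
        if etype == "Antisense":
            cls_strand = "-" if gene.strand == "+" else "+"
        _plant_intron_motif(seq, alt, "GT-AG", cls_strand)
        return TruthRecord(gene.gene_id, etype, alt, (alt,), alt_fraction, samples)
    raise ValueError(f"unknown event type {etype!r}")


# ---------------------------------------------------------------------------
# read simulation


def _spliced_read(
    chrom: str, junction: Interval, o: int, read_len: int,
    read_id: str, sample: str,
) -> AlignmentRecord:
    s, e = junction
    return AlignmentRecord(
        read_id=read_id,
        chrom=chrom,
        strand_of_alignment="+",
        blocks=((s - o, s), (e, e + read_len - o)),
        mismatches=0,
        is_unique=True,
        sample_id=sample,
    )


def simulate_reads(
    genome: dict[str, str],
    genes: Sequence[GeneModel],
    truth: Sequence[TruthRecord],
    coverage: int = 30,
    read_len: int = 85,
    n_samples: int = 10,
    seed: int = 0,
    exon_coverage: int | None = None,
) -> dict[str, list[AlignmentRecord]]:
    """Simulate already-aligned reads for every sample.

    Every sample gets ``coverage`` spliced reads per annotated intron and
    exon-tiling unspliced reads at ``exon_coverage`` (default ``coverage``);
    each truth record additionally gets ``round(fraction * coverage)``
    alternative reads, in its planted samples only.  Truth records are
    updated in place with the exact per-sample expected AER derived from the
    planted read layout.
    """
    if read_len < 16:
        warnings.warn(
            f"read_len={read_len} cannot guarantee junction overhang >= 8",
            stacklevel=2,
        )
    exon_cov = coverage if exon_coverage is None else exon_coverage
    rng = np.random.default_rng(seed)
    samples = [f"s{i + 1:02d}" for i in range(n_samples)]
    truth_by_gene: dict[str, list[TruthRecord]] = {}
    for t in truth:
        truth_by_gene.setdefault(t.gene_id, []).append(t)

    reads_by_sample: dict[str, list[AlignmentRecord]] = {s: [] for s in samples}
    o_lo = min(8, max(1, read_len // 2))  # degenerate read lengths: clamp
    o_hi = max(o_lo, read_len - o_lo)
    for gene in genes:
        chrom = gene.chrom
        for sample in samples:
            out = reads_by_sample[sample]
            gene_blocks: list[Interval] = []
            serial = 0

            def emit(rec: AlignmentRecord) -> None:
                out.append(rec)
                gene_blocks.extend(rec.blocks)

            # constitutive spliced reads over every annotated intron
            for iv in gene.annotated_introns:
                for _ in range(coverage):
                    o = int(rng.integers(o_lo, o_hi + 1))
                    serial += 1
                    emit(_spliced_read(
                        chrom, iv, o, read_len,
                        f"{gene.gene_id}:c:{serial}:{sample}", sample,
                    ))
            # exon-tiling unspliced reads
            for x0, x1 in gene.exons:
                rl = min(read_len, x1 - x0)
                n_tiles = max(1, round((x1 - x0) * exon_cov / rl))
                starts = rng.integers(x0, x1 - rl + 1, size=n_tiles)
                for st in sorted(starts.tolist()):
                    serial += 1
                    emit(AlignmentRecord(
                        read_id=f"{gene.gene_id}:x:{serial}:{sample}",
                        chrom=chrom, strand_of_alignment="+",
                        blocks=((st, st + rl),), sample_id=sample,
                    ))
            # planted alternative evidence
            for t in truth_by_gene.get(gene.gene_id, []):
                if sample not in t.planted_samples:
                    continue
                n_alt = max(1, round(t.planted_alt_fraction * coverage))
                if t.event_type == "IR":
                    s, e = t.alt_interval
                    L = e - s
                    n_ir = max(
                        2,
                        round(t.planted_alt_fraction * coverage
                              * (L + read_len) / read_len),
                        (L // (read_len - 1)) + 2,
                    )
                    starts = np.linspace(
                        s - read_len // 2, e - read_len // 2, n_ir
                    ).round().astype(int)
                    for st in starts.tolist():
                        serial += 1
                        emit(AlignmentRecord(
                            read_id=f"{gene.gene_id}:a:{serial}:{sample}",
                            chrom=chrom, strand_of_alignment="+",
                            blocks=((st, st + read_len),), sample_id=sample,
                        ))
                else:
                    for _ in range(n_alt):
                        o = int(rng.integers(o_lo, o_hi + 1))
                        serial += 1
                        emit(_spliced_read(
                            chrom, t.alt_interval, o, read_len,
                            f"{gene.gene_id}:a:{serial}:{sample}", sample,
                        ))

            # exact per-sample expectations from the planted layout
            for t in truth_by_gene.get(gene.gene_id, []):
                if sample not in t.planted_samples:
                    continue
                n_alt = max(1, round(t.planted_alt_fraction * coverage))
                if t.event_type == "IR":
                    s, e = t.alt_interval
                    d = coverage_array(gene_blocks, s, e)
                    exp = float(np.median(d)) / coverage
                elif t.event_type == "IRc":
                    # alt reads splice the interval out, so they add no depth
                    s, e = t.alt_interval
                    med = float(np.median(coverage_array(gene_blocks, s, e)))
                    exp = n_alt / med
                elif t.event_type == "ES":
                    exp = n_alt / (2.0 * coverage)
                else:  # Alt5 / Alt3 / Antisense
                    exp = n_alt / float(coverage)
                t.expected_aer_by_sample[sample] = exp
                if t.planted_samples and sample == t.planted_samples[0]:
                    t.expected_aer = exp
    for sample in samples:
        reads_by_sample[sample].sort(key=lambda r: (r.chrom, r.span[0], r.read_id))
    return reads_by_sample


def make_scenario(
    n_genes: int = 50,
    coverage: int = 30,
    alt_fraction: float = 0.2,
    n_samples: int = 3,
    seed: int = 0,
    read_len: int = 85,
    exons_per_gene: tuple[int, int] = (3, 7),
    motif_fractions: Sequence[float] = DEFAULT_MOTIF_FRACTIONS,
    constitutive_fraction: float = 0.25,
    event_types: Sequence[str] = EVENT_CYCLE,
    sample_subsets: Callable[[int, list[str]], Sequence[str]] | None = None,
) -> Scenario:
    """Generate a complete planted-event study.

    Roughly ``constitutive_fraction`` of genes stay constitutive-only
    (negative controls); the rest receive one event each, cycling through
    ``event_types``.  ``sample_subsets(event_index, samples)`` can restrict
    each event to a subset of libraries (default: planted in all).
    """
    rng = np.random.default_rng(seed)
    genome, genes, intron_motifs, motif_counts = make_genome_and_genes(
        n_genes,
        exons_per_gene=exons_per_gene,
        seed=int(rng.integers(2**31)),
        motif_fractions=motif_fractions,
    )
    chrom = genes[0].chrom
    seq = np.array(list(genome[chrom]))
    samples = [f"s{i + 1:02d}" for i in range(n_samples)]
    truth: list[TruthRecord] = []
    n_const = round(constitutive_fraction * n_genes)
    ei = 0
    for gi, gene in enumerate(genes):
        if gi < n_const or gene.n_exons < 3:
            continue  # constitutive-only control
        etype = event_types[ei % len(event_types)]
        subset = tuple(
            sample_subsets(ei, samples) if sample_subsets else samples
        )
        truth.append(
            _plan_event(gene, etype, alt_fraction, subset, rng, seq)
        )
        ei += 1
    genome = {chrom: "".join(seq.tolist())}
    reads = simulate_reads(
        genome, genes, truth,
        coverage=coverage, read_len=read_len, n_samples=n_samples,
        seed=int(rng.integers(2**31)),
    )
    return Scenario(
        genome=genome, genes=genes, truth=truth, reads_by_sample=reads,
        motif_counts=motif_counts, intron_motifs=intron_motifs,
        seed=seed, coverage=coverage, read_len=read_len,
    )


# ---------------------------------------------------------------------------
# file writers (text formats only)


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            s = genome[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """1-based closed GFF3 with gene/mRNA/exon/CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.span)):
            s, e = g.span
            fh.write(
                f"{g.chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (x0, x1) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{x0 + 1}\t{x1}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
                if g.cds_span is not None:
                    c0 = max(x0, g.cds_span[0])
                    c1 = min(x1, g.cds_span[1])
                    if c1 > c0:
                        fh.write(
                            f"{g.chrom}\tsim\tCDS\t{c0 + 1}\t{c1}\t.\t"
                            f"{g.strand}\t0\tID={mrna}.cds{i};Parent={mrna}\n"
                        )


def _cigar_of(blocks: Sequence[Interval]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def write_sam(
    records: Sequence[AlignmentRecord],
    genome: dict[str, str],
    path: str | Path,
) -> None:
    """Plain-text SAM with NM/NH tags; sequence and qualities omitted."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom in sorted(genome):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(genome[chrom])}\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.span[0], r.read_id)):
            flag = 16 if r.strand_of_alignment == "-" else 0
            fh.write(
                "\t".join(
                    [
                        r.read_id,
                        str(flag),
                        r.chrom,
                        str(r.blocks[0][0] + 1),
                        "60",
                        _cigar_of(r.blocks),
                        "*", "0", "0", "*", "*",
                        f"NM:i:{r.mismatches}",
                        "NH:i:1" if r.is_unique else "NH:i:2",
                    ]
                )
                + "\n"
            )


TRUTH_COLUMNS = [
    "gene_id", "event_type", "alt_start", "alt_end", "const_starts",
    "const_ends", "planted_alt_fraction", "planted_samples",
    "expected_aer", "shift_distance",
]


def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TRUTH_COLUMNS) + "\n")
        for t in sorted(truth, key=lambda t: t.key):
            fh.write(
                "\t".join(
                    [
                        t.gene_id,
                        t.event_type,
                        str(t.alt_interval[0]),
                        str(t.alt_interval[1]),
                        ",".join(str(s) for s, _ in t.const_intervals),
                        ",".join(str(e) for _, e in t.const_intervals),
                        repr(t.planted_alt_fraction),
                        ",".join(t.planted_samples),
                        repr(float(t.expected_aer)),
                        "" if t.shift_distance is None else str(t.shift_distance),
                    ]
                )
                + "\n"
            )


def write_scenario(scenario: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Write a scenario as FASTA + GFF3 + one SAM per sample + truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fa",
        "gff3": out_dir / "genes.gff3",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(scenario.genome, paths["genome"])
    write_gff3(scenario.genes, paths["gff3"])
    write_truth(scenario.truth, paths["truth"])
    for sample in scenario.sample_ids:
        p = out_dir / f"{sample}.sam"
        write_sam(scenario.reads_by_sample[sample], scenario.genome, p)
        paths[sample] = p
    return paths


# ---------------------------------------------------------------------------
# hand-built boundary fixtures


@dataclass
class EdgeCase:
    """One deterministic hand-built scenario with its expected outcome."""

    name: str
    genome: dict[str, str]
    genes: list[GeneModel]
    records: list[AlignmentRecord]
    expect: dict


def _reads(chrom: str, blocks: Interval | Sequence[Interval], n: int,
           prefix: str, mismatches: int = 0, unique: bool = True,
           sample: str = "e1") -> list[AlignmentRecord]:
    if isinstance(blocks[0], int):
        blocks = (blocks,)
    return [
        AlignmentRecord(
            read_id=f"{prefix}.{i}", chrom=chrom, strand_of_alignment="+",
            blocks=tuple(tuple(b) for b in blocks), mismatches=mismatches,
            is_unique=unique, sample_id=sample,
        )
        for i in range(n)
    ]


def edge_case_suite() -> dict[str, EdgeCase]:
    """Named deterministic fixtures probing every filter and detector
    boundary: overhang 8 vs 7, intron 25 vs 24, mismatches 8 vs 9, abutting
    and two-gene TUs, antisense and cryptic-intron junctions, an even-length
    intron-retention depth median, and AER values exactly 0.05 and 1.0."""
    cases: dict[str, EdgeCase] = {}

    def seq(n: int, plants: dict[int, str] | None = None) -> str:
        s = np.full(n, "A")
        for pos, dinuc in (plants or {}).items():
            _plant(s, pos, dinuc)
        return "".join(s.tolist())

    # -- overhang boundary: shorter end 8 kept, 7 rejected
    g = GeneModel("EG1", "ce1", "+", ((0, 100), (160, 260)))
    recs = (
        _reads("ce1", ((92, 100), (160, 237)), 1, "keep8")   # overhang 8
        + _reads("ce1", ((93, 100), (160, 238)), 1, "drop7")  # overhang 7
    )
    cases["overhang"] = EdgeCase(
        "overhang", {"ce1": seq(400)}, [g], recs,
        {"junction": ("ce1", 100, 160), "support": 1},
    )

    # -- minimum intron length: gap 25 is a junction, 24 is not
    g1 = GeneModel("EG2a", "ce2", "+", ((0, 100), (125, 225)))
    g2 = GeneModel("EG2b", "ce2", "+", ((300, 400), (424, 524)))
    recs = (
        _reads("ce2", ((80, 100), (125, 190)), 1, "in25")
        + _reads("ce2", ((380, 400), (424, 489)), 1, "in24")
    )
    cases["intron_length"] = EdgeCase(
        "intron_length", {"ce2": seq(600)}, [g1, g2], recs,
        {"kept": ("ce2", 100, 125), "rejected": ("ce2", 400, 424)},
    )

    # -- mismatch cap: NM 8 kept, NM 9 rejected
    g = GeneModel("EG3", "ce3", "+", ((0, 100), (160, 260)))
    recs = (
        _reads("ce3", ((80, 100), (160, 225)), 1, "nm8", mismatches=8)
        + _reads("ce3", ((81, 100), (160, 226)), 1, "nm9", mismatches=9)
    )
    cases["mismatches"] = EdgeCase(
        "mismatches", {"ce3": seq(400)}, [g], recs,
        {"junction": ("ce3", 100, 160), "support": 1},
    )

    # -- multi-mapping: unique kept, multi-mapped rejected
    g = GeneModel("EG4", "ce4", "+", ((0, 100), (160, 260)))
    recs = (
        _reads("ce4", ((80, 100), (160, 225)), 1, "uniq")
        + _reads("ce4", ((81, 100), (160, 226)), 1, "multi", unique=False)
    )
    cases["uniqueness"] = EdgeCase(
        "uniqueness", {"ce4": seq(400)}, [g], recs,
        {"junction": ("ce4", 100, 160), "support": 1},
    )

    # -- abutting reads share no base: two TUs
    recs = _reads("ce5", (0, 100), 1, "left") + _reads("ce5", (100, 200), 1, "right")
    cases["abutting_tus"] = EdgeCase(
        "abutting_tus", {"ce5": seq(300)}, [], recs, {"n_tus": 2},
    )

    # -- a TU spanning two genes is dropped as ambiguous
    g1 = GeneModel("EG6a", "ce6", "+", ((0, 200),))
    g2 = GeneModel("EG6b", "ce6", "+", ((300, 500),))
    recs = _reads("ce6", (150, 350), 1, "bridge") + _reads("ce6", (10, 110), 1, "inA")
    cases["two_gene_tu"] = EdgeCase(
        "two_gene_tu", {"ce6": seq(600)}, [g1, g2], recs,
        {"n_retained": 1, "retained_gene": "EG6a"},
    )

    # -- antisense-motif junction inside a plus-strand gene
    g = GeneModel("EG7", "ce7", "+", ((0, 150), (210, 360)))
    plants = {150: "GT", 208: "AG", 240: "CT", 278: "AC"}
    recs = (
        _reads("ce7", ((130, 150), (210, 275)), 10, "sense")
        + _reads("ce7", ((220, 240), (280, 345)), 2, "anti")
    )
    cases["antisense"] = EdgeCase(
        "antisense", {"ce7": seq(500, plants)}, [g], recs,
        {"event_type": "Antisense", "alt_interval": (240, 280), "aer": 0.2},
    )

    # -- cryptic intron: novel junction strictly inside one exon
    g = GeneModel("EG8", "ce8", "+", ((0, 150), (210, 360)))
    plants = {150: "GT", 208: "AG", 240: "GT", 278: "AG"}
    recs = (
        _reads("ce8", ((130, 150), (210, 235)), 10, "sense")
        + _reads("ce8", ((220, 240), (280, 345)), 2, "alt")
        + _reads("ce8", (230, 300), 4, "depth")
    )
    cases["irc"] = EdgeCase(
        "irc", {"ce8": seq(500, plants)}, [g], recs,
        {"event_type": "IRc", "alt_interval": (240, 280), "aer": 0.5},
    )

    # -- intron retention with an even-length depth median
    g = GeneModel("EG9", "ce9", "+", ((0, 150), (176, 326)))
    recs = (
        _reads("ce9", ((130, 150), (176, 241)), 6, "sj")
        + _reads("ce9", (140, 186), 2, "full")   # whole intron at depth 2
        + _reads("ce9", (140, 163), 2, "half")   # first 13 bases to depth 4
    )
    cases["ir_even_median"] = EdgeCase(
        "ir_even_median", {"ce9": seq(400)}, [g], recs,
        {"event_type": "IR", "alt_interval": (150, 176),
         "alt_support": 3.0, "aer": 0.5},
    )

    # -- AER exactly 0.05 and exactly 1.0
    gP = GeneModel("EG10a", "cea", "+", ((0, 150), (210, 360)))
    gQ = GeneModel("EG10b", "cea", "+", ((500, 650), (710, 860)))
    recs = (
        _reads("cea", ((130, 150), (210, 275)), 20, "Pc")
        + _reads("cea", ((130, 150), (200, 265)), 1, "Pa")   # (150,200), shift 10
        + _reads("cea", ((630, 650), (710, 775)), 20, "Qc")
        + _reads("cea", ((630, 650), (700, 765)), 20, "Qa")  # (650,700), shift 10
    )
    cases["aer_boundary"] = EdgeCase(
        "aer_boundary", {"cea": seq(1000)}, [gP, gQ], recs,
        {"aers": {("EG10a", (150, 200)): 0.05, ("EG10b", (650, 700)): 1.0}},
    )
    return cases
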