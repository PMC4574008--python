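"""Readers and writers for the standard formats the pipeline touches.

All coordinates are 0-based half-open internally; conversion to the 1-based
closed convention of GFF3 and SAM happens only at file boundaries.  Gene
models read from GFF3 are collapsed to a single union-exon model per locus,
so every downstream comparison is against one reference splicing pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gffutils
import pysam

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class GFF3ParseError(ValueError):
    """Raised for a malformed GFF3 line; message names the line number."""


class GeneModelValidationError(ValueError):
    """Raised when a gene's features are internally inconsistent."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One read alignment reduced to its genomic blocks plus QC fields.

    ``blocks`` are 0-based half-open intervals of reference positions covered
    by aligned bases (deletions are absorbed into the enclosing block; only N
    gaps split blocks).  Gaps between consecutive blocks are candidate
    introns.
    """

    read_id: str
    chrom: str
    strand_of_alignment: str  # '+' or '-'
    blocks: tuple[Interval, ...]
    mismatches: int = 0
    is_unique: bool = True
    xs_strand: str = "unknown"  # transcription strand tag, if the aligner set one
    sample_id: str = ""

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.blocks:
            if end - start < 1:
                raise ValueError(f"{self.read_id}: zero-length block ({start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.read_id}: blocks overlap or are unsorted")
            prev_end = end

    @property
    def span(self) -> Interval:
        """Full genomic extent, introns included."""
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def gaps(self) -> tuple[Interval, ...]:
        """Inter-block gaps (candidate introns), 0-based half-open."""
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class GeneModel:
    """A gene collapsed to one ordered exon chain with an optional CDS span.

    ``annotated_introns`` are the gaps between consecutive exons.  Exonic
    sequence outside ``cds_span`` is UTR.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[Interval, ...]
    cds_span: Optional[Interval] = None

    def __post_init__(self) -> None:
        exons = tuple(sorted(tuple(e) for e in self.exons))
        prev_end = None
        for start, end in exons:
            if end <= start:
                raise GeneModelValidationError(
                    f"{self.gene_id}: empty exon ({start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise GeneModelValidationError(
                    f"{self.gene_id}: overlapping exons"
                )
            prev_end = end
        self.exons = exons
        if self.cds_span is not None:
            c0, c1 = self.cds_span
            g0, g1 = self.span
            if not (g0 <= c0 < c1 <= g1):
                raise GeneModelValidationError(
                    f"{self.gene_id}: CDS {self.cds_span} outside gene span {self.span}"
                )

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def annotated_introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def coding_class(self, pos: int) -> str:
        """'CDS' if ``pos`` lies inside the coding span, else 'UTR'."""
        if self.cds_span is not None and self.cds_span[0] <= pos < self.cds_span[1]:
            return "CDS"
        return "UTR"

    def utr_regions(self) -> list[Interval]:
        """Exonic intervals outside the CDS span."""
        if self.cds_span is None:
            return list(self.exons)
        c0, c1 = self.cds_span
        out: list[Interval] = []
        for s, e in self.exons:
            if s < c0:
                out.append((s, min(e, c0)))
            if e > c1:
                out.append((max(s, c1), e))
        return out


def _merge_intervals(ivs: Iterable[Interval]) -> tuple[Interval, ...]:
    ivs = sorted(ivs)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _prevalidate_gff3(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"{path}: malformed GFF3 line {lineno}: expected 9 fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GFF3ParseError(
                    f"{path}: malformed GFF3 line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GFF3ParseError(
                    f"{path}: malformed GFF3 line {lineno}: bad interval {start}-{end}"
                )


def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Load gene models from a GFF3 file, one union-exon model per gene.

    Multi-isoform loci are collapsed to the union of all annotated exons and
    the overall extent of all CDS features; this yields the least-assuming
    single reference splicing pattern per locus.  GFF3 1-based closed
    coordinates are converted to 0-based half-open.
    """
    gff3_path = Path(gff3_path)
    _prevalidate_gff3(gff3_path)
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    n_collapsed = 0
    for gene in db.features_of_type("gene", order_by="start"):
        exon_ivs = [
            (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
        ]
        if not exon_ivs:
            # annotation without exon features: use the gene body
            exon_ivs = [(gene.start - 1, gene.end)]
        gene_iv = (gene.start - 1, gene.end)
        for s, e in exon_ivs:
            if s < gene_iv[0] or e > gene_iv[1]:
                raise GeneModelValidationError(
                    f"{gene.id}: exon ({s},{e}) outside gene span {gene_iv}"
                )
        merged = _merge_intervals(exon_ivs)
        if len(merged) != len(exon_ivs):
            n_collapsed += 1
        cds_ivs = [
            (f.start - 1, f.end) for f in db.children(gene, featuretype="CDS")
        ]
        cds_span = (
            (min(s for s, _ in cds_ivs), max(e for _, e in cds_ivs))
            if cds_ivs
            else None
        )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=merged,
                cds_span=cds_span,
            )
        )
    if n_collapsed:
        logger.info("collapsed %d multi-isoform loci to union-exon models", n_collapsed)
    return genes


# CIGAR operations: which consume reference, and which close a block.
_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X
_BLOCK_SPLITTING = {3}  # N
_NO_REF = {1, 4, 5, 6}  # I, S, H, P
_KNOWN_OPS = _REF_CONSUMING | _BLOCK_SPLITTING | _NO_REF


def blocks_from_cigar(pos: int, cigartuples: Sequence[tuple[int, int]]) -> tuple[Interval, ...]:
    """Genomic blocks of an alignment starting at 0-based ``pos``.

    M/=/X and D extend the current block's genomic footprint; N closes the
    block and opens the next; I/S/H/P consume no reference.
    """
    blocks: list[Interval] = []
    cur_start = pos
    cur = pos
    for op, length in cigartuples:
        if op in _REF_CONSUMING:
            cur += length
        elif op in _BLOCK_SPLITTING:
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur += length
            cur_start = cur
        elif op in _NO_REF:
            pass
        else:
            raise ValueError(f"unknown CIGAR operation code {op}")
    if cur > cur_start:
        blocks.append((cur_start, cur))
    if not blocks:
        raise ValueError("CIGAR produced no aligned blocks")
    return tuple(blocks)


@dataclass
class UniquenessRule:
    """How to decide whether an alignment is uniquely mapped.

    If a hit-count tag (``NH``) is present, unique means NH == 1.  Otherwise
    the record is unique when MAPQ exceeds ``mapq_multi_sentinel`` (aligners
    reserve small MAPQ values for multi-mapping reads).
    """

    nh_tag: str = "NH"
    mapq_multi_sentinel: int = 3

    def is_unique(self, read: "pysam.AlignedSegment") -> bool:
        if read.is_secondary or read.is_supplementary:
            return False
        if read.has_tag(self.nh_tag):
            return int(read.get_tag(self.nh_tag)) == 1
        return read.mapping_quality > self.mapq_multi_sentinel


def read_alignments(
    sam_path: str | Path,
    sample_id: str,
    uniqueness: UniquenessRule | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM/BAM file.

    Records without a CIGAR (unmapped or malformed) are skipped and counted
    in the log.  Mismatches come from the NM tag when present, else 0.
    """
    uniqueness = uniqueness or UniquenessRule()
    n_skipped = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.cigartuples is None:
                n_skipped += 1
                continue
            blocks = blocks_from_cigar(read.reference_start, read.cigartuples)
            nm = int(read.get_tag("NM")) if read.has_tag("NM") else 0
            xs = str(read.get_tag("XS")) if read.has_tag("XS") else "unknown"
            yield AlignmentRecord(
                read_id=read.query_name,
                chrom=read.reference_name,
                strand_of_alignment="-" if read.is_reverse else "+",
                blocks=blocks,
                mismatches=nm,
                is_unique=uniqueness.is_unique(read),
                xs_strand=xs if xs in "+-" else "unknown",
                sample_id=sample_id,
            )
    if n_skipped:
        logger.info("%s: skipped %d records without CIGAR", sam_path, n_skipped)


# ---------------------------------------------------------------------------
# Event table

EVENT_TABLE_COLUMNS = [
    "gene_id",
    "chrom",
    "strand",
    "event_type",
    "alt_start",
    "alt_end",
    "const_start",
    "const_end",
    "alt_support",
    "const_support",
    "aer",
    "shift_distance",
    "in_frame",
    "samples",
    "n_samples",
]


def _fmt_support(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def write_event_table(events: Sequence, path: str | Path) -> None:
    """Write finalized events as a tab-delimited table.

    The first row begins with '#' and holds the column labels; coordinates
    are emitted 1-based closed for human readability (stated in the header).
    Multi-part constitutive intervals (exon skipping) are comma-joined,
    position-aligned between const_start and const_end.
    """
    with open(path, "w") as fh:
        fh.write("## coordinates: 1-based, closed\n")
        fh.write("#" + "\t".join(EVENT_TABLE_COLUMNS) + "\n")
        for ev in sorted(
            events, key=lambda e: (e.chrom, e.gene_id, e.event_type, e.alt_interval)
        ):
            a0, a1 = ev.alt_interval
            row = [
                ev.gene_id,
                ev.chrom,
                ev.strand,
                ev.event_type,
                str(a0 + 1),
                str(a1),
                ",".join(str(s + 1) for s, _ in ev.const_intervals),
                ",".join(str(e) for _, e in ev.const_intervals),
                _fmt_support(ev.alt_support),
                _fmt_support(ev.const_support),
                repr(float(ev.aer)),
                "" if ev.shift_distance is None else str(ev.shift_distance),
                "" if ev.in_frame is None else str(int(ev.in_frame)),
                ",".join(sorted(ev.sample_ids)),
                str(len(ev.sample_ids)),
            ]
            fh.write("\t".join(row) + "\n")


def read_event_table(path: str | Path) -> list:
    """Re-read a table written by :func:`write_event_table`."""
    from .as_detector import ASEvent  # local import: avoids a cycle

    events = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = dict(zip(EVENT_TABLE_COLUMNS, line.split("\t")))
            starts = [int(x) - 1 for x in f["const_start"].split(",") if x]
            ends = [int(x) for x in f["const_end"].split(",") if x]
            events.append(
                ASEvent(
                    gene_id=f["gene_id"],
                    chrom=f["chrom"],
                    strand=f["strand"],
                    event_type=f["event_type"],
                    alt_interval=(int(f["alt_start"]) - 1, int(f["alt_end"])),
                    const_intervals=tuple(zip(starts, ends)),
                    alt_support=float(f["alt_support"]),
                    const_support=float(f["const_support"]),
                    aer=float(f["aer"]),
                    sample_ids=frozenset(
                        s for s in f["samples"].split(",") if s
                    ),
                    shift_distance=(
                        int(f["shift_distance"]) if f["shift_distance"] else None
                    ),
                    in_frame=bool(int(f["in_frame"])) if f["in_frame"] else None,
                )
            )
    return events


def read_genome(fasta_path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a dict of uppercase contig strings."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}
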