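"""Transcriptional-unit construction and single-gene assignment.

A transcriptional unit (TU) is a maximal group of overlapping read
alignments — a connected component of the overlap graph over the alignments'
full genomic extents (introns included, so one spliced read cannot sit in
two TUs).  Only TUs unambiguously tied to exactly one gene are kept for
event calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .formats_io import AlignmentRecord, GeneModel, Interval
from .junctions import build_gene_tree

logger = logging.getLogger(__name__)


class UnsortedInputError(ValueError):
    """Input alignments must be sorted by (chrom, start)."""


@dataclass
class TranscriptionalUnit:
    chrom: str
    span: Interval
    alignments: list[AlignmentRecord] = field(default_factory=list)
    gene_id: str | None = None
    sample_id: str = ""

    @property
    def read_ids(self) -> set[str]:
        return {a.read_id for a in self.alignments}


@dataclass
class AssignmentStats:
    n_tus: int = 0
    n_retained: int = 0
    n_intergenic: int = 0
    n_multi_gene: int = 0


def build_tus(alignments: Iterable[AlignmentRecord]) -> list[TranscriptionalUnit]:
    """Sweep-line grouping of sorted alignments into TUs.

    On input sorted by (chrom, start) a single linear pass finds the
    connected components of the overlap graph: a new alignment starts a new
    TU exactly when its start is at or beyond the current TU's running end
    (half-open intervals, so abutting reads do not merge).
    """
    tus: list[TranscriptionalUnit] = []
    cur: TranscriptionalUnit | None = None
    prev_key: tuple[str, int] | None = None
    for rec in alignments:
        start, end = rec.span
        key = (rec.chrom, start)
        if prev_key is not None and key < prev_key:
            raise UnsortedInputError(
                "alignments must be sorted by (chrom, start); "
                f"saw {key} after {prev_key} — sort the input first"
            )
        prev_key = key
        if cur is not None and rec.chrom == cur.chrom and start < cur.span[1]:
            cur.alignments.append(rec)
            cur.span = (cur.span[0], max(cur.span[1], end))
        else:
            cur = TranscriptionalUnit(
                chrom=rec.chrom,
                span=(start, end),
                alignments=[rec],
                sample_id=rec.sample_id,
            )
            tus.append(cur)
    return tus


def assign_tus(
    tus: Iterable[TranscriptionalUnit],
    genes: Iterable[GeneModel],
    stats: AssignmentStats | None = None,
) -> list[TranscriptionalUnit]:
    """Keep TUs overlapping exactly one gene; drop intergenic and ambiguous.

    Overlap means >=1 shared base between the TU span and the gene span (no
    flanking slop).  Dropped counts are recorded by reason.
    """
    stats = stats if stats is not None else AssignmentStats()
    trees = build_gene_tree(genes)
    retained: list[TranscriptionalUnit] = []
    for tu in tus:
        stats.n_tus += 1
        tree = trees.get(tu.chrom)
        hits = (
            sorted({iv.data.gene_id for iv in tree.overlap(*tu.span)})
            if tree is not None
            else []
        )
        if len(hits) == 1:
            tu.gene_id = hits[0]
            retained.append(tu)
            stats.n_retained += 1
        elif not hits:
            stats.n_intergenic += 1
        else:
            stats.n_multi_gene += 1
    if stats.n_intergenic or stats.n_multi_gene:
        logger.info(
            "dropped TUs: %d intergenic, %d spanning multiple genes",
            stats.n_intergenic,
            stats.n_multi_gene,
        )
    return retained
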