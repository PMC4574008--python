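"""Local alternative-splicing event detection within single-gene loci.

Six event types are called against the reference gene model, each requiring
read evidence for both the alternative and the constitutive form:

* ``Alt5`` / ``Alt3`` — a novel junction sharing exactly one boundary with a
  supported annotated intron; the shifted boundary decides donor (5') vs
  acceptor (3') given the gene strand.
* ``ES`` — a novel junction joining the start of one annotated intron to the
  end of a later one, skipping >=1 complete annotated exon; every flanking
  annotated intron must itself be supported.
* ``IRc`` (cryptic intron) — a novel junction with both boundaries strictly
  inside one annotated exon.
* ``Antisense`` — a junction whose splice-motif orientation opposes the gene
  strand, with sense transcription evidenced by annotated-junction support.
* ``IR`` (intron retention) — an annotated intron covered at every base
  while its excising junction is also observed; coverage-based, independent
  of the junction taxonomy.

A novel junction yields at most one event, with precedence
Antisense > ES > Alt5/Alt3 > IRc; a junction matching none of the patterns
(e.g. both ends internal to different exons) is left unclassified — the
taxonomy has no bucket for it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable, Optional, Sequence

import numpy as np

from . import aer_metrics
from .formats_io import GeneModel, Interval
from .junctions import SpliceJunction

logger = logging.getLogger(__name__)

EVENT_TYPES = ("ES", "Alt5", "Alt3", "Antisense", "IR", "IRc")


@dataclass(frozen=True)
class ASEvent:
    """One local alternative-splicing event.

    ``alt_interval`` is the alternative intron (for IR, the retained
    annotated intron); ``const_intervals`` the constitutive junction(s) it
    competes with.  Supports are read counts, except the depth-based sides
    of IR (alt = median intronic depth) and IRc (const = median exonic
    depth).
    """

    gene_id: str
    chrom: str
    strand: str
    event_type: str
    alt_interval: Interval
    const_intervals: tuple[Interval, ...]
    alt_support: float
    const_support: float
    aer: float
    sample_ids: frozenset[str] = frozenset()
    shift_distance: Optional[int] = None
    in_frame: Optional[bool] = None

    @property
    def key(self) -> tuple[str, str, Interval]:
        """Cross-sample identity: (gene, type, alternative coordinates)."""
        return (self.gene_id, self.event_type, self.alt_interval)


def _supported_annotated(
    gene: GeneModel, junctions: Sequence[SpliceJunction]
) -> dict[Interval, int]:
    """Support per annotated intron of the gene, from observed junctions."""
    ann = set(gene.annotated_introns)
    out = {iv: 0 for iv in gene.annotated_introns}
    for j in junctions:
        if j.interval in ann:
            out[j.interval] += j.support
    return out


def classify_novel_junction(
    gene: GeneModel, junction: Interval
) -> str:
    """Pattern class of a novel junction's endpoints against the gene model:
    'ES' (both ends match different annotated introns), 'Alt' (exactly one
    end matches), 'IRc' (both ends strictly inside one exon) or
    'unclassified'.  Mutually exclusive by construction: ES needs both ends
    annotated, Alt exactly one."""
    s, e = junction
    starts = {iv[0]: iv for iv in gene.annotated_introns}
    ends = {iv[1]: iv for iv in gene.annotated_introns}
    start_hit = starts.get(s)
    end_hit = ends.get(e)
    if start_hit and end_hit and start_hit != end_hit:
        return "ES"
    if (start_hit is None) != (end_hit is None):
        return "Alt"
    if start_hit is None and end_hit is None:
        for x0, x1 in gene.exons:
            if x0 < s and e < x1:
                return "IRc"
    return "unclassified"


def detect_alt_sites(
    gene: GeneModel,
    junctions: Sequence[SpliceJunction],
    sample_id: str = "",
) -> list[ASEvent]:
    """Alternative 5' donor / 3' acceptor events.

    A novel junction sharing exactly one endpoint with a supported annotated
    intron shifts the other splice site; on the plus strand a shifted intron
    start moves the donor (Alt5) and a shifted end the acceptor (Alt3), and
    the assignment mirrors on the minus strand.  The shift is in-frame when
    divisible by 3.
    """
    ann_support = _supported_annotated(gene, junctions)
    starts = {iv[0]: iv for iv in gene.annotated_introns}
    ends = {iv[1]: iv for iv in gene.annotated_introns}
    events = []
    for j in junctions:
        if j.novelty != "novel" or j.antisense:
            continue
        if classify_novel_junction(gene, j.interval) != "Alt":
            continue
        s, e = j.interval
        if s in starts:
            const = starts[s]
            shifted_is_start = False
            shift = abs(e - const[1])
        else:
            const = ends[e]
            shifted_is_start = True
            shift = abs(s - const[0])
        if ann_support.get(const, 0) <= 0 or shift == 0:
            continue
        donor_shifted = shifted_is_start if gene.strand == "+" else not shifted_is_start
        events.append(
            ASEvent(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                event_type="Alt5" if donor_shifted else "Alt3",
                alt_interval=j.interval,
                const_intervals=(const,),
                alt_support=j.support,
                const_support=ann_support[const],
                aer=aer_metrics.aer_alt(j.support, ann_support[const]),
                sample_ids=frozenset({sample_id or j.sample_id}),
                shift_distance=shift,
                in_frame=(shift % 3 == 0),
            )
        )
    return events


def detect_exon_skipping(
    gene: GeneModel,
    junctions: Sequence[SpliceJunction],
    sample_id: str = "",
) -> list[ASEvent]:
    """Exon-skipping events: a novel junction from one annotated donor to a
    later annotated acceptor excluding >=1 complete exon, with every flanking
    annotated intron supported (the constitutive form must be transcribed).
    Multi-exon skips are allowed."""
    if gene.n_exons < 3:
        return []
    ann_support = _supported_annotated(gene, junctions)
    introns = gene.annotated_introns
    start_idx = {iv[0]: i for i, iv in enumerate(introns)}
    end_idx = {iv[1]: i for i, iv in enumerate(introns)}
    events = []
    for j in junctions:
        if j.novelty != "novel" or j.antisense:
            continue
        s, e = j.interval
        i0 = start_idx.get(s)
        i1 = end_idx.get(e)
        if i0 is None or i1 is None or i1 <= i0:
            continue
        flanking = introns[i0 : i1 + 1]
        if any(ann_support[iv] <= 0 for iv in flanking):
            continue
        events.append(
            ASEvent(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                event_type="ES",
                alt_interval=j.interval,
                const_intervals=tuple(flanking),
                alt_support=j.support,
                const_support=sum(ann_support[iv] for iv in flanking),
                aer=aer_metrics.aer_es(
                    j.support, [ann_support[iv] for iv in flanking]
                ),
                sample_ids=frozenset({sample_id or j.sample_id}),
            )
        )
    return events


def detect_intron_retention(
    gene: GeneModel,
    junctions: Sequence[SpliceJunction],
    depth: np.ndarray,
    min_ir_depth: int = 1,
    sample_id: str = "",
) -> list[ASEvent]:
    """Intron-retention events from per-base coverage over the gene span.

    An annotated intron is retained iff every intronic base reaches
    ``min_ir_depth`` AND the junction excising it is observed in the same
    sample — complete coverage alone could be mis-annotation, not splicing.
    The alternative support is the median per-base depth across the intron.
    """
    ann_support = _supported_annotated(gene, junctions)
    g0, _ = gene.span
    events = []
    for iv in gene.annotated_introns:
        sj = ann_support[iv]
        if sj <= 0:
            continue
        d = depth[iv[0] - g0 : iv[1] - g0]
        if len(d) == 0 or d.min() < min_ir_depth:
            continue
        med = float(median(d.tolist()))
        if med <= 0:
            continue
        events.append(
            ASEvent(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                event_type="IR",
                alt_interval=iv,
                const_intervals=(iv,),
                alt_support=med,
                const_support=sj,
                aer=aer_metrics.aer_ir(d.tolist(), sj),
                sample_ids=frozenset({sample_id}),
            )
        )
    return events


def detect_cryptic_intron(
    gene: GeneModel,
    junctions: Sequence[SpliceJunction],
    depth: np.ndarray,
    sample_id: str = "",
) -> list[ASEvent]:
    """Cryptic-intron events: a novel junction spliced out entirely within
    one annotated exon (both boundaries strictly interior).  The constitutive
    form is the contiguous exon itself, quantified as the median exonic depth
    over the spliced-out interval."""
    g0, _ = gene.span
    events = []
    for j in junctions:
        if j.novelty != "novel" or j.antisense:
            continue
        if classify_novel_junction(gene, j.interval) != "IRc":
            continue
        d = depth[j.start - g0 : j.end - g0]
        if len(d) == 0:
            continue
        med = float(median(d.tolist()))
        if med <= 0:
            continue
        events.append(
            ASEvent(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                event_type="IRc",
                alt_interval=j.interval,
                const_intervals=(j.interval,),
                alt_support=j.support,
                const_support=med,
                aer=aer_metrics.aer_alt(j.support, med),
                sample_ids=frozenset({sample_id or j.sample_id}),
            )
        )
    return events


def detect_antisense(
    gene: GeneModel,
    junctions: Sequence[SpliceJunction],
    sample_id: str = "",
) -> list[ASEvent]:
    """Antisense junctions: splice-motif orientation opposite to the gene
    strand.  Sense transcription must be evidenced too — the constitutive
    support is the maximum support over the gene's annotated introns."""
    ann_support = _supported_annotated(gene, junctions)
    sense = max(ann_support.values(), default=0)
    if sense <= 0:
        return []
    events = []
    for j in junctions:
        if not j.antisense or j.support <= 0:
            continue
        events.append(
            ASEvent(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                event_type="Antisense",
                alt_interval=j.interval,
                const_intervals=(j.interval,),
                alt_support=j.support,
                const_support=sense,
                aer=aer_metrics.aer_alt(j.support, sense),
                sample_ids=frozenset({sample_id or j.sample_id}),
            )
        )
    return events


@dataclass
class DetectionStats:
    n_unclassified: int = 0


def detect_all(
    gene: GeneModel,
    junctions: Sequence[SpliceJunction],
    depth: np.ndarray,
    min_ir_depth: int = 1,
    sample_id: str = "",
    stats: DetectionStats | None = None,
) -> list[ASEvent]:
    """Run all detectors for one single-gene locus in one sample.

    Junction-derived types obey the precedence Antisense > ES > Alt5/Alt3 >
    IRc, so each junction yields at most one event; IR is coverage-based and
    independent.  ``depth`` must cover the gene span (index 0 = gene start).
    """
    events: list[ASEvent] = []
    claimed: set[Interval] = set()

    for ev in detect_antisense(gene, junctions, sample_id):
        events.append(ev)
        claimed.add(ev.alt_interval)

    remaining = [
        j for j in junctions if j.interval not in claimed and not j.antisense
    ]
    for detector in (detect_exon_skipping, detect_alt_sites):
        for ev in detector(gene, remaining, sample_id):
            if ev.alt_interval not in claimed:
                events.append(ev)
                claimed.add(ev.alt_interval)
        remaining = [j for j in remaining if j.interval not in claimed]
    for ev in detect_cryptic_intron(gene, remaining, depth, sample_id):
        if ev.alt_interval not in claimed:
            events.append(ev)
            claimed.add(ev.alt_interval)

    if stats is not None:
        for j in junctions:
            if (
                j.novelty == "novel"
                and not j.antisense
                and j.interval not in claimed
                and classify_novel_junction(gene, j.interval) == "unclassified"
            ):
                stats.n_unclassified += 1

    events.extend(
        detect_intron_retention(gene, junctions, depth, min_ir_depth, sample_id)
    )
    return events
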