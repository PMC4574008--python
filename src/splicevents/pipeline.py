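"""End-to-end orchestration: alignments in, conserved events and stats out.

One sample flows junction extraction → classification → TU construction →
single-gene assignment → per-gene event detection; a study merges the
per-sample events under the cross-library conservation filter and computes
the downstream summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import aer_metrics, conservation, downstream_stats
from .as_detector import ASEvent, DetectionStats, detect_all
from .coverage import depth_over
from .formats_io import AlignmentRecord, GeneModel
from .junctions import (
    FilterStats,
    SpliceJunction,
    classify_junctions,
    extract_junctions,
)
from .tu_builder import AssignmentStats, assign_tus, build_tus

logger = logging.getLogger(__name__)


@dataclass
class Params:
    """Pipeline thresholds; defaults are the method's standard settings."""

    min_intron: int = 25
    max_mismatches: int = 8
    min_overhang: int = 8
    require_unique: bool = True
    min_samples: int = 3
    min_ir_depth: int = 1
    aer_window: float = 0.05

    def as_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class SampleResult:
    sample_id: str
    junctions: list[SpliceJunction]
    events: list[ASEvent]
    covariates: pd.DataFrame
    filter_stats: FilterStats
    assignment_stats: AssignmentStats
    detection_stats: DetectionStats


def run_sample(
    genome,
    genes: Sequence[GeneModel],
    alignments: Iterable[AlignmentRecord],
    sample_id: str,
    params: Params | None = None,
) -> SampleResult:
    """Process one library: junctions, TUs, events, per-gene covariates.

    Only genes carried by >=1 retained (single-gene) transcriptional unit
    are examined; junction evidence flagged ambiguous between genes is
    excluded from event calling.
    """
    params = params or Params()
    records = sorted(alignments, key=lambda r: (r.chrom, r.span[0], r.read_id))
    fstats = FilterStats()
    jmap = extract_junctions(
        records,
        min_intron=params.min_intron,
        max_mismatches=params.max_mismatches,
        min_overhang=params.min_overhang,
        require_unique=params.require_unique,
        stats=fstats,
    )
    junctions = classify_junctions(jmap.values(), genome, genes)

    astats = AssignmentStats()
    retained = assign_tus(build_tus(records), genes, stats=astats)
    tus_by_gene: dict[str, list] = {}
    for tu in retained:
        tus_by_gene.setdefault(tu.gene_id, []).append(tu)

    junctions_by_gene: dict[str, list[SpliceJunction]] = {}
    for j in junctions:
        if j.gene_id is not None and not j.ambiguous:
            junctions_by_gene.setdefault(j.gene_id, []).append(j)

    dstats = DetectionStats()
    events: list[ASEvent] = []
    cov_rows = []
    for gene in genes:
        tus = tus_by_gene.get(gene.gene_id)
        if not tus:
            continue
        members = [a for tu in tus for a in tu.alignments]
        depth = depth_over(members, *gene.span)
        gene_junctions = sorted(
            junctions_by_gene.get(gene.gene_id, []),
            key=lambda j: (j.start, j.end),
        )
        events.extend(
            detect_all(
                gene,
                gene_junctions,
                depth,
                min_ir_depth=params.min_ir_depth,
                sample_id=sample_id,
                stats=dstats,
            )
        )
        cov_rows.append(
            {
                "gene_id": gene.gene_id,
                "n_exons": gene.n_exons,
                "splicing_reactions": sum(j.support for j in gene_junctions),
                "mean_depth": float(depth.mean()) if len(depth) else 0.0,
            }
        )
    covariates = pd.DataFrame(
        cov_rows, columns=["gene_id", "n_exons", "splicing_reactions", "mean_depth"]
    )
    return SampleResult(
        sample_id=sample_id,
        junctions=junctions,
        events=events,
        covariates=covariates,
        filter_stats=fstats,
        assignment_stats=astats,
        detection_stats=dstats,
    )


@dataclass
class StudyResult:
    per_sample: dict[str, SampleResult]
    merged_events: list[ASEvent]
    all_groups: list[ASEvent]  # merged without the conservation filter
    conservation: pd.DataFrame
    aer_histogram: pd.DataFrame
    aer_strata: dict
    shift_distribution: pd.DataFrame
    inframe_low: downstream_stats.InframeTestResult
    inframe_mid: downstream_stats.InframeTestResult
    per_gene: pd.DataFrame
    gene_globals: dict
    correlations: pd.DataFrame


def run_study(
    genome,
    genes: Sequence[GeneModel],
    reads_by_sample: Mapping[str, Iterable[AlignmentRecord]],
    params: Params | None = None,
) -> StudyResult:
    """Run every sample, merge events under the conservation filter and
    compute the downstream summaries (AER histogram and strata, shift
    distances, in-frame binomial tests, per-gene burden, activity
    correlations)."""
    params = params or Params()
    per_sample = {
        sample: run_sample(genome, genes, reads_by_sample[sample], sample, params)
        for sample in sorted(reads_by_sample)
    }
    events_by_sample = {s: r.events for s, r in per_sample.items()}
    merged = conservation.merge_events(events_by_sample, params.min_samples)
    all_groups = conservation.group_events(events_by_sample)
    cons = conservation.conservation_histogram(all_groups, len(per_sample))
    aer_hist, strata = aer_metrics.bin_aer(merged, window=params.aer_window)
    shift = downstream_stats.shift_distance_distribution(merged)
    inframe_low = downstream_stats.inframe_test(merged, 0.0, 0.1)
    inframe_mid = downstream_stats.inframe_test(merged, 0.1, 1.0)
    per_gene, gene_globals = downstream_stats.per_gene_summary(merged, genes)

    cov = None
    for r in per_sample.values():
        c = r.covariates.set_index("gene_id")
        cov = c if cov is None else cov.add(c, fill_value=0)
    if cov is None or cov.empty:
        correlations = pd.DataFrame(
            columns=["covariate", "pearson_r", "spearman_rho", "undefined"]
        )
    else:
        cov["mean_depth"] /= len(per_sample)
        cov["n_exons"] /= len(per_sample)
        tab = cov.join(
            per_gene.set_index("gene_id")["n_events"], how="left"
        ).fillna({"n_events": 0}).reset_index()
        correlations = downstream_stats.as_activity_correlation(
            tab[["gene_id", "n_events", "splicing_reactions", "n_exons", "mean_depth"]]
        )
    return StudyResult(
        per_sample=per_sample,
        merged_events=merged,
        all_groups=all_groups,
        conservation=cons,
        aer_histogram=aer_hist,
        aer_strata=strata,
        shift_distribution=shift,
        inframe_low=inframe_low,
        inframe_mid=inframe_mid,
        per_gene=per_gene,
        gene_globals=gene_globals,
        correlations=correlations,
    )
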