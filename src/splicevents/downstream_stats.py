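"""Summary statistics over called events.

Covers the shift-distance distribution of alternative donor/acceptor sites,
the reading-frame binomial test within AER strata (a shift divisible by 3
preserves the downstream frame; under random site choice in-frame positions
occur a third of the time), per-gene AS burden, and correlations of AS count
with splicing activity, exon number and expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .as_detector import ASEvent
from .formats_io import GeneModel


def shift_distance_distribution(
    events: Iterable[ASEvent], max_distance: int = 100
) -> pd.DataFrame:
    """Histogram of |splice-site shift| for Alt5/Alt3 events.

    Counts per distance 1..max_distance plus one overflow row; the fraction
    of events within 10 nt is attached as ``attrs['fraction_within_10']``.
    """
    shifts = [
        ev.shift_distance
        for ev in events
        if ev.event_type in ("Alt5", "Alt3") and ev.shift_distance is not None
    ]
    counts = {d: 0 for d in range(1, max_distance + 1)}
    overflow = 0
    for s in shifts:
        if s <= max_distance:
            counts[s] += 1
        else:
            overflow += 1
    rows = [{"distance": d, "count": c} for d, c in counts.items()]
    rows.append({"distance": max_distance + 1, "count": overflow})
    df = pd.DataFrame(rows)
    n = len(shifts)
    df.attrs["n_events"] = n
    df.attrs["fraction_within_10"] = (
        sum(1 for s in shifts if s <= 10) / n if n else float("nan")
    )
    return df


@dataclass(frozen=True)
class InframeTestResult:
    n: int
    k_inframe: int
    proportion: float
    p_value: Optional[float]
    aer_low: float
    aer_high: float
    p0: float


def inframe_test(
    events: Iterable[ASEvent],
    aer_low: float,
    aer_high: float,
    p0: float = 1.0 / 3.0,
    alternative: str = "two-sided",
) -> InframeTestResult:
    """Exact binomial test of in-frame shift prevalence in an AER stratum.

    Takes Alt5/Alt3 events with ``aer_low <= aer < aer_high``, counts those
    whose shift is a multiple of 3, and tests the in-frame proportion
    against ``p0`` (default 1/3, the random expectation over residues mod
    3).  Two-sided p-values sum the probabilities of all outcomes no more
    likely than the observed one.  With no events in the stratum the test is
    undefined and ``p_value`` is None.
    """
    shifts = [
        ev.shift_distance
        for ev in events
        if ev.event_type in ("Alt5", "Alt3")
        and ev.shift_distance is not None
        and aer_low <= ev.aer < aer_high
    ]
    n = len(shifts)
    if n == 0:
        return InframeTestResult(0, 0, float("nan"), None, aer_low, aer_high, p0)
    k = sum(1 for s in shifts if s % 3 == 0)
    p = sps.binomtest(k, n, p0, alternative=alternative).pvalue
    return InframeTestResult(n, k, k / n, float(p), aer_low, aer_high, p0)


def per_gene_summary(
    events: Sequence[ASEvent], genes: Sequence[GeneModel]
) -> tuple[pd.DataFrame, dict]:
    """Per-gene event counts and the global AS-burden fractions.

    The global fraction of alternatively spliced genes uses multi-exonic
    genes (>=2 exons in the union model) as the denominator; single-exon
    genes can host no splicing reaction.  The events-per-gene distribution
    is reported for 1, 2 and 3+ events.
    """
    by_gene: dict[str, dict[str, int]] = {}
    for ev in events:
        d = by_gene.setdefault(ev.gene_id, {t: 0 for t in
                               ("ES", "Alt5", "Alt3", "Antisense", "IR", "IRc")})
        d[ev.event_type] = d.get(ev.event_type, 0) + 1
    rows = []
    for g in genes:
        d = by_gene.get(g.gene_id, {})
        total = sum(d.values())
        rows.append(
            {
                "gene_id": g.gene_id,
                "n_exons": g.n_exons,
                "multi_exonic": g.n_exons >= 2,
                **{f"n_{t.lower()}": d.get(t, 0)
                   for t in ("ES", "Alt5", "Alt3", "Antisense", "IR", "IRc")},
                "n_events": total,
            }
        )
    df = pd.DataFrame(rows)
    multi = df[df["multi_exonic"]]
    n_multi = len(multi)
    n_as = int((multi["n_events"] > 0).sum())
    counts = multi["n_events"]
    global_stats = {
        "n_genes": len(df),
        "n_multi_exonic": n_multi,
        "n_as_genes": n_as,
        "fraction_multi_exonic_with_as": n_as / n_multi if n_multi else float("nan"),
        "n_genes_1_event": int((counts == 1).sum()),
        "n_genes_2_events": int((counts == 2).sum()),
        "n_genes_3plus_events": int((counts >= 3).sum()),
    }
    return df, global_stats


def as_activity_correlation(per_gene: pd.DataFrame) -> pd.DataFrame:
    """Pearson and Spearman correlation of per-gene AS count with each
    covariate column.

    Expects an ``n_events`` column plus covariates such as
    ``splicing_reactions`` (total junction-supporting reads over the gene),
    ``n_exons`` and ``mean_depth`` (expression proxy).  A zero-variance side
    yields NaN coefficients flagged ``undefined``.
    """
    y = per_gene["n_events"].to_numpy(dtype=float)
    rows = []
    covariates = [
        c for c in per_gene.columns
        if c not in ("gene_id", "n_events") and per_gene[c].dtype.kind in "ifb"
    ]
    for cov in covariates:
        x = per_gene[cov].to_numpy(dtype=float)
        undefined = len(y) < 3 or np.std(x) == 0 or np.std(y) == 0
        if undefined:
            pearson = spearman = float("nan")
        else:
            pearson = float(sps.pearsonr(y, x).statistic)
            spearman = float(sps.spearmanr(y, x).statistic)
        rows.append(
            {
                "covariate": cov,
                "pearson_r": pearson,
                "spearman_rho": spearman,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)
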