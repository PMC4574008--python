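"""Alternative Event Ratio (AER): alternative- vs constitutive-form evidence.

The AER quantifies how abundant the alternative form of an event is relative
to its constitutive counterpart, with a per-type formula:

* intron retention — median per-base read depth along the retained intron
  divided by the support of the splice junction that excises it;
* exon skipping — skip-junction support divided by the summed support of the
  skipped constitutive junctions;
* alternative donor/acceptor (and antisense, cryptic intron) — the plain
  ratio of alternative to constitutive support.

Values at or above 1 mean the "alternative" form dominates and are flagged
downstream as likely gene-model errors.
"""

from __future__ import annotations

from statistics import median
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


def aer_ir(intron_depths: Sequence[float], sj_support: float) -> float:
    """Median intron depth over excising-junction support.

    The median of an even-length depth vector is the mean of the two central
    values.
    """
    if len(intron_depths) == 0:
        raise ValueError("intron_depths must be non-empty")
    if sj_support <= 0:
        raise ValueError("an IR event requires junction support >= 1")
    return float(median(intron_depths)) / float(sj_support)


def aer_es(alt_support: float, const_supports: Sequence[float]) -> float:
    """Skip-junction support over the sum of skipped constitutive supports."""
    if len(const_supports) == 0:
        raise ValueError("exon skipping requires >=1 constitutive junction")
    total = float(sum(const_supports))
    if total <= 0:
        raise ValueError("constitutive support must be positive")
    return float(alt_support) / total


def aer_alt(alt_support: float, const_support: float) -> float:
    """Plain alternative/constitutive support ratio (Alt-5', Alt-3',
    antisense, cryptic intron)."""
    if const_support <= 0:
        raise ValueError("constitutive support must be positive")
    return float(alt_support) / float(const_support)


def bin_aer(
    events: Iterable,
    window: float = 0.05,
    cap: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-type AER histogram in half-open windows of ``window`` up to
    ``cap`` plus one overflow bin, and the low-abundance strata counts.

    Returns ``(histogram, strata)`` where histogram rows are
    (event_type, bin_low, bin_high, count, fraction) — fractions within each
    type sum to 1 — and strata holds counts for aer < 0.1, 0.1 <= aer < 1 and
    aer >= 1 plus the overall fraction below 0.1.
    """
    events = list(events)
    n_bins = int(round(cap / window))
    rows = []
    by_type: dict[str, list[float]] = {}
    for ev in events:
        by_type.setdefault(ev.event_type, []).append(float(ev.aer))
    for etype in sorted(by_type):
        aers = np.asarray(by_type[etype])
        n = len(aers)
        idx = np.floor(aers / window).astype(int)
        for k in range(n_bins):
            count = int(np.sum(idx == k))
            rows.append(
                {
                    "event_type": etype,
                    "bin_low": k * window,
                    "bin_high": (k + 1) * window,
                    "count": count,
                    "fraction": count / n,
                }
            )
        overflow = int(np.sum(aers >= cap))
        rows.append(
            {
                "event_type": etype,
                "bin_low": cap,
                "bin_high": float("inf"),
                "count": overflow,
                "fraction": overflow / n,
            }
        )
    all_aers = np.asarray([float(ev.aer) for ev in events])
    n = len(all_aers)
    strata = {
        "n_lt_0.1": int(np.sum(all_aers < 0.1)) if n else 0,
        "n_0.1_to_1": int(np.sum((all_aers >= 0.1) & (all_aers < 1.0))) if n else 0,
        "n_ge_1": int(np.sum(all_aers >= 1.0)) if n else 0,
        "fraction_lt_0.1": float(np.mean(all_aers < 0.1)) if n else 0.0,
    }
    return pd.DataFrame(rows), strata
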