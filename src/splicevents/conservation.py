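"""Cross-sample event merging and the conservation-evidence filter.

Events are matched across samples by exact identity — (gene, event type,
alternative-intron coordinates) — and only events observed in at least
``min_samples`` libraries are kept, which suppresses low-coverage sequencing
and mapping artifacts.  The merged event carries the union of sample ids and
the median of the per-sample AERs.
"""

from __future__ import annotations

from dataclasses import replace
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .as_detector import ASEvent


class ConfigurationError(ValueError):
    pass


def group_events(
    per_sample_events: Mapping[str, Iterable[ASEvent]],
) -> list[ASEvent]:
    """Merge per-sample events by identity key, without any filter.

    Per-sample supports and AERs are summarized by their median across the
    samples carrying the event; sample ids are unioned.  Output order is
    deterministic (sorted by key), so merging is invariant to sample order.
    """
    groups: dict[tuple, list[tuple[str, ASEvent]]] = {}
    for sample in per_sample_events:
        for ev in per_sample_events[sample]:
            groups.setdefault(ev.key, []).append((sample, ev))
    merged = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda t: t[0])
        samples = frozenset(s for s, _ in members)
        evs = [e for _, e in members]
        proto = evs[0]
        merged.append(
            replace(
                proto,
                alt_support=float(median(e.alt_support for e in evs)),
                const_support=float(median(e.const_support for e in evs)),
                aer=float(median(e.aer for e in evs)),
                sample_ids=samples,
            )
        )
    return merged


def merge_events(
    per_sample_events: Mapping[str, Iterable[ASEvent]],
    min_samples: int = 3,
) -> list[ASEvent]:
    """Merged events observed in at least ``min_samples`` libraries."""
    n_samples = len(per_sample_events)
    if min_samples > n_samples:
        raise ConfigurationError(
            f"min_samples={min_samples} exceeds the {n_samples} supplied samples"
        )
    return [
        ev
        for ev in group_events(per_sample_events)
        if len(ev.sample_ids) >= min_samples
    ]


def conservation_histogram(
    merged: Sequence[ASEvent], n_samples: int
) -> pd.DataFrame:
    """Counts and fractions of events per conservation level 1..n_samples,
    plus the mean level (feed the unfiltered :func:`group_events` output to
    see levels below the evidence threshold)."""
    levels = [len(ev.sample_ids) for ev in merged]
    n = len(levels)
    rows = []
    for lvl in range(1, n_samples + 1):
        c = sum(1 for x in levels if x == lvl)
        rows.append(
            {"level": lvl, "count": c, "fraction": c / n if n else 0.0}
        )
    df = pd.DataFrame(rows)
    df.attrs["mean_level"] = sum(levels) / n if n else float("nan")
    df.attrs["n_events"] = n
    return df
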