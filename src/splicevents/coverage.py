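"""Per-base read-depth computation from alignment blocks."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .formats_io import AlignmentRecord, Interval


def coverage_array(
    blocks: Iterable[Interval], start: int, end: int
) -> np.ndarray:
    """Per-base depth over ``[start, end)`` from an iterable of aligned
    blocks (0-based half-open).  Blocks outside the window are clipped."""
    width = end - start
    diff = np.zeros(width + 1, dtype=np.int64)
    for s, e in blocks:
        s = max(s, start)
        e = min(e, end)
        if e > s:
            diff[s - start] += 1
            diff[e - start] -= 1
    return np.cumsum(diff[:-1])


def depth_over(
    alignments: Iterable[AlignmentRecord], start: int, end: int
) -> np.ndarray:
    """Depth over a window from whole alignment records."""
    return coverage_array(
        (b for a in alignments for b in a.blocks), start, end
    )
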