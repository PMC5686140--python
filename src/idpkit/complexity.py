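"""Low-complexity segmentation by windowed compositional entropy.

SEG-style two-threshold segmentation: windows of length W whose Shannon
entropy (bits/position) falls at or below the trigger threshold K1 seed a
segment, which is extended over the maximal run of overlapping windows at
or below the extension threshold K2; overlapping extended runs are merged.
The defaults (W = 12, K1 = 2.2, K2 = 2.5) are the standard settings for
protein low-complexity detection.

The optimal-subsequence refinement step of the original algorithm is not
applied: segment boundaries are those of the trigger/extension windows, so
they may differ from canonical SEG output by a couple of residues at each
end.  Segment counts and approximate locations are stable to this choice.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .exceptions import InputError
from .sequence import ProteinSequence


@dataclass(frozen=True)
class LowComplexitySegment:
    """A low-complexity segment in 1-based inclusive coordinates."""

    start: int
    end: int
    min_window_complexity: float

    def __len__(self) -> int:
        return self.end - self.start + 1

    def to_bed(self, name: str) -> tuple[str, int, int]:
        """(chrom, chromStart, chromEnd) in 0-based half-open convention."""
        return name, self.start - 1, self.end


def window_complexity(window: str) -> float:
    """Shannon entropy of the window's residue composition, bits/position."""
    if not window:
        raise InputError("empty window")
    counts = np.array(list(Counter(window).values()), dtype=float)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def seg_segments(
    seq: ProteinSequence | str,
    window: int = 12,
    trigger: float = 2.2,
    extension: float = 2.5,
) -> list[LowComplexitySegment]:
    """Detect low-complexity segments.

    Parameters
    ----------
    seq : ProteinSequence or str
    window : int
        Trigger window length W.
    trigger : float
        Trigger complexity K1 in bits/position; windows with entropy <= K1
        seed segments.
    extension : float
        Extension complexity K2 >= K1; runs of windows with entropy <= K2
        around a trigger are absorbed into the segment.

    Returns
    -------
    list of LowComplexitySegment, disjoint and sorted by start.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    n = len(residues)
    if extension < trigger:
        raise InputError("extension threshold must be >= trigger threshold")
    if n < window:
        warnings.warn(
            f"sequence length {n} < window {window}: no segments computable",
            stacklevel=2,
        )
        return []

    entropies = np.array(
        [window_complexity(residues[i : i + window]) for i in range(n - window + 1)]
    )
    is_trigger = entropies <= trigger
    is_ext = entropies <= extension

    segments: list[tuple[int, int, float]] = []  # 0-based [start, end] residue spans
    i = 0
    m = len(entropies)
    while i < m:
        if not is_ext[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and is_ext[j + 1]:
            j += 1
        if np.any(is_trigger[i : j + 1]):
            segments.append((i, j + window - 1, float(entropies[i : j + 1].min())))
        i = j + 1

    # merge overlapping/contiguous residue spans
    merged: list[list] = []
    for s, e, h in segments:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = min(merged[-1][2], h)
        else:
            merged.append([s, e, h])

    return [
        LowComplexitySegment(s + 1, e + 1, h) for s, e, h in merged
    ]
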