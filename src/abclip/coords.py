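"""Genome <-> transcript coordinate projection.

Transcript coordinates run 5'->3' along the spliced (mRNA mode) or
unspliced (pre-mRNA mode) transcript, so position 0 is the annotated 5'
end regardless of genomic strand.
"""
from __future__ import annotations

import numpy as np

from .model import TranscriptModel


class TranscriptCoords:
    """Vectorised projection between genomic and transcript coordinates."""

    def __init__(self, model: TranscriptModel, mode: str = "mrna") -> None:
        if not model.exons:
            raise ValueError("transcript without exons")
        if mode not in ("mrna", "premrna"):
            raise ValueError(f"unknown mode {mode!r}")
        self.model = model
        self.mode = mode
        if mode == "premrna":
            blocks = [(model.start, model.end)]
        else:
            blocks = model.exons
        self._starts = np.array([s for s, _ in blocks], dtype=np.int64)
        self._ends = np.array([e for _, e in blocks], dtype=np.int64)
        sizes = self._ends - self._starts
        self._offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.length = int(self._offsets[-1])

    def to_transcript(self, gpos) -> np.ndarray:
        """Project genomic positions; -1 for bases outside the blocks."""
        gpos = np.asarray(gpos, dtype=np.int64)
        idx = np.searchsorted(self._starts, gpos, side="right") - 1
        idx_c = np.clip(idx, 0, len(self._starts) - 1)
        inside = (idx >= 0) & (gpos < self._ends[idx_c])
        plus = self._offsets[idx_c] + (gpos - self._starts[idx_c])
        out = np.where(inside, plus, -1)
        if self.model.strand == "-":
            out = np.where(out >= 0, self.length - 1 - out, -1)
        return out

    def to_genome(self, tpos) -> np.ndarray:
        tpos = np.asarray(tpos, dtype=np.int64)
        if np.any((tpos < 0) | (tpos >= self.length)):
            raise ValueError("transcript position out of range")
        if self.model.strand == "-":
            tpos = self.length - 1 - tpos
        idx = np.searchsorted(self._offsets, tpos, side="right") - 1
        return self._starts[idx] + (tpos - self._offsets[idx])

    def genomic_intervals(self, t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Genomic intervals covering transcript range [t_start, t_end)."""
        if not 0 <= t_start <= t_end <= self.length:
            raise ValueError("transcript range out of bounds")
        if t_start == t_end:
            return []
        if self.model.strand == "-":
            t_start, t_end = self.length - t_end, self.length - t_start
        out = []
        for s, e, off in zip(self._starts, self._ends, self._offsets):
            size = e - s
            lo, hi = max(t_start, off), min(t_end, off + size)
            if lo < hi:
                out.append((int(s + lo - off), int(s + hi - off)))
        return out


def subtract_intervals(base: list[tuple[int, int]],
                       cut: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set-subtract sorted-or-not interval lists (all half-open)."""
    out = []
    cut = sorted(cut)
    for s, e in sorted(base):
        cur = s
        for cs, ce in cut:
            if ce <= cur or cs >= e:
                continue
            if cs > cur:
                out.append((cur, cs))
            cur = max(cur, ce)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def merge_intervals(ivs: list[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    """Union of intervals, merging any separated by <= ``gap`` bp."""
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def intersect_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
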