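"""Turning raw RACE reads into stall-relative fragment 3'-end coordinates.

Three steps: 3'-adapter trimming (the ligated adapter marks the
fragment's true 3' terminus), ungapped placement on the single reporter
sequence by exhaustive Hamming scan, and conversion of the rightmost
aligned base into a distance upstream of the stall.  Every read is
assigned exactly one fate — mapped, or one rejection category — so fate
counts always partition the input.  Reads are never collapsed: duplicate
reads contribute duplicate fragments.

The aligner is deliberately bespoke and exhaustive: the reference is one
short reporter CDS, so minimising Hamming distance over every forward
offset is both exact and fast, and keeps the pipeline self-contained.
Externally aligned reads can bypass it via :func:`fragments_from_sam`.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .reporters import AnalysisConfig, RaceRead, ReporterSpec


class Fate(str, enum.Enum):
    """The single outcome assigned to every input read."""

    MAPPED = "mapped"
    NO_ADAPTER = "no_adapter"
    TOO_SHORT = "too_short"
    TOO_MANY_MISMATCHES = "too_many_mismatches"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class AlignedFragment:
    """One read's ungapped placement on the reporter.

    ``end3`` — the 1-based reporter position of the read's last template
    base — proxies the endonucleolytic cleavage site.
    """

    read_id: str
    start: int
    end3: int
    mismatches: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end3:
            raise ValueError(f"invalid fragment coordinates start={self.start} end3={self.end3}")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(
    sequence: str,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_frac: float = 0.1,
) -> Optional[str]:
    """Remove the 3' adapter; ``None`` if no qualifying match exists.

    The longest read suffix matching a prefix of the adapter (mismatch
    fraction <= ``max_mismatch_frac``, overlap >= ``min_overlap``) is
    removed, together with everything 3' of a full internal adapter
    occurrence.  Scanning candidate adapter start positions 5'->3', the
    earliest qualifying start wins, which is exactly the longest-suffix
    rule.  A read with no qualifying match is rejected — without the
    adapter its 3' end is unknowable.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, m = len(sequence), len(adapter)
    for i in range(n):
        overlap = min(n - i, m)
        if overlap < min_overlap and overlap < m:
            continue
        mismatches = hamming(sequence[i : i + overlap], adapter[:overlap])
        if mismatches <= max_mismatch_frac * overlap:
            return sequence[:i]
    return None


class ReporterAligner:
    """Exhaustive ungapped aligner against a single reporter sequence.

    For a trimmed read of length L, Hamming distance is computed at
    every forward-strand offset with start >= ``primer_start`` (the
    library's 5' primer bounds all genuine fragments); the unique
    minimum is accepted iff it does not exceed ``max_mismatches``.
    Placements are memoised by read sequence, so duplicate reads cost
    one scan.
    """

    def __init__(
        self,
        reporter: ReporterSpec,
        max_mismatches: int = 2,
        min_length: int = 15,
    ) -> None:
        self.reporter = reporter
        self.max_mismatches = max_mismatches
        self.min_length = min_length
        self._region = np.frombuffer(
            reporter.sequence[reporter.primer_start - 1 :].encode(), dtype=np.uint8
        )
        self._windows: dict[int, np.ndarray] = {}
        self._cache: dict[str, tuple[Fate, int, int]] = {}

    def _window_view(self, length: int) -> np.ndarray:
        view = self._windows.get(length)
        if view is None:
            view = sliding_window_view(self._region, length)
            self._windows[length] = view
        return view

    def align(self, read_id: str, trimmed: str) -> tuple[Fate, Optional[AlignedFragment]]:
        """Place a trimmed read; returns its fate and the fragment if mapped."""
        L = len(trimmed)
        if L < self.min_length:
            return Fate.TOO_SHORT, None
        cached = self._cache.get(trimmed)
        if cached is None:
            if L > self._region.size:
                cached = (Fate.TOO_SHORT, 0, 0)
            else:
                arr = np.frombuffer(trimmed.encode(), dtype=np.uint8)
                dists = (self._window_view(L) != arr).sum(axis=1)
                best = int(dists.min())
                if best > self.max_mismatches:
                    cached = (Fate.TOO_MANY_MISMATCHES, 0, 0)
                else:
                    hits = np.flatnonzero(dists == best)
                    if hits.size > 1:
                        cached = (Fate.AMBIGUOUS, 0, 0)
                    else:
                        start = int(hits[0]) + self.reporter.primer_start
                        cached = (Fate.MAPPED, start, best)
            self._cache[trimmed] = cached
        fate, start, mism = cached
        if fate is not Fate.MAPPED:
            return fate, None
        return fate, AlignedFragment(read_id=read_id, start=start, end3=start + L - 1, mismatches=mism)


def align_fragment(
    trimmed: str,
    reporter: ReporterSpec,
    max_align_mismatches: int = 2,
    min_length: int = 15,
    read_id: str = "",
) -> tuple[Fate, Optional[AlignedFragment]]:
    """One-shot wrapper around :class:`ReporterAligner`."""
    aligner = ReporterAligner(reporter, max_align_mismatches, min_length)
    return aligner.align(read_id, trimmed)


@dataclass
class MappingResult:
    """Mapped fragments plus the fate tally partitioning the input."""

    fragments: list[AlignedFragment]
    fates: Counter = field(default_factory=Counter)

    @property
    def n_reads(self) -> int:
        return sum(self.fates.values())


def map_reads(
    reads: Iterable[RaceRead],
    reporter: ReporterSpec,
    config: Optional[AnalysisConfig] = None,
) -> MappingResult:
    """Trim and align a read stream in a single forward pass."""
    config = config or AnalysisConfig()
    aligner = ReporterAligner(
        reporter,
        max_mismatches=config.max_align_mismatches,
        min_length=config.min_fragment_length,
    )
    trim_cache: dict[str, Optional[str]] = {}
    result = MappingResult(fragments=[])
    for read in reads:
        trimmed = trim_cache.get(read.sequence, "?")
        if trimmed == "?":
            trimmed = trim_adapter(
                read.sequence, config.adapter, config.min_overlap, config.max_mismatch_frac
            )
            trim_cache[read.sequence] = trimmed
        if trimmed is None:
            result.fates[Fate.NO_ADAPTER] += 1
            continue
        fate, frag = aligner.align(read.id, trimmed)
        result.fates[fate] += 1
        if frag is not None:
            result.fragments.append(frag)
    return result


def upstream_distance(frag: AlignedFragment, reporter: ReporterSpec) -> int:
    """Distance of the fragment 3' end upstream of the stall (nt).

    Positive values lie upstream; zero or negative values mark
    fragments ending at or past the stall (kept, but binned separately
    from peak calling).
    """
    return reporter.require_stall() - frag.end3


def fragments_to_distances(
    fragments: Iterable[AlignedFragment], reporter: ReporterSpec
) -> tuple[np.ndarray, int]:
    """Split fragments into upstream distances and a downstream tally.

    Returns (array of positive distances, count of fragments whose 3'
    end sits at or downstream of the stall).
    """
    stall = reporter.require_stall()
    distances = []
    n_downstream = 0
    for frag in fragments:
        d = stall - frag.end3
        if d >= 1:
            distances.append(d)
        else:
            n_downstream += 1
    return np.asarray(distances, dtype=int), n_downstream


def fragments_from_sam(path: str | Path, min_length: int = 15) -> MappingResult:
    """Load pre-aligned reads from SAM, bypassing the bespoke aligner.

    Each mapped record contributes a fragment whose ``end3`` is the
    rightmost aligned reference base (1-based).  Unmapped records are
    tallied under ``too_many_mismatches`` (the closest fate the external
    aligner's rejection maps onto); sub-minimum-length alignments under
    ``too_short``.
    """
    import pysam

    result = MappingResult(fragments=[])
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_end is None:
                result.fates[Fate.TOO_MANY_MISMATCHES] += 1
                continue
            length = rec.reference_end - rec.reference_start
            if length < min_length:
                result.fates[Fate.TOO_SHORT] += 1
                continue
            mismatches = rec.get_tag("NM") if rec.has_tag("NM") else 0
            result.fragments.append(
                AlignedFragment(
                    read_id=rec.query_name or "",
                    start=rec.reference_start + 1,
                    end3=rec.reference_end,
                    mismatches=int(mismatches),
                )
            )
            result.fates[Fate.MAPPED] += 1
    return result
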