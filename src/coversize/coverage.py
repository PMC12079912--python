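"""Coverage statistics: per-sequence summaries, high-coverage blacklisting,
and the pooled average depth over reference regions.

Blacklisting implements the default filter against sequences whose mean
depth is abnormally high relative to the assembly-wide mean — organellar
sequences (plastome, chondrome) and assembled contaminants attract reads
at many times the nuclear depth and would otherwise distort the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import EstimationError, InputError
from .io import CoverageTrack
from .regions import RegionSet

DEFAULT_BLACKLIST_FACTOR = 1.5


@dataclass(frozen=True)
class SequenceStats:
    sequence_id: str
    length: int
    total_bases: int

    @property
    def mean_depth(self) -> float:
        return self.total_bases / self.length


@dataclass(frozen=True)
class BlacklistResult:
    """Outcome of the high-coverage filter.

    ``overall_mean`` is the genome-wide pooled mean depth A (total aligned
    bases over total assembly positions, user pre-exclusions removed);
    a sequence is blacklisted iff its own mean depth exceeds
    ``factor × A``.
    """

    overall_mean: float
    factor: float
    blacklisted: frozenset[str]
    pre_excluded: frozenset[str]


def per_sequence_stats(track: CoverageTrack) -> list[SequenceStats]:
    if not track.depths:
        raise InputError("empty coverage track")
    return [
        SequenceStats(seq_id, int(arr.size), int(arr.sum()))
        for seq_id, arr in track.depths.items()
    ]


def blacklist_sequences(
    track: CoverageTrack,
    factor: float = DEFAULT_BLACKLIST_FACTOR,
    pre_excluded: Iterable[str] = (),
) -> BlacklistResult:
    """Single-pass high-coverage blacklisting (default factor 1.5).

    The genome-wide mean A is computed once over all sequences not already
    excluded by the user; no iterative re-computation after removal, so
    the result is deterministic and order-independent. For an assembly of
    ploidy p the recommended factor is 1.5 × p (see :mod:`coversize.ploidy`).
    """
    if factor <= 0:
        raise InputError("blacklist factor must be positive")
    pre_excluded = frozenset(pre_excluded)
    stats = [s for s in per_sequence_stats(track) if s.sequence_id not in pre_excluded]
    if not stats:
        raise EstimationError("all sequences pre-excluded; nothing to blacklist")
    total = sum(s.total_bases for s in stats)
    positions = sum(s.length for s in stats)
    overall_mean = total / positions
    blacklisted = frozenset(
        s.sequence_id for s in stats if s.mean_depth > factor * overall_mean
    )
    return BlacklistResult(overall_mean, float(factor), blacklisted, pre_excluded)


def pooled_region_depths(track: CoverageTrack, rs: RegionSet) -> np.ndarray:
    """Concatenate per-position depths over all reference regions.

    Order is deterministic: sequence id lexicographic, then coordinate.
    Zero-depth positions are included — silently skipping them would bias
    the average upward. ``rs`` must already be merged and clipped.
    """
    chunks: list[np.ndarray] = []
    for region in rs.sorted():
        if region.sequence_id not in track:
            raise InputError(
                f"region {region.label or '?'} references sequence "
                f"{region.sequence_id!r} absent from coverage track"
            )
        chunks.append(track[region.sequence_id][region.start : region.end])
    if not chunks:
        raise EstimationError("no reference regions")
    return np.concatenate(chunks)


def average_coverage(depths: Sequence[int] | np.ndarray, mode: str = "median") -> float:
    """Mean or median of the pooled reference-region depths.

    The median (the default downstream) is robust to residual repeats or
    collapsed paralogs inside the reference regions; the mean is exact
    under perfectly uniform depth. Even-length median is the midpoint of
    the two central values.
    """
    arr = np.asarray(depths)
    if arr.size == 0:
        raise EstimationError("no depths to average")
    if mode == "mean":
        value = float(np.mean(arr))
    elif mode == "median":
        value = float(np.median(arr))
    else:
        raise InputError(f"unknown averaging mode {mode!r} (expected 'mean' or 'median')")
    if value == 0.0:
        raise EstimationError("zero coverage in reference regions")
    return value
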