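"""Reference regions: the intervals over which average coverage is computed.

The estimator divides total aligned bases by an average per-position depth
measured inside a set of reference regions — ideally single-copy BUSCO
genes, which are expected exactly once per haploid genome and therefore
carry the genome's true 1x depth. This module builds, merges, clips and
filters those regions. All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping

from .exceptions import EstimationError, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .io import BuscoTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    sequence_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"region {self.label or self.sequence_id}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """An ordered collection of regions.

    After :func:`merge_and_clip`, regions on the same sequence are pairwise
    disjoint, sorted, and contained within their sequence.
    """

    regions: list[Region] = field(default_factory=list)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def sequences(self) -> set[str]:
        return {r.sequence_id for r in self.regions}

    def total_positions(self) -> int:
        return sum(len(r) for r in self.regions)

    def sorted(self) -> "RegionSet":
        return RegionSet(
            sorted(self.regions, key=lambda r: (r.sequence_id, r.start, r.end))
        )


def busco_to_regions(table: "BuscoTable", single_copy_only: bool = True) -> RegionSet:
    """Turn BUSCO records into reference regions.

    With ``single_copy_only`` (the default) only status ``Complete``
    records qualify — BUSCO's verdict that the gene is present exactly
    once. Otherwise ``Duplicated`` records qualify too (the copy-number-
    aware choice for polyploid assemblies). ``Fragmented`` and ``Missing``
    never yield regions.
    """
    accepted = {"Complete"} if single_copy_only else {"Complete", "Duplicated"}
    regions = [
        Region(rec.sequence_id, rec.start_1based - 1, rec.end_1based, rec.busco_id)
        for rec in table
        if rec.status in accepted
    ]
    if not regions:
        raise EstimationError("no reference regions: no qualifying BUSCO records")
    return RegionSet(regions)


def merge_and_clip(rs: RegionSet, lengths: Mapping[str, int]) -> RegionSet:
    """Sort, union overlapping/touching intervals, clip to sequence bounds.

    Merging guarantees each genomic position contributes exactly once to
    the pooled average coverage; overlapping gene annotations would
    otherwise double-weight their shared positions. Regions that vanish
    after clipping (entirely past the sequence end) are dropped.
    """
    unknown = sorted(rs.sequences() - set(lengths))
    if unknown:
        raise InputError(f"regions reference unknown sequences: {', '.join(unknown)}")
    by_seq: dict[str, list[Region]] = {}
    for region in rs:
        by_seq.setdefault(region.sequence_id, []).append(region)
    merged: list[Region] = []
    for seq_id in sorted(by_seq):
        seq_len = int(lengths[seq_id])
        intervals = sorted(by_seq[seq_id], key=lambda r: (r.start, r.end))
        cur_start = cur_end = None
        cur_label = ""
        for region in intervals:
            start, end = max(region.start, 0), min(region.end, seq_len)
            if start >= end:
                continue  # vanished after clipping
            if cur_start is None:
                cur_start, cur_end, cur_label = start, end, region.label
            elif start <= cur_end:  # overlap or touch: same position set either way
                cur_end = max(cur_end, end)
            else:
                merged.append(Region(seq_id, cur_start, cur_end, cur_label))
                cur_start, cur_end, cur_label = start, end, region.label
        if cur_start is not None:
            merged.append(Region(seq_id, cur_start, cur_end, cur_label))
    return RegionSet(merged)


def drop_sequences(rs: RegionSet, excluded: Iterable[str]) -> RegionSet:
    """Remove regions lying on excluded sequences (organelles, blacklist)."""
    excluded = set(excluded)
    kept = [r for r in rs if r.sequence_id not in excluded]
    n_dropped = len(rs) - len(kept)
    if n_dropped:
        logger.info("dropped %d region(s) on excluded sequences", n_dropped)
    if not kept:
        raise EstimationError("no reference regions remain after sequence exclusion")
    return RegionSet(kept)
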