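"""The headline computation: genome size N = L / C.

Under near-random fragmentation of the source DNA, sequencing reads fall
approximately uniformly over the genome, so the true genome length equals
the total number of aligned bases L divided by the per-position depth C
that a single-copy region experiences. Collapsed repeats (m genomic
copies assembled as one) do not break this: their reads still land in the
assembly and contribute to L at m-fold local depth, so N recovers the
repeat's full length even though the assembly does not.

This module assembles the estimate from coverage, reference regions,
blacklisting and user exclusions, and runs the subsampling saturation
sweep that locates the minimum sequencing effort for a stable estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .coverage import (
    DEFAULT_BLACKLIST_FACTOR,
    average_coverage,
    blacklist_sequences,
    pooled_region_depths,
)
from .exceptions import EstimationError, InputError
from .io import CoverageTrack
from .regions import RegionSet, drop_sequences


@dataclass(frozen=True)
class EstimateResult:
    """A genome size estimate and its full bookkeeping.

    ``genome_size_bp × average_coverage == total_aligned_bases`` holds to
    floating tolerance; L counts only sequences that are neither
    blacklisted nor user-excluded.
    """

    genome_size_bp: float
    total_aligned_bases: int
    average_coverage: float
    mode: str
    region_positions: int
    blacklisted: frozenset[str]
    excluded: frozenset[str]
    blacklist_factor: float | None
    overall_mean: float | None

    @property
    def genome_size_rounded_bp(self) -> int:
        return round(self.genome_size_bp)

    @property
    def genome_size_mbp(self) -> float:
        return round(self.genome_size_bp / 1e6, 2)


@dataclass(frozen=True)
class SaturationRow:
    """One subsampling level of the saturation sweep.

    ``estimate_bp`` is None when the thinned data could not support an
    estimate (e.g. zero coverage in the reference regions).
    """

    fraction: float
    sampled_bases: int
    estimate_bp: float | None
    within_tolerance: bool = False


def total_aligned_bases(track: CoverageTrack, included: Iterable[str]) -> int:
    """L: the sum of depths over the included sequences (exact integer)."""
    included = set(included)
    if not included:
        raise EstimationError("no sequences included: L undefined")
    missing = included - set(track.depths)
    if missing:
        raise InputError(f"included sequences absent from track: {sorted(missing)}")
    return int(sum(int(track[s].sum()) for s in included))


def estimate_genome_size(
    track: CoverageTrack,
    regions: RegionSet,
    mode: str = "median",
    blacklist_enabled: bool = True,
    blacklist_factor: float = DEFAULT_BLACKLIST_FACTOR,
    excluded: Iterable[str] = (),
) -> EstimateResult:
    """Estimate genome size as N = L / C.

    Pipeline: (1) optionally blacklist high-coverage sequences (on by
    default; the CLI's ``--ignore`` turns it off); (2) drop reference
    regions on blacklisted or user-excluded sequences; (3) C = mean or
    median depth pooled over the remaining regions; (4) L = total aligned
    bases on the remaining sequences; (5) N = L / C.

    ``regions`` must already be merged and clipped.
    """
    excluded = frozenset(excluded)
    if blacklist_enabled:
        bl = blacklist_sequences(track, blacklist_factor, pre_excluded=excluded)
        blacklisted = bl.blacklisted
        overall_mean: float | None = bl.overall_mean
        factor: float | None = bl.factor
    else:
        blacklisted = frozenset()
        overall_mean = None
        factor = None

    removed = blacklisted | excluded
    if removed:
        regions = drop_sequences(regions, removed)
    depths = pooled_region_depths(track, regions)
    coverage = average_coverage(depths, mode)

    included = set(track.depths) - removed
    aligned = total_aligned_bases(track, included)
    if aligned == 0:
        raise EstimationError("no aligned bases on included sequences")
    return EstimateResult(
        genome_size_bp=aligned / coverage,
        total_aligned_bases=aligned,
        average_coverage=coverage,
        mode=mode,
        region_positions=int(depths.size),
        blacklisted=blacklisted,
        excluded=excluded,
        blacklist_factor=factor,
        overall_mean=overall_mean,
    )


def saturation_analysis(
    track: CoverageTrack,
    regions: RegionSet,
    mode: str = "median",
    fractions: Sequence[float] = (1.0, 0.75, 0.5, 0.25, 0.1, 0.075, 0.05, 0.025, 0.01, 0.005),
    tolerance: float = 0.05,
    seed: int = 0,
    **estimator_options,
) -> tuple[list[SaturationRow], int | None]:
    """Re-estimate on binomially thinned coverage at each fraction.

    Emulates re-running the estimator on subsampled read sets: each depth
    d is replaced by a Binomial(d, f) draw, which is the depth
    distribution an f-fraction read subsample induces. The fraction-1.0
    row uses the untouched track, so its estimate equals the full
    estimate bitwise. Each fraction gets its own derived seed
    (``seed + index``) so rows are independently reproducible.

    ``minimum_bases`` is the smallest sampled-bases value b such that
    every row with at least b sampled bases deviates from the full
    estimate by at most ``tolerance`` (relative); None when only the full
    run qualifies. A failing fraction yields a row with ``estimate_bp``
    None and never aborts the sweep.
    """
    from .simulate import thin_track

    fractions = list(fractions)
    if 1.0 not in fractions:
        raise InputError("fractions must include 1.0 (the full data set)")
    if tolerance <= 0:
        raise InputError("tolerance must be positive")

    full = estimate_genome_size(track, regions, mode=mode, **estimator_options)
    rows: list[SaturationRow] = []
    for index, fraction in enumerate(fractions):
        if not 0.0 < fraction <= 1.0:
            raise InputError(f"fraction {fraction} outside (0, 1]")
        if fraction == 1.0:
            thinned = track
        else:
            thinned = thin_track(track, fraction, seed=seed + index)
        try:
            result = estimate_genome_size(thinned, regions, mode=mode, **estimator_options)
        except EstimationError:
            rows.append(SaturationRow(fraction, thinned.total_bases(), None, False))
            continue
        within = (
            abs(result.genome_size_bp - full.genome_size_bp) / full.genome_size_bp
            <= tolerance
        )
        rows.append(
            SaturationRow(fraction, result.total_aligned_bases, result.genome_size_bp, within)
        )

    # Plateau rule: walk rows from most to least sampled bases; the
    # qualifying prefix (uninterrupted within-tolerance run from the top)
    # defines the stable regime, and its smallest sampled_bases is the
    # minimum sequencing effort.
    ordered = sorted(rows, key=lambda r: r.sampled_bases, reverse=True)
    qualifying: list[SaturationRow] = []
    for row in ordered:
        if row.estimate_bp is None or not row.within_tolerance:
            break
        qualifying.append(row)
    if len(qualifying) <= 1:
        return rows, None
    return rows, qualifying[-1].sampled_bases
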