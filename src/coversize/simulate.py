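"""Synthetic coverage scenarios with known ground truth.

The generator emulates the depth signal a shotgun mapping produces on an
imperfect assembly:

* near-uniform nuclear depth c (exact, or Poisson(c) per position),
* collapsed repeats — m true genomic copies assembled as one copy, so
  reads from all m copies pile onto it at m × c depth,
* an organellar sequence ("pt") at a high depth multiplier (organelle
  copies per cell vastly outnumber nuclear copies),
* contaminant bases that were sequenced but never map — they appear
  nowhere in the track, which is exactly how the estimator ignores them,
* a set of single-copy BUSCO genes placed outside the repeat blocks.

The ground truth genome size is nuclear-only (organelles are excluded
from the nucleome estimate): nuclear_length + Σ (m−1) × repeat_length.

Per-position depths are simulated directly rather than via reads; an
alignment-level generator exists to exercise the SAM-to-coverage path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import InputError
from .io import BuscoRecord, BuscoTable, CoverageTrack
from .regions import Region, RegionSet, merge_and_clip


@dataclass(frozen=True)
class SyntheticScenario:
    """Declarative simulation settings.

    ``repeat_blocks`` entries are ``(assembly_offset, length, m)`` with m
    the true copy number of the collapsed repeat (m = 1 is an ordinary
    block). ``noise`` is ``"none"`` (exact depths) or ``"poisson"``.
    """

    nuclear_length: int = 1_000_000
    base_depth: int = 20
    repeat_blocks: tuple[tuple[int, int, int], ...] = ()
    organelle: tuple[int, int] | None = None  # (length, depth multiplier)
    contaminant_bases: int = 0
    noise: str = "none"
    n_single_copy_buscos: int = 100
    busco_length: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nuclear_length < 1 or self.base_depth < 1:
            raise InputError("nuclear_length and base_depth must be positive")
        if self.noise not in ("none", "poisson"):
            raise InputError(f"unknown noise model {self.noise!r}")
        blocks = sorted(self.repeat_blocks)
        prev_end = 0
        for offset, length, m in blocks:
            if offset < prev_end:
                raise InputError("repeat blocks overlap")
            if offset + length > self.nuclear_length:
                raise InputError("repeat block extends past nuclear sequence")
            if m < 1:
                raise InputError("repeat copy number must be >= 1")
            prev_end = offset + length

    @property
    def true_genome_size(self) -> int:
        """Nuclear truth: assembly length plus the collapsed repeat excess."""
        return self.nuclear_length + sum(
            (m - 1) * length for _, length, m in self.repeat_blocks
        )


@dataclass
class SyntheticDataset:
    track: CoverageTrack
    regions: RegionSet
    busco_table: BuscoTable
    excluded_ids: frozenset[str]
    truth: dict = field(default_factory=dict)


def _place_buscos(scenario: SyntheticScenario, rng: np.random.Generator) -> list[int]:
    """Pick BUSCO start offsets outside repeat blocks, disjoint, seeded."""
    blocks = sorted(scenario.repeat_blocks)
    free: list[tuple[int, int]] = []
    cursor = 0
    for offset, length, _ in blocks:
        if offset > cursor:
            free.append((cursor, offset))
        cursor = offset + length
    if cursor < scenario.nuclear_length:
        free.append((cursor, scenario.nuclear_length))
    slots: list[int] = []
    for start, end in free:
        n_fit = (end - start) // scenario.busco_length
        slots.extend(start + i * scenario.busco_length for i in range(n_fit))
    if len(slots) < scenario.n_single_copy_buscos:
        raise InputError(
            f"cannot place {scenario.n_single_copy_buscos} BUSCO regions of length "
            f"{scenario.busco_length} outside the repeat blocks"
        )
    chosen = rng.choice(len(slots), size=scenario.n_single_copy_buscos, replace=False)
    return sorted(slots[i] for i in chosen)


def simulate_depth_scenario(scenario: SyntheticScenario) -> SyntheticDataset:
    """Generate the coverage track, BUSCO table, regions, and truth.

    Deterministic under the scenario seed. With ``noise="none"`` the
    depth over a repeat block equals m × c exactly and the median/mean
    estimators recover the true genome size exactly.
    """
    rng = np.random.default_rng(scenario.seed)
    c = scenario.base_depth

    expected = np.full(scenario.nuclear_length, c, dtype=np.int64)
    for offset, length, m in scenario.repeat_blocks:
        expected[offset : offset + length] = m * c
    if scenario.noise == "poisson":
        nuc = rng.poisson(expected).astype(np.int64)
    else:
        nuc = expected.copy()

    depths = {"nuc": nuc}
    expected_depths = {"nuc": expected}
    excluded: frozenset[str] = frozenset()
    if scenario.organelle is not None:
        pt_length, multiplier = scenario.organelle
        pt_expected = np.full(pt_length, multiplier * c, dtype=np.int64)
        depths["pt"] = (
            rng.poisson(pt_expected).astype(np.int64)
            if scenario.noise == "poisson"
            else pt_expected.copy()
        )
        expected_depths["pt"] = pt_expected
        excluded = frozenset({"pt"})

    starts = _place_buscos(scenario, rng)
    records = [
        BuscoRecord(f"BUSCO{i:04d}", "Complete", "nuc", s + 1, s + scenario.busco_length)
        for i, s in enumerate(starts)
    ]
    table = BuscoTable(records)
    track = CoverageTrack(depths)
    regions = merge_and_clip(
        RegionSet(
            [Region("nuc", s, s + scenario.busco_length, r.busco_id) for s, r in zip(starts, records)]
        ),
        track.lengths(),
    )
    truth = {
        "true_genome_size": scenario.true_genome_size,
        "expected_depths": expected_depths,
        "contaminant_bases": scenario.contaminant_bases,
    }
    return SyntheticDataset(track, regions, table, excluded, truth)


def simulate_alignments(
    scenario: SyntheticScenario, read_length: int = 100
) -> tuple[str, dict[str, int]]:
    """Emit SAM-dialect records realizing the scenario's expected depths.

    Noiseless scenarios only. Depth is built in layers: for each depth
    level, the positions still requiring coverage form intervals that are
    tiled with reads of ``read_length`` (the final read of an interval is
    shortened, never overhanging), so the resulting per-position coverage
    equals the expected track exactly.
    """
    if scenario.noise != "none":
        raise InputError("alignment simulation supports noise='none' only")
    dataset = simulate_depth_scenario(scenario)
    lengths = dataset.track.lengths()
    if any(read_length > n for n in lengths.values()):
        raise InputError("read_length exceeds a sequence length")

    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for seq_id in lengths:
        lines.append(f"@SQ\tSN:{seq_id}\tLN:{lengths[seq_id]}")
    n_read = 0
    for seq_id, expected in dataset.truth["expected_depths"].items():
        max_depth = int(expected.max())
        for layer in range(max_depth):
            mask = expected > layer
            # interval extraction: starts/ends of runs of True
            padded = np.concatenate(([False], mask, [False]))
            edges = np.flatnonzero(padded[1:] != padded[:-1])
            for start, end in zip(edges[::2], edges[1::2]):
                pos = int(start)
                while pos < end:
                    span = min(read_length, int(end) - pos)
                    lines.append(
                        f"r{n_read:06d}\t0\t{seq_id}\t{pos + 1}\t60\t{span}M\t*\t0\t0\t*\t*"
                    )
                    n_read += 1
                    pos += span
    return "\n".join(lines) + "\n", lengths


def thin_track(track: CoverageTrack, fraction: float, seed: int = 0) -> CoverageTrack:
    """Binomial thinning: each depth d becomes Binomial(d, fraction).

    This is the depth distribution induced by keeping each read
    independently with probability ``fraction`` — a fast surrogate for
    read-level subsampling followed by re-mapping. fraction 1 is the
    identity; fraction 0 zeroes the track.
    """
    if not 0.0 <= fraction <= 1.0:
        raise InputError(f"fraction {fraction} outside [0, 1]")
    if fraction == 1.0:
        return track.copy()
    rng = np.random.default_rng(seed)
    return CoverageTrack(
        {s: rng.binomial(a, fraction).astype(np.int64) for s, a in track.depths.items()}
    )


def simulate_busco_copy_table(
    copy_counts: Mapping[int, int],
    sequence_id: str = "nuc",
    gene_length: int = 1_000,
    seed: int = 0,
) -> BuscoTable:
    """A BUSCO table with a prescribed copy-number composition.

    ``copy_counts`` maps copy number to the number of BUSCO ids carrying
    that many copies, e.g. ``{2: 450, 1: 40, 4: 10}`` for a diploid-
    resolved assembly. Single-copy ids get status Complete; multi-copy
    ids get one Duplicated record per copy laid out head-to-tail.
    """
    records: list[BuscoRecord] = []
    offset = 0
    index = 0
    for copies in sorted(copy_counts):
        if copies < 1:
            raise InputError("copy numbers must be >= 1")
        for _ in range(copy_counts[copies]):
            busco_id = f"BUSCO{index:05d}"
            index += 1
            status = "Complete" if copies == 1 else "Duplicated"
            for _copy in range(copies):
                records.append(
                    BuscoRecord(busco_id, status, sequence_id, offset + 1, offset + gene_length)
                )
                offset += gene_length
    if not records:
        raise InputError("copy_counts produced no records")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return BuscoTable([records[i] for i in order])


# ---------------------------------------------------------------------------
# Named presets for the CLI and examples.

PRESETS: dict[str, SyntheticScenario] = {
    "clean": SyntheticScenario(
        nuclear_length=100_000, base_depth=10, noise="none",
        n_single_copy_buscos=20, busco_length=1_000, seed=0,
    ),
    "repeat": SyntheticScenario(
        nuclear_length=100_000, base_depth=10,
        repeat_blocks=((60_000, 10_000, 3),), noise="none",
        n_single_copy_buscos=20, busco_length=1_000, seed=0,
    ),
    "organelle": SyntheticScenario(
        nuclear_length=100_000, base_depth=10, organelle=(5_000, 10),
        noise="none", n_single_copy_buscos=20, busco_length=1_000, seed=0,
    ),
    "noisy": SyntheticScenario(
        nuclear_length=1_000_000, base_depth=20,
        repeat_blocks=((600_000, 10_000, 3),), noise="poisson",
        n_single_copy_buscos=100, busco_length=1_000, seed=0,
    ),
    "polyploid": SyntheticScenario(
        nuclear_length=200_000, base_depth=20, noise="poisson",
        n_single_copy_buscos=50, busco_length=1_000, seed=0,
    ),
}


def preset(name: str, seed: int | None = None) -> SyntheticScenario:
    """Look up a named preset, optionally re-seeded."""
    if name not in PRESETS:
        raise InputError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    scenario = PRESETS[name]
    if seed is not None:
        scenario = SyntheticScenario(
            **{**scenario.__dict__, "seed": seed}  # type: ignore[arg-type]
        )
    return scenario
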