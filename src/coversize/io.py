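"""Readers and writers for the file dialects the estimator consumes.

Supported formats:

* per-position coverage TSV (the ``bedtools genomecov -d`` shape:
  ``sequence<TAB>position_1based<TAB>depth`` with full consecutive
  position enumeration),
* SAM-dialect alignment text (parsed with pysam; only FLAG, RNAME,
  POS and CIGAR are interpreted),
* GFF3 feature rows,
* BUSCO "full table" TSV,
* FASTA (sequence lengths only).

All genomic intervals are converted to 0-based half-open coordinates at
the boundary; everything downstream of this module uses that convention.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Union

import numpy as np
import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .exceptions import DialectError, InputError
from .regions import Region, RegionSet

TextSource = Union[str, Path, IO[str], Iterable[str]]

#: CIGAR operation codes that consume reference positions.
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X
#: Reference-consuming codes counted as read coverage. D is included so a
#: small deletion does not punch a zero-depth hole through a covered gene.
_COVERING = {0, 2, 7, 8}  # M, D, =, X


@dataclass
class CoverageTrack:
    """Per-sequence arrays of per-position aligned-read depth.

    ``depths`` maps sequence id to an int64 array; index 0 is the first
    base of the sequence. This is the central in-memory structure of the
    package: every estimate is a function of one of these.
    """

    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for seq_id, arr in self.depths.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 1 or arr.size < 1:
                raise InputError(f"sequence {seq_id!r}: depths must be a non-empty 1-D array")
            if (arr < 0).any():
                raise InputError(f"sequence {seq_id!r}: negative depth")
            clean[seq_id] = arr
        self.depths = clean

    def sequences(self) -> list[str]:
        return list(self.depths)

    def lengths(self) -> dict[str, int]:
        return {s: int(a.size) for s, a in self.depths.items()}

    def total_bases(self) -> int:
        """Sum of all depths: the total number of aligned bases."""
        return int(sum(int(a.sum()) for a in self.depths.values()))

    def copy(self) -> "CoverageTrack":
        return CoverageTrack({s: a.copy() for s, a in self.depths.items()})

    def scaled(self, k: int) -> "CoverageTrack":
        """Every depth multiplied by a positive integer ``k``."""
        if k <= 0:
            raise InputError("scale factor must be a positive integer")
        return CoverageTrack({s: a * int(k) for s, a in self.depths.items()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if set(self.depths) != set(other.depths):
            return False
        return all(np.array_equal(self.depths[s], other.depths[s]) for s in self.depths)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.depths

    def __getitem__(self, seq_id: str) -> np.ndarray:
        return self.depths[seq_id]


_BUSCO_STATUSES = frozenset({"Complete", "Duplicated", "Fragmented", "Missing"})


@dataclass(frozen=True)
class BuscoRecord:
    """One row of a BUSCO full table (1-based inclusive coordinates)."""

    busco_id: str
    status: str
    sequence_id: str | None = None
    start_1based: int | None = None
    end_1based: int | None = None

    def __post_init__(self) -> None:
        if self.status not in _BUSCO_STATUSES:
            raise InputError(f"unknown BUSCO status {self.status!r}")
        if self.status == "Missing":
            if self.sequence_id is not None or self.start_1based is not None:
                raise InputError(f"{self.busco_id}: Missing records carry no coordinates")
        else:
            if self.sequence_id is None or self.start_1based is None or self.end_1based is None:
                raise InputError(f"{self.busco_id}: non-Missing record lacks coordinates")
            if self.start_1based > self.end_1based:
                raise InputError(f"{self.busco_id}: start > end")


@dataclass
class BuscoTable:
    """Ordered collection of :class:`BuscoRecord`.

    A busco_id may repeat only when its status is Duplicated.
    """

    records: list[BuscoRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for rec in self.records:
            if rec.busco_id in seen:
                if rec.status != "Duplicated" or seen[rec.busco_id] != "Duplicated":
                    raise InputError(
                        f"busco id {rec.busco_id!r} repeats with non-Duplicated status"
                    )
            seen[rec.busco_id] = rec.status

    def __iter__(self) -> Iterator[BuscoRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _iter_lines(source: TextSource) -> Iterator[str]:
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        with open(source, "rt") as handle:
            yield from handle
    elif isinstance(source, str):
        yield from source.splitlines()
    else:
        yield from source


def read_coverage_file(source: TextSource) -> CoverageTrack:
    """Parse a per-position coverage TSV into a :class:`CoverageTrack`.

    The dialect is ``sequence<TAB>position<TAB>depth`` with 1-based
    positions enumerated consecutively from 1 and all lines of one
    sequence contiguous. A missing position is a dialect error, not an
    implicit zero — truncated files must not silently shrink a genome.
    """
    depths: dict[str, list[int]] = {}
    current: str | None = None
    n_data = 0
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise DialectError(f"line {lineno}: expected 3 TAB-separated columns")
        seq_id = parts[0]
        try:
            pos = int(parts[1])
            depth = int(parts[2])
        except ValueError:
            raise DialectError(f"line {lineno}: non-integer position or depth") from None
        if depth < 0:
            raise DialectError(f"line {lineno}: negative depth {depth}")
        if seq_id != current:
            if seq_id in depths:
                raise DialectError(
                    f"line {lineno}: lines for sequence {seq_id!r} are not contiguous"
                )
            depths[seq_id] = []
            current = seq_id
        expected = len(depths[seq_id]) + 1
        if pos != expected:
            raise DialectError(
                f"line {lineno}: sequence {seq_id!r} position {pos}, expected {expected}"
            )
        depths[seq_id].append(depth)
        n_data += 1
    if n_data == 0:
        raise DialectError("empty coverage file")
    return CoverageTrack({s: np.asarray(d, dtype=np.int64) for s, d in depths.items()})


def write_coverage_file(track: CoverageTrack, handle: IO[str] | None = None) -> str:
    """Emit the exact dialect :func:`read_coverage_file` consumes.

    Returns the text; also writes it to ``handle`` if given.
    ``read_coverage_file(write_coverage_file(t)) == t``.
    """
    chunks: list[str] = []
    for seq_id, arr in track.depths.items():
        positions = np.arange(1, arr.size + 1)
        chunks.extend(f"{seq_id}\t{p}\t{d}\n" for p, d in zip(positions, arr))
    text = "".join(chunks)
    if handle is not None:
        handle.write(text)
    return text


def _sam_path(alignments: str | Path) -> tuple[str, bool]:
    """Return (path, is_temp). Text input is spooled to a temp file for pysam."""
    if isinstance(alignments, Path) or (
        isinstance(alignments, str) and "\n" not in alignments and os.path.exists(alignments)
    ):
        return str(alignments), False
    fd, path = tempfile.mkstemp(suffix=".sam", text=True)
    with os.fdopen(fd, "wt") as handle:
        handle.write(str(alignments))
    return path, True


def alignments_to_coverage(
    alignments: str | Path, lengths: Mapping[str, int]
) -> CoverageTrack:
    """Accumulate per-position depth from SAM-dialect alignment records.

    Every reference position consumed by a CIGAR M/=/X/D operation of a
    mapped primary record increments depth by one. Unmapped records are
    skipped silently — discarding reads that never map is precisely how
    contaminant reads stay out of the estimate. Secondary (0x100) and
    supplementary (0x800) records are skipped so each read contributes a
    single placement.
    """
    path, is_temp = _sam_path(alignments)
    track = {seq: np.zeros(int(n), dtype=np.int64) for seq, n in lengths.items()}
    try:
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for name, declared in zip(sam.header.references, sam.header.lengths):
                if name not in lengths:
                    raise InputError(f"@SQ sequence {name!r} absent from lengths")
                if int(declared) != int(lengths[name]):
                    raise InputError(
                        f"@SQ length for {name!r} is {declared}, expected {lengths[name]}"
                    )
            for read in sam:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                ref = read.reference_name
                if ref not in track:
                    raise InputError(f"alignment references unknown sequence {ref!r}")
                arr = track[ref]
                pos = read.reference_start  # 0-based
                if read.cigartuples is None:
                    raise DialectError(f"mapped record {read.query_name!r} lacks a CIGAR")
                for op, length in read.cigartuples:
                    if op not in _REF_CONSUMING:
                        continue
                    end = pos + length
                    if end > arr.size:
                        raise InputError(
                            f"alignment {read.query_name!r} extends past end of {ref!r}"
                        )
                    if op in _COVERING:
                        arr[pos:end] += 1
                    pos = end
    finally:
        if is_temp:
            os.unlink(path)
    return CoverageTrack(track)


def read_gff3_regions(source: TextSource, feature_types: set[str]) -> RegionSet:
    """Extract regions of the requested feature types from GFF3 rows.

    1-based inclusive coordinates become 0-based half-open; strand is
    ignored (coverage is strandless). Labels come from an ``ID=`` or
    ``Name=`` attribute when present, else ``type:line``.
    """
    regions: list[Region] = []
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise DialectError(f"line {lineno}: expected 9 GFF3 columns, got {len(cols)}")
        seq_id, _source, ftype, start_s, end_s = cols[0], cols[1], cols[2], cols[3], cols[4]
        if ftype not in feature_types:
            continue
        try:
            start = int(start_s)
            end = int(end_s)
        except ValueError:
            raise DialectError(f"line {lineno}: non-integer coordinates") from None
        if start > end:
            raise DialectError(f"line {lineno}: start {start} > end {end}")
        label = f"{ftype}:{lineno}"
        for attr in cols[8].split(";"):
            key, _, value = attr.strip().partition("=")
            if key in ("ID", "Name") and value:
                label = value
                break
        regions.append(Region(seq_id, start - 1, end, label))
    return RegionSet(regions)


def read_busco_full_table(source: TextSource) -> BuscoTable:
    """Parse a BUSCO "full table": ``busco_id status sequence start end …``.

    The full table (rather than BUSCO's per-gene GFF3s) is the canonical
    carrier because the status column — Complete vs Duplicated — drives
    both single-copy reduction and ploidy inference.
    """
    records: list[BuscoRecord] = []
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise DialectError(f"line {lineno}: expected at least busco_id and status")
        busco_id, status = cols[0], cols[1]
        if status not in _BUSCO_STATUSES:
            raise DialectError(f"line {lineno}: unknown BUSCO status {status!r}")
        if status == "Missing":
            records.append(BuscoRecord(busco_id, status))
            continue
        if len(cols) < 5 or not cols[2] or not cols[3] or not cols[4]:
            raise DialectError(f"line {lineno}: {status} row lacks coordinate columns")
        try:
            start = int(cols[3])
            end = int(cols[4])
        except ValueError:
            raise DialectError(f"line {lineno}: non-integer coordinates") from None
        try:
            records.append(BuscoRecord(busco_id, status, cols[2], start, end))
        except InputError as exc:
            raise DialectError(f"line {lineno}: {exc}") from None
    try:
        return BuscoTable(records)
    except InputError as exc:
        raise DialectError(str(exc)) from None


def read_fasta_lengths(source: TextSource) -> dict[str, int]:
    """Sequence lengths from FASTA; id is the header token before whitespace."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        with open(source, "rt") as handle:
            return _fasta_lengths(handle)
    if isinstance(source, str):
        import io as _io

        return _fasta_lengths(_io.StringIO(source))
    return _fasta_lengths(source)


def _fasta_lengths(handle: IO[str]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for header, seq in SimpleFastaParser(handle):
        seq_id = header.split()[0] if header.split() else header
        if seq_id in lengths:
            raise DialectError(f"duplicate FASTA id {seq_id!r}")
        lengths[seq_id] = len("".join(seq.split()))
    if not lengths:
        raise DialectError("empty FASTA input")
    for seq_id, residues in lengths.items():
        if residues == 0:
            raise DialectError(f"FASTA record {seq_id!r} is empty")
    return lengths
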