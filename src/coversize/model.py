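"""Model/results interface over the genome-size estimator.

`GenomeSizeModel` binds the data (a coverage track and a reference-region
set) together with the estimation options; `fit()` performs the N = L / C
computation and returns a `GenomeSizeResults` carrying the estimate, its
bookkeeping, a text `summary()`, the saturation sweep, and plotting.

    >>> model = GenomeSizeModel(track, regions, mode="median")
    >>> res = model.fit()
    >>> res.genome_size_bp
    135000000.0
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from . import io as _io
from .coverage import DEFAULT_BLACKLIST_FACTOR
from .estimator import (
    EstimateResult,
    SaturationRow,
    estimate_genome_size,
    saturation_analysis,
)
from .exceptions import InputError
from .io import CoverageTrack
from .regions import RegionSet, busco_to_regions, merge_and_clip


class GenomeSizeModel:
    """Mapping-coverage genome size model.

    Parameters
    ----------
    track
        Per-position aligned-read depth over the assembly.
    regions
        Reference regions for the average-coverage calculation (merged
        and clipped against the track on construction).
    mode
        ``"median"`` (default, robust) or ``"mean"``.
    blacklist
        Automatically exclude sequences whose mean depth exceeds
        ``blacklist_factor`` times the assembly-wide mean (default on;
        turn off for polyploid assemblies, or raise the factor to
        1.5 × ploidy).
    excluded
        Sequence ids excluded up front (typically plastome/chondrome).
    """

    def __init__(
        self,
        track: CoverageTrack,
        regions: RegionSet,
        mode: str = "median",
        blacklist: bool = True,
        blacklist_factor: float = DEFAULT_BLACKLIST_FACTOR,
        excluded: Iterable[str] = (),
    ) -> None:
        if mode not in ("mean", "median"):
            raise InputError(f"unknown averaging mode {mode!r}")
        self.track = track
        self.regions = merge_and_clip(regions, track.lengths())
        self.mode = mode
        self.blacklist = blacklist
        self.blacklist_factor = blacklist_factor
        self.excluded = frozenset(excluded)

    @classmethod
    def from_files(
        cls,
        coverage: str | Path | None = None,
        sam: str | Path | None = None,
        fasta: str | Path | None = None,
        busco: str | Path | None = None,
        gff: str | Path | None = None,
        feature: str = "gene",
        single_copy_only: bool = True,
        **options,
    ) -> "GenomeSizeModel":
        """Build a model from files: a coverage TSV (or SAM + FASTA) plus
        a BUSCO full table (or GFF3 with a feature type)."""
        if coverage is not None:
            track = _io.read_coverage_file(coverage)
        elif sam is not None and fasta is not None:
            track = _io.alignments_to_coverage(sam, _io.read_fasta_lengths(fasta))
        else:
            raise InputError("need either a coverage file or SAM + FASTA")
        if busco is not None:
            regions = busco_to_regions(
                _io.read_busco_full_table(busco), single_copy_only=single_copy_only
            )
        elif gff is not None:
            regions = _io.read_gff3_regions(gff, {feature})
        else:
            raise InputError("need either a BUSCO full table or a GFF3 file")
        return cls(track, regions, **options)

    def fit(self) -> "GenomeSizeResults":
        result = estimate_genome_size(
            self.track,
            self.regions,
            mode=self.mode,
            blacklist_enabled=self.blacklist,
            blacklist_factor=self.blacklist_factor,
            excluded=self.excluded,
        )
        return GenomeSizeResults(self, result)


class GenomeSizeResults:
    """Fitted genome-size estimate with diagnostics.

    Attributes mirror :class:`~coversize.estimator.EstimateResult`;
    ``summary()`` renders a readable table, ``saturation()`` runs the
    subsampling sweep around this fit's settings.
    """

    def __init__(self, model: GenomeSizeModel, result: EstimateResult) -> None:
        self.model = model
        self._result = result

    # -- pass-through accessors -------------------------------------------
    @property
    def genome_size_bp(self) -> float:
        return self._result.genome_size_bp

    @property
    def genome_size_mbp(self) -> float:
        return self._result.genome_size_mbp

    @property
    def total_aligned_bases(self) -> int:
        return self._result.total_aligned_bases

    @property
    def average_coverage(self) -> float:
        return self._result.average_coverage

    @property
    def blacklisted(self) -> frozenset[str]:
        return self._result.blacklisted

    @property
    def excluded(self) -> frozenset[str]:
        return self._result.excluded

    @property
    def estimate(self) -> EstimateResult:
        return self._result

    def summary(self) -> str:
        r = self._result
        lines = [
            "Genome size estimate (N = L / C)",
            "=" * 48,
            f"{'genome size N':<28}{r.genome_size_rounded_bp:>14,d} bp",
            f"{'':<28}{r.genome_size_mbp:>14.2f} Mbp",
            f"{'total aligned bases L':<28}{r.total_aligned_bases:>14,d}",
            f"{'average coverage C':<28}{r.average_coverage:>14.4f}",
            f"{'averaging mode':<28}{r.mode:>14}",
            f"{'reference positions':<28}{r.region_positions:>14,d}",
        ]
        if r.blacklist_factor is not None:
            lines.append(f"{'blacklist factor':<28}{r.blacklist_factor:>14.2f}")
            lines.append(f"{'assembly-wide mean depth':<28}{r.overall_mean:>14.4f}")
        else:
            lines.append(f"{'blacklisting':<28}{'off':>14}")
        lines.append(
            f"{'blacklisted sequences':<28}{', '.join(sorted(r.blacklisted)) or '-':>14}"
        )
        lines.append(
            f"{'excluded sequences':<28}{', '.join(sorted(r.excluded)) or '-':>14}"
        )
        lines.append("=" * 48)
        return "\n".join(lines)

    def saturation(
        self,
        fractions: Sequence[float] = (1.0, 0.75, 0.5, 0.25, 0.1, 0.075, 0.05, 0.025, 0.01, 0.005),
        tolerance: float = 0.05,
        seed: int = 0,
    ) -> tuple[list[SaturationRow], int | None]:
        """Subsampling saturation sweep at this fit's settings."""
        return saturation_analysis(
            self.model.track,
            self.model.regions,
            mode=self.model.mode,
            fractions=fractions,
            tolerance=tolerance,
            seed=seed,
            blacklist_enabled=self.model.blacklist,
            blacklist_factor=self.model.blacklist_factor,
            excluded=self.model.excluded,
        )

    def plot_saturation(self, rows: Sequence[SaturationRow], ax=None):
        """Estimate vs sampled bases; the full-data estimate as a dashed line."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        good = [r for r in rows if r.estimate_bp is not None]
        ax.plot(
            [r.sampled_bases for r in good],
            [r.estimate_bp / 1e6 for r in good],
            "o-",
        )
        ax.axhline(self.genome_size_bp / 1e6, linestyle="--", color="grey")
        ax.set_xlabel("sampled aligned bases")
        ax.set_ylabel("estimated genome size (Mbp)")
        ax.set_xscale("log")
        return ax

    def __repr__(self) -> str:
        return (
            f"<GenomeSizeResults N={self._result.genome_size_rounded_bp} bp, "
            f"C={self._result.average_coverage:.3f} ({self._result.mode}), "
            f"L={self._result.total_aligned_bases}>"
        )
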