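"""TSV and log rendering for estimates, saturation sweeps, and ploidy.

Data files (TSV) and logs are strictly separated: TSVs carry no
timestamps or paths, so two runs with identical inputs and seeds are
byte-identical and diff-stable; provenance (versions, input digests,
parameters, timestamps) lives in the accompanying log.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

from .estimator import EstimateResult, SaturationRow
from .ploidy import PloidyReport

ESTIMATE_HEADER = (
    "genome_size_bp\tgenome_size_Mbp\ttotal_aligned_bases\taverage_coverage\t"
    "mode\tregion_positions\tblacklisted\texcluded\tblacklist_factor"
)
SATURATION_HEADER = "fraction\tsampled_bases\testimate_bp\twithin_tolerance"


@dataclass
class RunManifest:
    """Everything needed to re-run: version, inputs + digests, parameters."""

    tool_version: str
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    parameters: dict[str, object] = field(default_factory=dict)
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    @classmethod
    def collect(
        cls, version: str, input_paths: Sequence[str | Path], parameters: Mapping[str, object]
    ) -> "RunManifest":
        digests = {}
        for path in input_paths:
            h = hashlib.sha256()
            with open(path, "rb") as handle:
                for chunk in iter(lambda: handle.read(1 << 16), b""):
                    h.update(chunk)
            digests[str(path)] = h.hexdigest()
        return cls(version, digests, dict(parameters))

    def render(self) -> str:
        lines = [f"tool version: {self.tool_version}", f"run at: {self.created}"]
        for path, digest in self.inputs.items():
            lines.append(f"input: {path} sha256={digest}")
        for key in sorted(self.parameters):
            lines.append(f"param: {key}={self.parameters[key]}")
        return "\n".join(lines) + "\n"


def _id_list(ids: frozenset[str] | set[str]) -> str:
    return ",".join(sorted(ids)) if ids else "-"


def render_estimate(result: EstimateResult, manifest: RunManifest) -> tuple[str, str]:
    """Single-row estimate TSV plus a provenance log."""
    factor = "-" if result.blacklist_factor is None else str(result.blacklist_factor)
    row = "\t".join(
        [
            str(result.genome_size_rounded_bp),
            f"{result.genome_size_bp / 1e6:.2f}",
            str(result.total_aligned_bases),
            str(result.average_coverage),
            result.mode,
            str(result.region_positions),
            _id_list(result.blacklisted),
            _id_list(result.excluded),
            factor,
        ]
    )
    tsv = f"{ESTIMATE_HEADER}\n{row}\n"
    log = manifest.render() + (
        f"estimate: N={result.genome_size_bp} bp ({result.genome_size_mbp:.2f} Mbp), "
        f"L={result.total_aligned_bases}, C={result.average_coverage} ({result.mode})\n"
        f"blacklisted: {_id_list(result.blacklisted)}\n"
        f"excluded: {_id_list(result.excluded)}\n"
    )
    return tsv, log


def render_saturation(
    rows: Sequence[SaturationRow], minimum_bases: int | None, manifest: RunManifest
) -> str:
    """Saturation sweep TSV with a ``# minimum_bases=`` footer comment."""
    out = [SATURATION_HEADER]
    for row in rows:
        estimate = "NA" if row.estimate_bp is None else str(row.estimate_bp)
        within = "true" if (row.estimate_bp is not None and row.within_tolerance) else "false"
        out.append(f"{row.fraction}\t{row.sampled_bases}\t{estimate}\t{within}")
    out.append(f"# minimum_bases={minimum_bases if minimum_bases is not None else 'NA'}")
    return "\n".join(out) + "\n"


def render_ploidy(report: PloidyReport, manifest: RunManifest) -> tuple[str, str]:
    """Histogram TSV (copy_number, busco_ids) plus the derived numbers."""
    out = ["copy_number\tbusco_ids"]
    for copies in sorted(report.histogram):
        out.append(f"{copies}\t{report.histogram[copies]}")
    out.append(f"# pseudo_ploidy={report.pseudo_ploidy}")
    out.append(f"# recommended_blacklist_factor={report.recommended_blacklist_factor}")
    tsv = "\n".join(out) + "\n"
    log = manifest.render() + (
        f"pseudo ploidy: {report.pseudo_ploidy}\n"
        f"recommended blacklist factor: {report.recommended_blacklist_factor}\n"
    )
    return tsv, log
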