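"""Pseudo-ploidy inference from BUSCO gene duplication.

Single-copy orthologs should appear exactly once per haploid genome. In
an assembly that separately represents p haplotypes (or subgenomes), most
of them instead appear p times. The copy-number histogram of BUSCO genes
therefore peaks at the assembly's effective ploidy; its mode is reported
as a "pseudo ploidy number" p, and the recommended high-coverage
blacklist factor is scaled to 1.5 × p so that p-fold-covered sequences
are not discarded as outliers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .exceptions import EstimationError
from .io import BuscoTable

_COUNTED = {"Complete", "Duplicated"}


@dataclass(frozen=True)
class PloidyReport:
    histogram: dict[int, int]
    pseudo_ploidy: int
    recommended_blacklist_factor: float


def copy_number_histogram(table: BuscoTable) -> dict[int, int]:
    """copy number -> count of BUSCO ids with that many Complete/Duplicated hits.

    Fragmented and Missing records contribute nothing: partial hits are
    unreliable copy evidence, so ids with only such records are dropped.
    """
    copies: Counter[str] = Counter()
    for rec in table:
        if rec.status in _COUNTED:
            copies[rec.busco_id] += 1
    if not copies:
        raise EstimationError("no Complete or Duplicated BUSCO records")
    histogram: Counter[int] = Counter(copies.values())
    return dict(sorted(histogram.items()))


def pseudo_ploidy(histogram: dict[int, int]) -> int:
    """The modal copy number; ties break toward the smaller copy number
    (conservative — lower ploidy keeps the blacklist stricter)."""
    if not histogram:
        raise EstimationError("empty copy-number histogram")
    best = max(histogram.values())
    return min(k for k, v in histogram.items() if v == best)


def recommended_blacklist_factor(p: int) -> float:
    """1.5 × pseudo ploidy: raises the high-coverage cutoff so that
    sequences covered p-fold by construction survive the filter."""
    if p < 1:
        raise EstimationError("ploidy must be >= 1")
    return 1.5 * p


def infer_ploidy(table: BuscoTable) -> PloidyReport:
    """Histogram + pseudo ploidy + recommended factor in one call."""
    histogram = copy_number_histogram(table)
    p = pseudo_ploidy(histogram)
    return PloidyReport(histogram, p, recommended_blacklist_factor(p))


def plot_copy_number_histogram(report: PloidyReport, ax=None):
    """Bar plot of the BUSCO copy-number frequency distribution."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ks = sorted(report.histogram)
    ax.bar(ks, [report.histogram[k] for k in ks])
    ax.axvline(report.pseudo_ploidy, linestyle="--", color="grey")
    ax.set_xlabel("copies per BUSCO gene")
    ax.set_ylabel("BUSCO genes")
    ax.set_title(f"pseudo ploidy = {report.pseudo_ploidy}")
    return ax
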