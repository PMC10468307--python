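"""Associating dated gene emergence with the temperature record.

Emergence counts are histogrammed on node ages themselves (markers sit at
divergence times; no arbitrary time binning), tallied inside analysis windows
(e.g. the recent 10 or 13 MY), classified against detected warming intervals,
and compared between gene sets (de novo vs cancer-associated vs random) via
their peak nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .clade_inference import EmergenceEstimate
from .paleotemp import (
    TemperatureSeries,
    WarmingInterval,
    in_lwp,
    range_overlaps_lwp,
)

__all__ = [
    "GeneSet",
    "EmergenceSummary",
    "OverlapResult",
    "emergence_histogram",
    "window_count",
    "lwp_overlap",
    "peak_nodes",
    "export_overlay",
]

CATEGORIES = ("dated", "pre_root", "undetected", "no_signal")


@dataclass(frozen=True)
class GeneSet:
    """A labelled collection of query genes.

    Conventional labels are ``de_novo``, ``cancer`` and ``random``; anything
    else is treated as a custom set.  Within a set, ids are unique.
    """

    label: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted(
                {g for g in self.genes if self.genes.count(g) > 1}
            )
            raise ValueError(f"gene set {self.label!r} has duplicates: {dupes}")

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class EmergenceSummary:
    """Histogram of dated emergences per (node age, gene set) plus tallies."""

    #: columns: age_mya, set_label, count — one row per (node age, set)
    histogram: pd.DataFrame
    #: per set label: counts of dated / pre_root / undetected / no_signal
    tallies: dict[str, dict[str, int]]


def _split_by_set(
    estimates: Sequence[EmergenceEstimate], sets: Sequence[GeneSet]
) -> dict[str, list[EmergenceEstimate]]:
    by_gene = {e.gene: e for e in estimates}
    out: dict[str, list[EmergenceEstimate]] = {}
    for gs in sets:
        out[gs.label] = [by_gene[g] for g in gs.genes if g in by_gene]
    return out


def emergence_histogram(
    estimates: Sequence[EmergenceEstimate],
    sets: Sequence[GeneSet],
    allow_overlap: bool = False,
) -> EmergenceSummary:
    """Count dated genes per (node age, gene set).

    Genes whose category is not ``dated`` do not enter the histogram but are
    tallied.  Overlapping gene sets are rejected unless ``allow_overlap`` —
    mirroring study designs where e.g. the cancer set is drawn to not overlap
    the de novo set.
    """
    if not allow_overlap:
        seen: dict[str, str] = {}
        for gs in sets:
            for g in gs.genes:
                if g in seen:
                    raise ValueError(
                        f"gene {g!r} appears in sets {seen[g]!r} and "
                        f"{gs.label!r}; pass allow_overlap=True to permit"
                    )
                seen[g] = gs.label

    rows = []
    tallies: dict[str, dict[str, int]] = {}
    for label, ests in _split_by_set(estimates, sets).items():
        tallies[label] = {cat: 0 for cat in CATEGORIES}
        counts: dict[float, int] = {}
        for e in ests:
            tallies[label][e.category] += 1
            if e.category == "dated":
                counts[e.age] = counts.get(e.age, 0) + 1
        for age in sorted(counts, reverse=True):
            rows.append(
                {"age_mya": age, "set_label": label, "count": counts[age]}
            )
    histogram = pd.DataFrame(rows, columns=["age_mya", "set_label", "count"])
    return EmergenceSummary(histogram=histogram, tallies=tallies)


def window_count(
    estimates: Sequence[EmergenceEstimate],
    window: tuple[float, float],
    gene_set: GeneSet | None = None,
) -> int:
    """Number of dated genes with emergence age inside [min, max] MYA."""
    lo, hi = window
    if lo > hi:
        raise ValueError(f"window min {lo} exceeds max {hi}")
    members = set(gene_set.genes) if gene_set is not None else None
    return sum(
        1
        for e in estimates
        if e.category == "dated"
        and (members is None or e.gene in members)
        and lo <= e.age <= hi
    )


@dataclass
class OverlapResult:
    """Warming-interval classification of dated genes."""

    n_in: int
    n_out: int
    #: per dated gene: True if its emergence falls in (or, with ranges, its
    #: age range overlaps) a warming interval
    flags: dict[str, bool]


def lwp_overlap(
    estimates: Sequence[EmergenceEstimate],
    lwps: Sequence[WarmingInterval],
    use_ranges: bool = False,
    gene_set: GeneSet | None = None,
) -> OverlapResult:
    """Classify each dated gene as emerging inside or outside warming periods.

    By point age by default; with ``use_ranges``, a gene whose node carries an
    age confidence range counts as inside if the range overlaps any interval.
    """
    members = set(gene_set.genes) if gene_set is not None else None
    flags: dict[str, bool] = {}
    for e in estimates:
        if e.category != "dated":
            continue
        if members is not None and e.gene not in members:
            continue
        if use_ranges and e.age_range is not None:
            flags[e.gene] = range_overlaps_lwp(e.age_range, lwps)
        else:
            flags[e.gene] = in_lwp(e.age, lwps)
    n_in = sum(flags.values())
    return OverlapResult(n_in=n_in, n_out=len(flags) - n_in, flags=flags)


def peak_nodes(
    summary: EmergenceSummary, set_label: str, top_k: int = 1
) -> list[tuple[float, int]]:
    """The k node ages with the highest emergence counts for one set.

    Ties are broken toward the older age.  Returns at most as many entries as
    there are node ages with nonzero counts.
    """
    sub = summary.histogram[summary.histogram["set_label"] == set_label]
    ranked = sorted(
        zip(sub["age_mya"], sub["count"]),
        key=lambda item: (-item[1], -item[0]),
    )
    return [(float(a), int(c)) for a, c in ranked[:top_k]]


def export_overlay(
    summary: EmergenceSummary,
    series: TemperatureSeries,
    out_prefix,
    lwps: Sequence[WarmingInterval] = (),
    node_ranges: Mapping[float, tuple[float, float]] | None = None,
    fig_format: str = "png",
) -> tuple[Path, Path]:
    """Write the histogram TSV and the temperature/emergence overlay figure.

    Returns (tsv_path, figure_path).  The figure shows the Ts curve with
    per-set emergence counts as stems at their node ages, optional shading of
    warming intervals and of node age-confidence bands.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = out_prefix.with_suffix(".tsv")
    fig_path = out_prefix.with_suffix(f".{fig_format}")
    summary.histogram.to_csv(tsv_path, sep="\t", index=False)

    fig, ax_t = plt.subplots(figsize=(10, 4.5))
    ax_t.plot(series.ages, series.ts, color="0.5", lw=0.8, label="Ts")
    ax_t.set_xlabel("age (MYA)")
    ax_t.set_ylabel("global surface temperature (°C)")
    ax_t.invert_xaxis()
    for iv in lwps:
        ax_t.axvspan(iv.end_age, iv.start_age, color="tab:red", alpha=0.15)
    if node_ranges:
        for lo, hi in node_ranges.values():
            ax_t.axvspan(lo, hi, color="tab:green", alpha=0.12)

    if not summary.histogram.empty:
        ax_n = ax_t.twinx()
        ax_n.set_ylabel("emerged genes")
        for i, label in enumerate(sorted(summary.tallies)):
            sub = summary.histogram[summary.histogram["set_label"] == label]
            if sub.empty:
                continue
            markerline, stemlines, _ = ax_n.stem(
                sub["age_mya"], sub["count"], label=label, basefmt=" "
            )
            color = f"C{i}"
            plt.setp(markerline, color=color)
            plt.setp(stemlines, color=color)
        ax_n.legend(loc="upper left", fontsize="small")
    fig.tight_layout()
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    return tsv_path, fig_path
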