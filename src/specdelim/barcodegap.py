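"""Barcoding-gap detection.

Classifies every pairwise distance between unique haplotypes as
intra-lineage or inter-lineage under a lineage hypothesis and asks
whether the largest intra-lineage distance falls below the smallest
inter-lineage distance — the "barcoding gap".  No 10x-mean-intraspecific
threshold is applied; the decision is purely the order condition
``max_intra < min_inter``, reported with its interval.

Specific lineage pairs can be excluded to diagnose which comparison
destroys a gap: excluding pair {X, Y} removes the X–Y cross distances
and the intra distances of X and of Y, while the comparisons of X and Y
with every other lineage remain classified as inter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix
from .errors import NoOverlapError, NothingToCompareError
from .seqio import GroupingScheme


@dataclass(frozen=True)
class GapReport:
    """Outcome of one barcoding-gap analysis."""

    hypothesis: str
    locus: str
    intra: tuple[float, ...]
    inter: tuple[float, ...]
    n_excluded: int
    excluded_pairs: frozenset[frozenset[str]]
    singleton_lineages: tuple[str, ...]

    @property
    def max_intra(self) -> float:
        return max(self.intra) if self.intra else float("-inf")

    @property
    def min_inter(self) -> float:
        return min(self.inter) if self.inter else float("inf")

    @property
    def gap_exists(self) -> bool:
        return self.max_intra < self.min_inter

    @property
    def gap_interval(self) -> tuple[float, float] | None:
        """[max_intra, min_inter] when the gap exists, else None."""
        return (self.max_intra, self.min_inter) if self.gap_exists else None

    @property
    def overlap(self) -> float | None:
        """Magnitude max_intra - min_inter when the sets overlap."""
        return None if self.gap_exists else self.max_intra - self.min_inter

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "locus": self.locus,
            "n_intra": len(self.intra),
            "n_inter": len(self.inter),
            "n_excluded": self.n_excluded,
            "excluded_pairs": sorted(sorted(p) for p in self.excluded_pairs),
            "singleton_lineages": list(self.singleton_lineages),
            "max_intra": self.max_intra if self.intra else None,
            "min_inter": self.min_inter if self.inter else None,
            "gap_exists": self.gap_exists,
            "gap_interval": list(self.gap_interval) if self.gap_interval else None,
            "overlap": self.overlap,
        }


def gap_analysis(
    m: DistanceMatrix,
    g: GroupingScheme,
    exclude_pairs: Iterable[tuple[str, str]] = (),
    hypothesis: str | None = None,
    locus: str | None = None,
) -> GapReport:
    """Classify haplotype-pair distances and test for a barcoding gap.

    ``m`` should be computed on haplotype-collapsed sequences so that
    duplicate specimens do not inflate the intra set with zeros.  Every
    haplotype in ``m`` must be assigned to a lineage by ``g``.  A
    lineage with a single haplotype contributes no intra distances
    (allowed; listed in ``singleton_lineages``).
    """
    excluded = frozenset(frozenset(p) for p in exclude_pairs)
    for pair in excluded:
        if len(pair) != 2:
            raise ValueError(f"excluded pair must have two lineages: {sorted(pair)}")
    lineage_of = {sid: g.group_of(sid) for sid in m.ids}
    lineages = set(lineage_of.values())
    if len(lineages) < 2:
        raise NothingToCompareError(
            "a single lineage yields no inter-lineage distances"
        )
    excluded_lineages = frozenset().union(*excluded) if excluded else frozenset()

    intra: list[float] = []
    inter: list[float] = []
    n_excluded = 0
    counts: dict[str, int] = {}
    for sid in m.ids:
        counts[lineage_of[sid]] = counts.get(lineage_of[sid], 0) + 1
    for i, j in combinations(range(len(m.ids)), 2):
        li, lj = lineage_of[m.ids[i]], lineage_of[m.ids[j]]
        d = float(m.values[i, j])
        if li == lj:
            if li in excluded_lineages:
                n_excluded += 1
            else:
                intra.append(d)
        elif frozenset((li, lj)) in excluded:
            n_excluded += 1
        else:
            inter.append(d)
    singletons = tuple(sorted(l for l, c in counts.items() if c == 1))
    return GapReport(
        hypothesis=hypothesis or g.name,
        locus=locus or m.model,
        intra=tuple(intra),
        inter=tuple(inter),
        n_excluded=n_excluded,
        excluded_pairs=excluded,
        singleton_lineages=singletons,
    )


def overlap_fraction(report: GapReport) -> float:
    """Fraction of classified distances inside [min_inter, max_intra].

    Only meaningful when the intra and inter sets overlap; raises
    :class:`NoOverlapError` when a gap exists.
    """
    if report.gap_exists:
        raise NoOverlapError("intra and inter sets are disjoint")
    lo, hi = report.min_inter, report.max_intra
    pooled = report.intra + report.inter
    inside = sum(1 for d in pooled if lo <= d <= hi)
    return inside / len(pooled)


def classified_distances(report: GapReport) -> pd.DataFrame:
    """Long-form table of classified distances (for TSV export/plots)."""
    rows = [{"class": "intra", "distance": d} for d in report.intra]
    rows += [{"class": "inter", "distance": d} for d in report.inter]
    return pd.DataFrame(rows)


def plot_gap(report: GapReport, path: str | Path, bins: int = 40) -> None:
    """Histogram of intra (white) vs inter (grey) distances."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    pooled = np.array(report.intra + report.inter, dtype=float)
    edges = np.histogram_bin_edges(pooled, bins=bins) if pooled.size else 10
    ax.hist(
        report.intra,
        bins=edges,
        color="white",
        edgecolor="black",
        label="intra-lineage",
    )
    ax.hist(
        report.inter,
        bins=edges,
        color="grey",
        edgecolor="black",
        alpha=0.7,
        label="inter-lineage",
    )
    ax.set_xlabel("genetic distance")
    ax.set_ylabel("count")
    title = f"{report.hypothesis} / {report.locus}"
    if report.gap_exists:
        lo, hi = report.gap_interval
        title += f"  gap [{lo:.4f}, {hi:.4f}]"
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
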