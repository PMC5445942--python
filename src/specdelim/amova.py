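"""Hierarchical analysis of molecular variance (AMOVA).

Partitions molecular variance among groups (lineages), among populations
within groups, and within populations, from squared pairwise molecular
distances, following the classic nested decomposition with
unequal-sample-size coefficients.  Produces the fixation-index
analogues

    phi_ST = (sigma_a^2 + sigma_b^2) / sigma_total^2
    phi_SC =  sigma_b^2 / (sigma_b^2 + sigma_c^2)
    phi_CT =  sigma_a^2 / sigma_total^2

and the phi_CT plateau criterion used to choose the number of lineages:
among candidate arrangements with increasing group counts k, the
selected k is the smallest one beyond which no coarser-to-finer step
gains more than a threshold tau of phi_CT per added lineage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix
from .errors import (
    EmptyGroupError,
    InvalidHierarchyError,
    NoCandidatesError,
    NoMolecularVariationError,
)
from .seqio import GroupingScheme

DELTA_SQ_MODES = ("count_of_differences", "squared_distance")


@dataclass(frozen=True)
class AmovaResult:
    """Variance components and phi-statistics for one arrangement."""

    arrangement: str
    k: int
    ssd_ag: float  # among groups
    ssd_ap_wg: float  # among populations within groups
    ssd_wp: float  # within populations
    df_ag: int
    df_ap_wg: int
    df_wp: int
    sigma_a: float  # among-group variance component
    sigma_b: float  # among-population-within-group component
    sigma_c: float  # within-population component
    phi_st: float
    phi_sc: float
    phi_ct: float
    negative_component: bool = False
    winker_benchmark: bool = False  # phi_CT > 0.95 diagnostic only

    @property
    def total_variance(self) -> float:
        return self.sigma_a + self.sigma_b + self.sigma_c

    def to_dict(self) -> dict:
        return {
            "arrangement": self.arrangement,
            "k": self.k,
            "SSD_AG": self.ssd_ag,
            "SSD_AP_WG": self.ssd_ap_wg,
            "SSD_WP": self.ssd_wp,
            "df_AG": self.df_ag,
            "df_AP_WG": self.df_ap_wg,
            "df_WP": self.df_wp,
            "sigma_a2": self.sigma_a,
            "sigma_b2": self.sigma_b,
            "sigma_c2": self.sigma_c,
            "phi_ST": self.phi_st,
            "phi_SC": self.phi_sc,
            "phi_CT": self.phi_ct,
            "negative_component": self.negative_component,
            "winker_benchmark": self.winker_benchmark,
        }


def _delta_sq(m: DistanceMatrix, mode: str) -> np.ndarray:
    if mode == "count_of_differences":
        # p-distances scaled back to per-pair difference counts; for a
        # matrix already holding counts this is the identity (sites=1).
        return m.values * m.sites_used
    if mode == "squared_distance":
        return m.values**2
    raise ValueError(f"unknown delta_sq mode {mode!r}")


def amova_components(
    m: DistanceMatrix,
    g: GroupingScheme,
    delta_sq: str = "count_of_differences",
) -> AmovaResult:
    """Nested AMOVA variance components and phi-statistics.

    ``delta_sq`` selects the squared molecular distance between two
    individuals: the count of differing sites (molecular-distance AMOVA,
    the default) or the square of the stored distance.

    Negative variance-component estimates are retained as-is and
    flagged, never truncated at zero.  phi_CT is NaN for a single
    group; phi_SC is NaN when sigma_b^2 + sigma_c^2 = 0.
    """
    scheme = g.restrict(m.ids)
    by_group = scheme.populations_by_group()
    if not by_group:
        raise EmptyGroupError("no specimens of the scheme occur in the matrix")
    for grp, pops in by_group.items():
        if not pops:
            raise EmptyGroupError(f"group {grp!r} empty")

    d2 = _delta_sq(m, delta_sq)
    pos = {sid: i for i, sid in enumerate(m.ids)}

    n_total = sum(len(v) for pops in by_group.values() for v in pops.values())
    n_groups = len(by_group)
    n_pops = sum(len(pops) for pops in by_group.values())

    def ss(idx: np.ndarray) -> float:
        """Sum over unordered pairs of delta^2 divided by group size."""
        sub = d2[np.ix_(idx, idx)]
        return float(sub.sum() / (2.0 * len(idx)))

    assigned = np.array([pos[s] for s in scheme.mapping], dtype=int)
    ssd_total = ss(assigned)
    if ssd_total == 0.0:
        raise NoMolecularVariationError(
            "all sequences identical: phi statistics undefined"
        )

    ssd_wp = 0.0
    ssd_wg = 0.0
    for grp, pops in by_group.items():
        g_idx = np.array([pos[s] for ms in pops.values() for s in ms], dtype=int)
        ssd_wg += ss(g_idx)
        for members in pops.values():
            ssd_wp += ss(np.array([pos[s] for s in members], dtype=int))
    ssd_ap_wg = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_ag = n_groups - 1
    df_ap_wg = n_pops - n_groups
    df_wp = n_total - n_pops

    # unequal-sample-size coefficients of the expected mean squares
    pop_sizes = {
        (grp, p): len(ms)
        for grp, pops in by_group.items()
        for p, ms in pops.items()
    }
    grp_sizes = {grp: sum(len(ms) for ms in pops.values()) for grp, pops in by_group.items()}
    sum_np2_over_ng = sum(
        sum(len(ms) ** 2 for ms in pops.values()) / grp_sizes[grp]
        for grp, pops in by_group.items()
    )
    sum_np2_over_n = sum(v**2 for v in pop_sizes.values()) / n_total
    sum_ng2_over_n = sum(v**2 for v in grp_sizes.values()) / n_total

    n1 = (n_total - sum_np2_over_ng) / df_ap_wg if df_ap_wg > 0 else 0.0
    n2 = (sum_np2_over_ng - sum_np2_over_n) / df_ag if df_ag > 0 else 0.0
    n3 = (n_total - sum_ng2_over_n) / df_ag if df_ag > 0 else 0.0

    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
    if df_ap_wg > 0 and n1 > 0:
        msd_ap = ssd_ap_wg / df_ap_wg
        sigma_b = (msd_ap - sigma_c) / n1
    else:
        sigma_b = 0.0
    if df_ag > 0 and n3 > 0:
        msd_ag = ssd_ag / df_ag
        sigma_a = (msd_ag - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = math.nan

    negative = (sigma_b < 0) or (not math.isnan(sigma_a) and sigma_a < 0)
    if negative:
        warnings.warn(
            f"{g.name}: negative variance component estimate retained",
            stacklevel=2,
        )

    total = sigma_a + sigma_b + sigma_c  # NaN propagates for k = 1
    phi_ct = sigma_a / total if total != 0 else math.nan
    phi_st = (sigma_a + sigma_b) / total if total != 0 else math.nan
    bc = sigma_b + sigma_c
    phi_sc = sigma_b / bc if bc != 0 else math.nan

    return AmovaResult(
        arrangement=g.name,
        k=n_groups,
        ssd_ag=ssd_ag,
        ssd_ap_wg=ssd_ap_wg,
        ssd_wp=ssd_wp,
        df_ag=df_ag,
        df_ap_wg=df_ap_wg,
        df_wp=df_wp,
        sigma_a=sigma_a,
        sigma_b=sigma_b,
        sigma_c=sigma_c,
        phi_st=phi_st,
        phi_sc=phi_sc,
        phi_ct=phi_ct,
        negative_component=negative,
        winker_benchmark=bool(phi_ct > 0.95) if not math.isnan(phi_ct) else False,
    )


def permutation_pvalue(
    m: DistanceMatrix,
    g: GroupingScheme,
    delta_sq: str = "count_of_differences",
    permutations: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for phi_CT (whole populations shuffled among groups).

    Offered as an optional diagnostic; the plateau criterion, not the
    p-value, drives lineage selection.
    """
    observed = amova_components(m, g, delta_sq).phi_ct
    rng = np.random.default_rng(seed)
    pops = sorted(g.restrict(m.ids).populations())
    group_of_pop = {
        pop: grp for _sid, (grp, pop) in g.restrict(m.ids).mapping.items()
    }
    labels = [group_of_pop[p] for p in pops]
    hits = 0
    for _ in range(permutations):
        perm = list(labels)
        rng.shuffle(perm)
        mapping = {
            sid: (perm[pops.index(pop)], pop)
            for sid, (_grp, pop) in g.restrict(m.ids).mapping.items()
        }
        try:
            stat = amova_components(
                m, GroupingScheme("perm", mapping), delta_sq
            ).phi_ct
        except NoMolecularVariationError:  # pragma: no cover - guarded above
            continue
        if stat >= observed:
            hits += 1
    return (hits + 1) / (permutations + 1)


# ---------------------------------------------------------------------------
# candidate arrangements


def enumerate_candidate_arrangements(
    levels: Sequence[Mapping[str, str]],
    populations: Mapping[str, Sequence[str]],
    names: Sequence[str] | None = None,
) -> list[GroupingScheme]:
    """Build one GroupingScheme per hierarchy level, coarse to fine.

    ``levels`` maps population id -> group label, ordered from the
    coarsest arrangement to the finest; each finer level must refine the
    previous one (no fine cell may span two coarse cells).
    ``populations`` maps population id -> member specimen ids and is held
    fixed across arrangements.
    """
    if not levels:
        raise NoCandidatesError("no arrangements supplied")
    schemes = []
    for li, level in enumerate(levels):
        missing = set(populations) - set(level)
        if missing:
            raise InvalidHierarchyError(
                f"level {li}: populations without group label {sorted(missing)}"
            )
        if li > 0:
            prev = levels[li - 1]
            parent: dict[str, str] = {}
            for pop in populations:
                fine, coarse = level[pop], prev[pop]
                if parent.setdefault(fine, coarse) != coarse:
                    raise InvalidHierarchyError(
                        f"level {li}: group {fine!r} spans coarse groups "
                        f"{parent[fine]!r} and {coarse!r}"
                    )
        name = names[li] if names else f"k{len(set(level.values()))}"
        mapping = {
            sid: (level[pop], pop)
            for pop, sids in populations.items()
            for sid in sids
        }
        schemes.append(GroupingScheme(name, mapping))
    return schemes


def read_arrangement_table(
    path: str | Path, populations: Mapping[str, Sequence[str]]
) -> list[GroupingScheme]:
    """Read a candidate-arrangement TSV (rows = populations, one column
    per arrangement, cells = group labels) into GroupingSchemes.

    Columns are taken in file order; nesting is NOT required here, since
    published arrangement tables may include non-nested alternatives.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    schemes = []
    for col in df.columns:
        level = df[col].dropna().to_dict()
        mapping = {
            sid: (level[pop], pop)
            for pop, sids in populations.items()
            if pop in level
            for sid in sids
        }
        schemes.append(GroupingScheme(str(col), mapping))
    return schemes


def published_phi_ct_series() -> dict[str, dict[int, float]]:
    """The published Queensland phi_CT series (COI and 16S) shipped with
    the package, keyed locus -> {candidate k -> phi_CT}.

    These are the AMOVA estimates for the candidate lineage arrangements
    of the *Tenuibranchiurus* dataset at k = 2, 3, 5, 6, 8, 10, 11, 13,
    used as the reference input for plateau selection.
    """
    from importlib.resources import files

    path = files("specdelim").joinpath("data/qld_phi_ct.tsv")
    df = pd.read_csv(path, sep="\t")
    return {
        str(locus): dict(zip(sub["k"].astype(int), sub["phi_ct"].astype(float)))
        for locus, sub in df.groupby("locus")
    }


# ---------------------------------------------------------------------------
# plateau selection


@dataclass(frozen=True)
class PlateauSelection:
    """Result of the phi_CT plateau criterion."""

    candidates: tuple[int, ...]
    series: dict[str, dict[int, float]]
    tau: float
    per_locus_k: dict[str, int]
    no_plateau: dict[str, bool]
    selected_k: int | None
    discordant: bool

    def to_dict(self) -> dict:
        return {
            "candidates": list(self.candidates),
            "tau": self.tau,
            "per_locus_k": self.per_locus_k,
            "no_plateau": self.no_plateau,
            "selected_k": self.selected_k,
            "discordant": self.discordant,
        }


def _select_one(series: Mapping[int, float], tau: float) -> tuple[int, bool]:
    ks = sorted(series)
    for k in ks[:-1]:
        if all(
            (series[kp] - series[k]) / (kp - k) < tau for kp in ks if kp > k
        ):
            return k, False
    # the largest k qualifies only vacuously: no plateau was reached
    return ks[-1], True


def select_plateau(
    series: Mapping[str, Mapping[int, float]], tau: float = 0.02
) -> PlateauSelection:
    """Select the number of lineages at which phi_CT plateaus.

    Per locus, the selected k is the smallest candidate such that every
    larger candidate k' gains less than ``tau`` phi_CT per added lineage:
    (phi_CT(k') - phi_CT(k)) / (k' - k) < tau.  If no candidate
    qualifies the largest is returned with a no-plateau flag.  The joint
    selection requires the same k across loci, otherwise the result is
    flagged discordant and ``selected_k`` is None.
    """
    if not series or any(not s for s in series.values()):
        raise NoCandidatesError("empty phi_CT series")
    candidate_sets = {tuple(sorted(s)) for s in series.values()}
    if len(candidate_sets) != 1:
        raise NoCandidatesError("loci disagree on candidate k values")
    candidates = candidate_sets.pop()
    if len(candidates) < 2:
        raise NoCandidatesError("need at least 2 candidate k values")
    for locus, s in series.items():
        if any(not np.isfinite(v) for v in s.values()):
            raise ValueError(f"{locus}: non-finite phi_CT in series")

    per_locus_k: dict[str, int] = {}
    no_plateau: dict[str, bool] = {}
    for locus, s in series.items():
        k, flag = _select_one(s, tau)
        per_locus_k[locus] = k
        no_plateau[locus] = flag
    ks = set(per_locus_k.values())
    discordant = len(ks) > 1
    return PlateauSelection(
        candidates=tuple(candidates),
        series={loc: dict(s) for loc, s in series.items()},
        tau=tau,
        per_locus_k=per_locus_k,
        no_plateau=no_plateau,
        selected_k=None if discordant else ks.pop(),
        discordant=discordant,
    )


def plot_plateau(selection: PlateauSelection, path: str | Path) -> None:
    """phi_CT versus candidate k, one series per locus, with the
    selected k marked by a dotted vertical line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    markers = ["o", "s", "^", "D"]
    for i, (locus, s) in enumerate(selection.series.items()):
        ks = sorted(s)
        ax.plot(
            ks,
            [s[k] for k in ks],
            marker=markers[i % len(markers)],
            fillstyle="none" if i % 2 == 0 else "full",
            color="black",
            label=locus,
        )
    if selection.selected_k is not None:
        ax.axvline(selection.selected_k, linestyle=":", color="grey")
    ax.set_xlabel("number of lineages (k)")
    ax.set_ylabel(r"$\phi_{CT}$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
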