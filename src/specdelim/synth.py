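"""Seeded simulator of multi-lineage, multi-locus alignments.

Generates the kind of data the delimitation pipeline consumes: several
lineages, each holding one or more populations with unequal sample
sizes, typed at fast mitochondrial-style loci and slower nuclear-style
loci, with per-specimen missing loci.

Sequences evolve by Jukes–Cantor substitution "sprinkling" along a star
phylogeny: a root sequence is drawn uniformly; each lineage ancestor is
derived from the root by substituting each site independently with a
branch-specific probability (substituted sites receive a uniformly
chosen different base); populations and specimens add their own
sprinkles.  Under this scheme the expected observed p-distance between
two sequences separated by sprinkles q1, q2, ... composes as

    E[p] = q1 (+) q2 (+) ...,   where  a (+) b = a + b - (4/3) a b,

i.e. 1 - (4/3) E[p] multiplies across branches, so branch probabilities
can be chosen to hit target within-lineage diversities and net
between-lineage distances exactly in expectation:

* within a population, two specimens should differ at a fraction
  pi_w * rate of sites, so each specimen branch gets m with
  m (+) m = pi_w * rate;
* between lineages, the NET distance (between mean minus average of the
  within means) should equal D_ij * rate; since within-sprinkles act on
  both sides, net = A_ij * (1 - (4/3) c) with c the within-pair
  expectation, so the ancestor-pair divergence target is
  A_ij = D_ij * rate / (1 - (4/3) c), and branch lengths solving
  u_i + u_j = -log(1 - (4/3) A_ij) are fitted by least squares on the
  star tree (exact whenever the divergence matrix is star-realisable,
  e.g. any 2-lineage design or a constant D).

Population offsets add private substitutions between populations of the
same lineage; they inflate within-lineage (not within-population) means
and so trade off against the exact net calibration, which is stated for
``pop_divergence = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SaturationError
from .seqio import Alignment, GroupingScheme

_BASES = np.array(list("ACGT"), dtype="U1")

MT_NU_RATE_RATIO = 5.0  # mitochondrial loci evolve ~5x faster than nuclear


@dataclass(frozen=True)
class LocusConfig:
    name: str
    length: int
    rate: float = 1.0  # relative substitution rate (mtDNA-scale = 1)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"locus {self.name}: length must be >= 1")
        if self.rate <= 0:
            raise ValueError(f"locus {self.name}: rate must be > 0")


@dataclass(frozen=True)
class LineageConfig:
    name: str
    populations: Mapping[str, int]  # population id -> sample size
    pi_w: float = 0.005  # target within-population pairwise diversity

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi_w <= 0.1):
            raise ValueError(f"lineage {self.name}: pi_w must be in [0, 0.1]")
        if not self.populations:
            raise ValueError(f"lineage {self.name}: needs >= 1 population")
        for pop, n in self.populations.items():
            if n < 1:
                raise ValueError(f"population {pop}: sample size must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated dataset."""

    seed: int
    loci: tuple[LocusConfig, ...]
    lineages: tuple[LineageConfig, ...]
    divergence: np.ndarray  # expected net substitutions/site between lineages
    missing_prob: float = 0.0  # per specimen x locus dropout probability
    pop_divergence: float = 0.0  # private divergence between sister populations

    def __post_init__(self) -> None:
        k = len(self.lineages)
        D = np.asarray(self.divergence, dtype=float)
        if D.shape != (k, k):
            raise ValueError(f"divergence matrix must be {k}x{k}")
        if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
            raise ValueError("divergence matrix must be symmetric, zero diagonal")
        if (D < 0).any():
            raise ValueError("divergences must be non-negative")
        if not (0.0 <= self.missing_prob < 1.0):
            raise ValueError("missing_prob must be in [0, 1)")
        if self.pop_divergence < 0:
            raise ValueError("pop_divergence must be non-negative")
        max_rate = max(l.rate for l in self.loci)
        worst = (
            (D.max(initial=0.0) + max(l.pi_w for l in self.lineages) + self.pop_divergence)
            * max_rate
        )
        if worst >= 0.75:
            raise SaturationError(
                f"expected distances reach {worst:.3f} >= 0.75: infeasible config"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        """Load a configuration from a plain-text YAML file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        loci = tuple(LocusConfig(**l) for l in raw["loci"])
        lineages = tuple(
            LineageConfig(
                name=l["name"],
                populations=dict(l["populations"]),
                pi_w=float(l.get("pi_w", 0.005)),
            )
            for l in raw["lineages"]
        )
        return cls(
            seed=int(raw["seed"]),
            loci=loci,
            lineages=lineages,
            divergence=np.asarray(raw["divergence"], dtype=float),
            missing_prob=float(raw.get("missing_prob", 0.0)),
            pop_divergence=float(raw.get("pop_divergence", 0.0)),
        )


@dataclass(frozen=True)
class SimResult:
    alignments: dict[str, Alignment]
    specimens: pd.DataFrame
    truth: GroupingScheme


def _compose(a: float, b: float) -> float:
    """Expected-p-distance composition a (+) b = a + b - 4ab/3."""
    return a + b - 4.0 * a * b / 3.0


def _branch_prob_for_pair_target(c: float) -> float:
    """m such that m (+) m = c (target within-pair expected p-distance)."""
    if c == 0.0:
        return 0.0
    return 0.75 * (1.0 - np.sqrt(1.0 - 4.0 * c / 3.0))


def _star_branch_probs(A: np.ndarray) -> np.ndarray:
    """Per-lineage sprinkle probabilities realising pairwise targets A.

    Solves u_i + u_j = -log(1 - 4 A_ij / 3) by least squares on the star
    phylogeny (exact for 2 lineages or constant A), then maps back with
    q_i = (3/4)(1 - exp(-u_i)).  Negative solutions are clipped at 0.
    """
    k = A.shape[0]
    if k == 1:
        return np.zeros(1)
    b = []
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            row = np.zeros(k)
            row[i] = row[j] = 1.0
            rows.append(row)
            b.append(-np.log1p(-4.0 * A[i, j] / 3.0))
    u, *_ = np.linalg.lstsq(np.array(rows), np.array(b), rcond=None)
    u = np.clip(u, 0.0, None)
    return 0.75 * (1.0 - np.exp(-u))


def _sprinkle(seq: np.ndarray, q: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability q to a uniform other base."""
    if q <= 0.0:
        return seq.copy()
    out = seq.copy()
    hits = rng.random(seq.size) < q
    n_hits = int(hits.sum())
    if n_hits:
        out[hits] = (out[hits] + rng.integers(1, 4, size=n_hits)) % 4
    return out


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Generate alignments, a specimen table and the true grouping.

    Deterministic: identical config and seed give byte-identical
    sequences and tables.
    """
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.lineages)
    D = np.asarray(cfg.divergence, dtype=float)

    # specimen roster (fixed across loci)
    specimens: list[tuple[str, str, str]] = []  # (specimen, population, lineage)
    for lin in cfg.lineages:
        for pop, n in lin.populations.items():
            for i in range(1, n + 1):
                specimens.append((f"{pop}_{i:02d}", pop, lin.name))
    truth = GroupingScheme(
        "truth", {sid: (lin, pop) for sid, pop, lin in specimens}
    )

    alignments: dict[str, Alignment] = {}
    present: dict[str, dict[str, bool]] = {sid: {} for sid, _, _ in specimens}
    for locus in cfg.loci:
        L, r = locus.length, locus.rate
        root = rng.integers(0, 4, size=L, dtype=np.int8)

        # exact-in-expectation calibration (see module docstring)
        seqs: dict[str, np.ndarray] = {}
        lineage_anc: dict[str, np.ndarray] = {}
        A = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                c_i = cfg.lineages[i].pi_w * r
                c_j = cfg.lineages[j].pi_w * r
                c_bar = (c_i + c_j) / 2.0
                A[i, j] = A[j, i] = min(
                    D[i, j] * r / max(1.0 - 4.0 * c_bar / 3.0, 1e-9), 0.7499
                )
        q_lineage = _star_branch_probs(A)
        for li, lin in enumerate(cfg.lineages):
            lineage_anc[lin.name] = _sprinkle(root, float(q_lineage[li]), rng)

        for li, lin in enumerate(cfg.lineages):
            m = _branch_prob_for_pair_target(lin.pi_w * r)
            # private population branches: half the pairwise offset each
            q_pop = _branch_prob_for_pair_target(cfg.pop_divergence * r)
            for pop in lin.populations:
                pop_anc = _sprinkle(lineage_anc[lin.name], q_pop, rng)
                for sid, spop, slin in specimens:
                    if slin == lin.name and spop == pop:
                        seqs[sid] = _sprinkle(pop_anc, m, rng)

        # per-specimen missing loci
        keep_ids = []
        for sid, _pop, _lin in specimens:
            keep = cfg.missing_prob == 0.0 or rng.random() >= cfg.missing_prob
            present[sid][locus.name] = keep
            if keep:
                keep_ids.append(sid)
        if len(keep_ids) < 2:  # keep the locus analysable
            keep_ids = [sid for sid, _, _ in specimens[:2]]
            for sid in keep_ids:
                present[sid][locus.name] = True
        alignments[locus.name] = Alignment(
            locus.name,
            tuple(keep_ids),
            tuple("".join(_BASES[seqs[sid]]) for sid in keep_ids),
        )

    table = pd.DataFrame(
        [
            {
                "specimen_id": sid,
                "locality_id": pop,
                "population_id": pop,
                "lineage": lin,
                **{
                    f"has_{locus.name}": int(present[sid][locus.name])
                    for locus in cfg.loci
                },
            }
            for sid, pop, lin in specimens
        ]
    )
    return SimResult(alignments=alignments, specimens=table, truth=truth)


def study_like_config(
    seed: int,
    n_regions: int = 2,
    lineages_per_region: Sequence[int] = (6, 2),
    within_region_divergence: float = 0.08,
    between_region_divergence: float = 0.16,
    pi_w: float = 0.005,
    pop_divergence: float = 0.01,
    missing_prob: float = 0.1,
) -> SimConfig:
    """A default configuration shaped like the crayfish study system.

    Eight lineages in two geographic regions (six in one, two in the
    other), each lineage one to three populations with unequal sample
    sizes, two fast mitochondrial-style loci (644 and 449 sites) and one
    slower nuclear-style locus, moderate within-lineage diversity and an
    order of magnitude more divergence between lineages.
    """
    sizes_cycle = [(10, 4), (14, 7, 4), (4,), (1,), (7, 7), (8, 7), (13,), (13, 9, 2)]
    lineages: list[LineageConfig] = []
    region_of: list[int] = []
    idx = 0
    for region, count in enumerate(lineages_per_region[:n_regions]):
        for _ in range(count):
            sizes = sizes_cycle[idx % len(sizes_cycle)]
            name = f"L{idx + 1}"
            pops = {f"{name}P{p + 1}": n for p, n in enumerate(sizes)}
            lineages.append(LineageConfig(name=name, populations=pops, pi_w=pi_w))
            region_of.append(region)
            idx += 1
    k = len(lineages)
    D = np.full((k, k), within_region_divergence)
    for i in range(k):
        for j in range(k):
            if region_of[i] != region_of[j]:
                D[i, j] = between_region_divergence
    np.fill_diagonal(D, 0.0)
    loci = (
        LocusConfig("coi", 644, 1.0),
        LocusConfig("16s", 449, 0.7),
        LocusConfig("gapdh", 563, 1.0 / MT_NU_RATE_RATIO),
    )
    return SimConfig(
        seed=seed,
        loci=loci,
        lineages=tuple(lineages),
        divergence=D,
        missing_prob=missing_prob,
        pop_divergence=pop_divergence,
    )
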