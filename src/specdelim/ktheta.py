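"""The K/theta (4X-rule) lineage validation test.

For each clade, the mean within-clade uncorrected p-distance d gives the
nucleotide diversity

    pi = d * n / (n - 1)

(the small-sample correction for n sampled sequences), and the
population-scaled diversity parameter

    theta = pi / (1 - 4 * pi / 3)

(theta = 2*Ne*mu for mitochondrial loci; the Jukes–Cantor-style
denominator corrects pi for multiple hits).  When d = 0 the upper-bound
fallback pi = 2 / (L * (n - 1)) is used, where L is the number of sites
analysed — the diversity that one segregating site among the sampled
sequences would have produced.

Between sister clades, K is the uncorrected net between-group mean
distance.  The test statistic is K divided by the LARGER theta of the
pair (the conservative choice); a ratio above 4 means the clades are too
divergent to be explained by drift within a single species, and they
are accepted as distinct lineages.  When a clade's sister is ambiguous
(a polytomy), K is computed to every candidate and the clade with the
smallest K is taken as the sister.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distmat import DistanceMatrix
from .errors import (
    InsufficientSampleError,
    NoCandidatesError,
    ThetaUndefinedError,
)

FOUR_X_THRESHOLD = 4.0


@dataclass(frozen=True)
class CladeDiversity:
    """Within-clade diversity summary for one clade at one locus."""

    clade: str
    n: int
    d: float
    pi: float
    theta: float
    zero_d_flag: bool
    L: int


@dataclass(frozen=True)
class KThetaResult:
    """One sister-pair K/theta comparison."""

    focal: str
    sister: str
    K: float
    theta_max: float
    ratio: float
    distinct: bool
    singleton_theta: bool = False  # a singleton clade contributed no theta

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "sister": self.sister,
            "K": self.K,
            "theta_max": self.theta_max,
            "K_over_theta": self.ratio,
            "distinct": self.distinct,
            "singleton_theta": self.singleton_theta,
        }


def theta_from_pi(pi: float) -> float:
    """theta = pi / (1 - 4*pi/3); diverges as pi approaches 3/4."""
    if pi < 0:
        raise ValueError("pi must be non-negative")
    if pi >= 0.75:
        raise ThetaUndefinedError(f"pi = {pi} >= 3/4: theta undefined")
    return pi / (1.0 - 4.0 * pi / 3.0)


def clade_diversity(
    m: DistanceMatrix,
    members: Sequence[str],
    L: int | None = None,
    clade: str = "",
    zero_d_fallback: str = "per_sequence",
) -> CladeDiversity:
    """Within-clade d, pi and theta from a p-distance matrix.

    Parameters
    ----------
    members : specimen ids of the clade (must be in the matrix).
    L : sites analysed; defaults to the matrix's ``sites_used``.
    zero_d_fallback : {"per_sequence", "per_pair"}
        Parse of the d = 0 fallback: ``pi = 2/(L*(n-1))`` (default) or
        ``pi = 2/(L*n*(n-1))``.

    Raises
    ------
    InsufficientSampleError
        d = 0 with n = 1 (the fallback divides by n - 1).
    ThetaUndefinedError
        pi >= 3/4.
    """
    if L is None:
        L = m.sites_used
    if L < 1:
        raise ValueError("L must be >= 1")
    members = list(members)
    n = len(members)
    if n < 1:
        raise ValueError("clade must have at least one member")
    if m.model != "p":
        warnings.warn(
            f"K/theta expects uncorrected p-distances, got model {m.model!r}",
            stacklevel=2,
        )
    idx = m.index_of(members)
    if n >= 2:
        sub = m.values[np.ix_(idx, idx)]
        d = float(sub[np.triu_indices(n, k=1)].mean())
    else:
        d = 0.0
    zero_d = d == 0.0
    if zero_d:
        if n < 2:
            raise InsufficientSampleError(
                f"clade {clade or members}: d = 0 fallback needs n >= 2 (n = {n})"
            )
        if zero_d_fallback == "per_sequence":
            pi = 2.0 / (L * (n - 1))
        elif zero_d_fallback == "per_pair":
            pi = 2.0 / (L * n * (n - 1))
        else:
            raise ValueError(f"unknown fallback {zero_d_fallback!r}")
    else:
        pi = d * n / (n - 1)
    return CladeDiversity(
        clade=clade or ",".join(members[:3]),
        n=n,
        d=d,
        pi=pi,
        theta=theta_from_pi(pi),
        zero_d_flag=zero_d,
        L=L,
    )


def resolve_sister_clade(
    focal: str,
    candidates: Iterable[str],
    clades: Mapping[str, Sequence[str]],
    m: DistanceMatrix,
) -> tuple[str, dict[str, float]]:
    """Choose the sister of ``focal`` among candidate clades by minimum K.

    K per candidate is the uncorrected net between-group mean distance.
    Ties are broken by clade id order, with a warning.  Returns the
    chosen sister and K for every candidate.
    """
    from .distmat import net_between
    from .seqio import GroupingScheme

    candidates = sorted(set(candidates) - {focal})
    if not candidates:
        raise NoCandidatesError(f"no sister candidates for clade {focal!r}")
    mapping = {
        sid: (cl, cl)
        for cl in [focal, *candidates]
        for sid in clades[cl]
    }
    scheme = GroupingScheme("sisters", mapping)
    ks = {c: net_between(m, scheme, focal, c) for c in candidates}
    best = min(ks.values())
    winners = [c for c in candidates if ks[c] == best]
    if len(winners) > 1:
        warnings.warn(
            f"clade {focal!r}: K tie among {winners}; choosing {winners[0]!r}",
            stacklevel=2,
        )
    return winners[0], ks


def ktheta_test(
    focal: CladeDiversity,
    sister: CladeDiversity,
    K: float,
    threshold: float = FOUR_X_THRESHOLD,
) -> KThetaResult:
    """Apply the 4X rule: distinct iff K / max(theta) > threshold.

    Symmetric in its two clade arguments.  ``theta_max = 0`` (both
    clades monomorphic with theta 0, which the fallback normally
    prevents) raises :class:`ThetaUndefinedError`.
    """
    theta_max = max(focal.theta, sister.theta)
    if theta_max == 0.0:
        raise ThetaUndefinedError(
            f"{focal.clade}/{sister.clade}: both thetas are zero; "
            f"K = {K} cannot be scaled"
        )
    ratio = K / theta_max
    return KThetaResult(
        focal=focal.clade,
        sister=sister.clade,
        K=K,
        theta_max=theta_max,
        ratio=ratio,
        distinct=ratio > threshold,
    )


def ktheta_table(results: Iterable[KThetaResult]) -> pd.DataFrame:
    """Sister-pair results as a tidy table (one row per comparison)."""
    return pd.DataFrame([r.to_dict() for r in results])
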