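"""Pairwise and group-level genetic distances.

Implements uncorrected p-distances and Tamura–Nei (TN93) distances with
gamma rate heterogeneity, within/between/net group means, and
site-bootstrap standard errors.

The net distance between two groups X and Y is

    net(X, Y) = d_XY - (d_X + d_Y) / 2

where d_XY is the mean pairwise distance across groups and d_X, d_Y are
the mean pairwise distances within each group.  Net distances may be
negative when within-group diversity exceeds between-group divergence
and are deliberately not clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyGroupError, IncomparablePairError
from .seqio import Alignment, GroupingScheme, complete_deletion

MODELS = ("p", "tn93_gamma")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with its provenance.

    ``sites_used`` is the number of alignment columns analysed (the
    post-complete-deletion length, or the original length for pairwise
    deletion, where per-pair comparable-site counts vary).
    """

    ids: tuple[str, ...]
    values: np.ndarray
    model: str
    deletion_policy: str
    sites_used: int

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T]):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("nonzero diagonal")

    def index_of(self, ids) -> np.ndarray:
        pos = {sid: i for i, sid in enumerate(self.ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"id not in distance matrix: {e.args[0]!r}") from None

    def get(self, a: str, b: str) -> float:
        i, j = self.index_of([a, b])
        return float(self.values[i, j])

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = self.index_of(ids)
        return DistanceMatrix(
            tuple(ids),
            self.values[np.ix_(idx, idx)],
            self.model,
            self.deletion_policy,
            self.sites_used,
        )

    def to_square_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )

    def to_long_tsv(self, path: str | Path) -> None:
        rows = [
            {"id1": self.ids[i], "id2": self.ids[j], "distance": self.values[i, j]}
            for i, j in combinations(range(len(self.ids)), 2)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pairwise distances


def _p_distances(mat: np.ndarray) -> np.ndarray:
    """p-distance on an encoded matrix, pairwise-comparable sites only."""
    n = mat.shape[0]
    valid = mat >= 0
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (mat[i] != mat[i + 1 :]) & both
        counts = both.sum(axis=1)
        if (counts == 0).any():
            j = int(np.nonzero(counts == 0)[0][0]) + i + 1
            raise IncomparablePairError(
                f"sequences {i} and {j} share no comparable sites"
            )
        d[i, i + 1 :] = diff.sum(axis=1) / counts
    return d + d.T


def _tn93_gamma_pair(
    x: np.ndarray, y: np.ndarray, gamma_shape: float | None
) -> float:
    """TN93 (optionally gamma-corrected) distance for one encoded pair.

    Base frequencies are estimated from the two sequences being
    compared.  Returns ``inf`` when a logarithm/power argument is
    non-positive (saturation beyond the model's reach).
    """
    both = (x >= 0) & (y >= 0)
    if not both.any():
        raise IncomparablePairError("pair shares no comparable sites")
    xs, ys = x[both], y[both]
    m = both.sum()

    # substitution proportions
    diff = xs != ys
    pair_min = np.minimum(xs, ys)
    pair_max = np.maximum(xs, ys)
    p1 = float(np.sum(diff & (pair_min == 0) & (pair_max == 2)) / m)  # A<->G
    p2 = float(np.sum(diff & (pair_min == 1) & (pair_max == 3)) / m)  # C<->T
    purine = np.isin(xs, (0, 2))
    q = float(np.sum(diff & (purine != np.isin(ys, (0, 2)))) / m)

    counts = np.bincount(np.concatenate([xs, ys]), minlength=4)
    g = counts / counts.sum()
    ga, gc, gg, gt = g
    gr, gy = ga + gg, gc + gt
    if gr == 0 or gy == 0:
        return np.inf if (p1 or p2 or q) else 0.0

    k1 = 2 * ga * gg / gr
    k2 = 2 * gt * gc / gy
    k3 = 2 * (gr * gy - ga * gg * gy / gr - gt * gc * gr / gy)

    w1 = 1 - (p1 / k1 if k1 > 0 else 0.0) - q / (2 * gr)
    w2 = 1 - (p2 / k2 if k2 > 0 else 0.0) - q / (2 * gy)
    w3 = 1 - q / (2 * gr * gy)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return np.inf

    if gamma_shape is None:
        return float(-k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3))
    a = gamma_shape
    return float(
        a
        * (
            k1 * w1 ** (-1 / a)
            + k2 * w2 ** (-1 / a)
            + k3 * w3 ** (-1 / a)
            - (k1 + k2 + k3)
        )
    )


def distance_matrix(
    a: Alignment,
    model: str = "p",
    policy: str = "complete",
    gamma_shape: float = 1.0,
) -> DistanceMatrix:
    """Compute the pairwise distance matrix of an alignment.

    Parameters
    ----------
    model : {"p", "tn93_gamma"}
        Uncorrected p-distance, or TN93 with gamma rate correction.
    policy : {"complete", "pairwise"}
        Complete deletion drops every column with a gap/N anywhere;
        pairwise deletion drops sites per sequence pair.
    gamma_shape : float
        Shape parameter of the gamma rate distribution (tn93_gamma only).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if policy == "complete":
        a = complete_deletion(a)
    elif policy != "pairwise":
        raise ValueError(f"unknown deletion policy {policy!r}")
    mat = a.to_array()
    n = mat.shape[0]
    if model == "p":
        values = _p_distances(mat)
    else:
        values = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            values[i, j] = values[j, i] = _tn93_gamma_pair(
                mat[i], mat[j], gamma_shape
            )
        if np.isinf(values).any():
            warnings.warn(
                "TN93 correction diverged for at least one pair "
                "(distance set to inf)",
                stacklevel=2,
            )
    return DistanceMatrix(a.ids, values, model, policy, a.length)


# ---------------------------------------------------------------------------
# group summaries


@dataclass(frozen=True)
class GroupDistanceSummary:
    """Within, between and net mean distances per group (pair)."""

    within: dict[str, float]
    between: dict[tuple[str, str], float]
    net: dict[tuple[str, str], float]
    se: dict[str, dict] | None = None

    def net_between(self, x: str, y: str) -> float:
        if x == y:
            return 0.0
        key = (x, y) if (x, y) in self.net else (y, x)
        return self.net[key]


def _within_mean(sub: np.ndarray) -> float:
    n = sub.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    return float(sub[iu].mean())


def group_mean_distances(
    m: DistanceMatrix, g: GroupingScheme
) -> GroupDistanceSummary:
    """Within-group, between-group and net mean distances.

    Singleton groups have within-mean 0 by convention (with a warning),
    so net distances stay computable for single-specimen lineages.
    """
    groups = g.restrict(m.ids).groups()
    for name, members in groups.items():
        if not members:
            raise EmptyGroupError(f"group {name!r} has no members in matrix")
    if not groups:
        raise EmptyGroupError("no group has members in the distance matrix")
    idx = {name: m.index_of(members) for name, members in groups.items()}

    within: dict[str, float] = {}
    for name, ii in idx.items():
        if len(ii) < 2:
            warnings.warn(
                f"group {name!r} is a singleton; within-group mean set to 0",
                stacklevel=2,
            )
            within[name] = 0.0
        else:
            within[name] = _within_mean(m.values[np.ix_(ii, ii)])

    between: dict[tuple[str, str], float] = {}
    net: dict[tuple[str, str], float] = {}
    names = list(groups)
    for x, y in combinations(names, 2):
        dxy = float(m.values[np.ix_(idx[x], idx[y])].mean())
        between[(x, y)] = dxy
        net[(x, y)] = dxy - (within[x] + within[y]) / 2.0
    return GroupDistanceSummary(within, between, net)


def net_between(m: DistanceMatrix, g: GroupingScheme, x: str, y: str) -> float:
    """Net between-group mean distance for one group pair."""
    sub = g.restrict(m.ids)
    members = sub.groups()
    for name in (x, y):
        if name not in members or not members[name]:
            raise EmptyGroupError(f"group {name!r} has no members in matrix")
    ix, iy = m.index_of(members[x]), m.index_of(members[y])
    dxy = float(m.values[np.ix_(ix, iy)].mean())
    dx = _within_mean(m.values[np.ix_(ix, ix)])
    dy = _within_mean(m.values[np.ix_(iy, iy)])
    return dxy - (dx + dy) / 2.0


# ---------------------------------------------------------------------------
# site bootstrap


def bootstrap_se(
    a: Alignment,
    g: GroupingScheme,
    statistic: Callable[[DistanceMatrix, GroupingScheme], Mapping[str, float]],
    replicates: int = 1000,
    seed: int = 0,
    model: str = "p",
    policy: str = "complete",
    gamma_shape: float = 1.0,
) -> dict[str, float]:
    """Site-bootstrap standard errors of group-level statistics.

    Alignment columns (of the post-deletion alignment, matching the
    sites actually analysed) are resampled with replacement
    ``replicates`` times; the statistic is recomputed per replicate and
    the standard deviation across replicates returned per key.
    Replicates where the statistic raises are dropped and counted; a
    warning is issued if more than 10% are dropped.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if policy == "complete":
        a = complete_deletion(a)
    rng = np.random.default_rng(seed)
    mat = a.to_array()
    n_sites = mat.shape[1]
    samples: dict[str, list[float]] = {}
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep = mat[:, cols]
        valid = rep >= 0
        try:
            if model == "p":
                values = _p_distances(rep)
            else:
                nseq = rep.shape[0]
                values = np.zeros((nseq, nseq))
                for i, j in combinations(range(nseq), 2):
                    values[i, j] = values[j, i] = _tn93_gamma_pair(
                        rep[i], rep[j], gamma_shape
                    )
            dm = DistanceMatrix(a.ids, values, model, policy, n_sites)
            result = statistic(dm, g)
            if any(not np.isfinite(v) for v in result.values()):
                raise FloatingPointError("non-finite statistic")
        except Exception:
            dropped += 1
            continue
        for key, val in result.items():
            samples.setdefault(key, []).append(float(val))
    if dropped > 0.1 * replicates:
        warnings.warn(
            f"{dropped}/{replicates} bootstrap replicates dropped",
            stacklevel=2,
        )
    if not samples:
        raise IncomparablePairError("statistic failed in every replicate")
    return {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in samples.items()}
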