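"""Alignment and metadata I/O.

Reads and writes per-locus FASTA alignments and the specimen metadata
table, collapses identical sequences to unique haplotypes, and applies
the gap/missing-data deletion policies that all distance-based analyses
downstream depend on.

Sequences are nucleotide strings over the alphabet ``A C G T - N``
(case-insensitive on input, ``U`` mapped to ``T``).  ``-`` (alignment
gap) and ``N`` (undetermined base) are treated identically as missing
data by the deletion policies, since both make a site incomparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateSpecimenError,
    InvalidCharacterError,
    NoComparableSitesError,
    NoSequencesError,
    UnalignedInputError,
)

VALID_CHARS = frozenset("ACGT-N")

# integer encoding used by the numeric modules: A=0 C=1 G=2 T=3, missing=-1
_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": -1, "N": -1}
_DECODE = np.array(list("ACGT"), dtype="U1")


@dataclass(frozen=True)
class Alignment:
    """An aligned set of nucleotide sequences for one locus.

    Parameters
    ----------
    locus_name : str
        Name of the locus (e.g. ``"COI"``, ``"16S"``).
    ids : tuple of str
        Ordered, unique specimen (or haplotype) identifiers.
    seqs : tuple of str
        Uppercase sequences over ``ACGT-N``, all the same length.
    """

    locus_name: str
    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(self.ids) == 0:
            raise NoSequencesError(f"{self.locus_name}: no sequences")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DuplicateSpecimenError(
                f"{self.locus_name}: duplicate specimen id(s) {dupes}"
            )
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise UnalignedInputError(
                f"{self.locus_name}: unaligned input (lengths {sorted(lengths)})"
            )
        bad = {c for s in self.seqs for c in s} - VALID_CHARS
        if bad:
            raise InvalidCharacterError(
                f"{self.locus_name}: invalid characters {sorted(bad)}"
            )

    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self.ids)

    @property
    def length(self) -> int:
        """Number of alignment columns (sites), L."""
        return len(self.seqs[0])

    def to_array(self) -> np.ndarray:
        """Integer-encoded matrix, shape (n, L); missing sites are -1."""
        out = np.empty((self.n, self.length), dtype=np.int8)
        table = np.full(128, -2, dtype=np.int8)
        for ch, code in _ENCODE.items():
            table[ord(ch)] = code
        for i, s in enumerate(self.seqs):
            out[i] = table[np.frombuffer(s.encode(), dtype=np.uint8)]
        return out

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Restrict to the given specimen ids, preserving alignment order."""
        keep = set(ids)
        idx = [i for i, sid in enumerate(self.ids) if sid in keep]
        missing = keep - set(self.ids)
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return Alignment(
            self.locus_name,
            tuple(self.ids[i] for i in idx),
            tuple(self.seqs[i] for i in idx),
        )


def _normalise(seq: str, locus: str, rec_id: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_CHARS
    if bad:
        raise InvalidCharacterError(
            f"{locus}/{rec_id}: invalid characters {sorted(bad)}"
        )
    return s


def read_alignment(path: str | Path, locus_name: str) -> Alignment:
    """Read a FASTA alignment; ids are header tokens before whitespace.

    Raises
    ------
    NoSequencesError, UnalignedInputError, DuplicateSpecimenError,
    InvalidCharacterError
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise NoSequencesError(f"{path}: no sequences")
    ids = tuple(r.id for r in records)
    seqs = tuple(_normalise(str(r.seq), locus_name, r.id) for r in records)
    return Alignment(locus_name, ids, seqs)


def write_alignment(a: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA (one record per specimen, in order)."""
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(a.ids, a.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def collapse_haplotypes(
    a: Alignment,
) -> tuple[Alignment, dict[str, list[str]]]:
    """Collapse identical sequences to unique haplotypes.

    Haplotype identity is exact string equality of the (already
    policy-applied, if desired) sequences.  The representative of each
    haplotype is the first specimen carrying it, in alignment order, and
    the returned mapping ``haplotype id -> member specimen ids``
    partitions the input ids.
    """
    members: dict[str, list[str]] = {}
    rep_for_seq: dict[str, str] = {}
    order: list[str] = []
    for sid, seq in zip(a.ids, a.seqs):
        rep = rep_for_seq.get(seq)
        if rep is None:
            rep_for_seq[seq] = sid
            members[sid] = [sid]
            order.append(sid)
        else:
            members[rep].append(sid)
    collapsed = Alignment(
        a.locus_name,
        tuple(order),
        tuple(a.seqs[a.ids.index(h)] for h in order),
    )
    return collapsed, members


def complete_deletion(a: Alignment) -> Alignment:
    """Drop every column containing a gap or N in any sequence.

    Raises :class:`NoComparableSitesError` if nothing survives.
    """
    mat = a.to_array()
    keep = (mat >= 0).all(axis=0)
    if not keep.any():
        raise NoComparableSitesError(
            f"{a.locus_name}: no comparable sites under complete deletion"
        )
    if keep.all():
        return a
    seqs = tuple("".join(_DECODE[row[keep]]) for row in mat)
    return Alignment(a.locus_name, a.ids, seqs)


def pairwise_mask(a: Alignment) -> np.ndarray:
    """Boolean (n, L) matrix of per-sequence comparable sites.

    Used by the pairwise deletion policy: a column is compared for a
    pair iff both rows are True there.
    """
    return a.to_array() >= 0


def apply_deletion_policy(a: Alignment, policy: str):
    """Apply a site-deletion policy.

    ``"complete"`` returns a gap/N-free :class:`Alignment`; ``"pairwise"``
    returns the per-sequence site mask consumed later per pair.
    """
    if policy == "complete":
        return complete_deletion(a)
    if policy == "pairwise":
        return pairwise_mask(a)
    raise ValueError(f"unknown deletion policy: {policy!r}")


# ---------------------------------------------------------------------------
# specimen metadata and grouping schemes


def read_specimen_table(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata TSV.

    Required columns: ``specimen_id``, ``locality_id``, ``population_id``;
    any extra columns (e.g. per-locus availability flags ``has_<locus>``)
    are preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"specimen_id", "locality_id", "population_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"specimen table missing columns {sorted(missing)}")
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise DuplicateSpecimenError(f"duplicate specimen id(s) {dupes}")
    return df


def write_specimen_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GroupingScheme:
    """Nested assignment specimen -> population -> group (lineage).

    ``mapping`` takes each specimen id to a ``(group_id, population_id)``
    pair.  Populations must be nested within groups: no population may
    span two groups.
    """

    name: str
    mapping: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        from .errors import InvalidHierarchyError

        pop_group: dict[str, str] = {}
        for _sid, (grp, pop) in self.mapping.items():
            if pop_group.setdefault(pop, grp) != grp:
                raise InvalidHierarchyError(
                    f"{self.name}: population {pop!r} spans groups "
                    f"{pop_group[pop]!r} and {grp!r}"
                )

    @property
    def k(self) -> int:
        """Number of groups (lineages)."""
        return len(self.groups())

    def groups(self) -> dict[str, list[str]]:
        """group id -> member specimen ids (insertion order)."""
        out: dict[str, list[str]] = {}
        for sid, (grp, _pop) in self.mapping.items():
            out.setdefault(grp, []).append(sid)
        return out

    def populations(self) -> dict[str, list[str]]:
        """population id -> member specimen ids."""
        out: dict[str, list[str]] = {}
        for sid, (_grp, pop) in self.mapping.items():
            out.setdefault(pop, []).append(sid)
        return out

    def populations_by_group(self) -> dict[str, dict[str, list[str]]]:
        """group id -> {population id -> member specimen ids}."""
        out: dict[str, dict[str, list[str]]] = {}
        for sid, (grp, pop) in self.mapping.items():
            out.setdefault(grp, {}).setdefault(pop, []).append(sid)
        return out

    def group_of(self, specimen_id: str) -> str:
        return self.mapping[specimen_id][0]

    def restrict(self, ids: Iterable[str], name: str | None = None) -> "GroupingScheme":
        """Sub-scheme containing only the given specimen ids."""
        keep = set(ids)
        return GroupingScheme(
            name or self.name,
            {sid: gp for sid, gp in self.mapping.items() if sid in keep},
        )

    def with_population_as_group(self, name: str | None = None) -> "GroupingScheme":
        """Scheme in which every population is its own group."""
        return GroupingScheme(
            name or f"{self.name}:populations",
            {sid: (pop, pop) for sid, (_g, pop) in self.mapping.items()},
        )


def scheme_from_table(
    df: pd.DataFrame, group_col: str, name: str | None = None
) -> GroupingScheme:
    """Build a GroupingScheme from a metadata-style DataFrame.

    ``df`` must contain ``specimen_id`` and ``population_id`` columns and
    the named group column.
    """
    mapping = {
        str(r.specimen_id): (str(getattr(r, group_col)), str(r.population_id))
        for r in df.itertuples()
    }
    return GroupingScheme(name or group_col, mapping)


def write_haplotype_map(members: Mapping[str, list[str]], path: str | Path) -> None:
    """Emit the haplotype membership mapping as a two-column TSV."""
    rows = [
        {"haplotype_id": hap, "specimen_id": sid}
        for hap, sids in members.items()
        for sid in sids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
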