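"""Pedigree relationship matrices and status-number effective population size.

The numerator relationship matrix A holds expected additive genetic
relationships between all pedigree members (diagonal 1 + F). It is built with
the tabular (recursive) method; unknown parents are treated as unique,
unrelated, non-inbred founders. The status number Ns = 0.5 / group
coancestry converts unequal parental contributions into the census size of an
idealized population with the same gene diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeTable",
    "RelationshipMatrix",
    "ContributionVector",
    "build_numerator_relationship",
    "inbreeding_coefficients",
    "status_number",
]

UNKNOWN = "0"


@dataclass(frozen=True)
class PedigreeTable:
    """Topologically ordered pedigree records (id, sire, dam).

    ``"0"`` denotes an unknown parent. Construction validates uniqueness and
    ordering; :meth:`from_records` additionally attempts a topological
    reorder and reports cycles with the offending id.
    """

    ids: list
    sires: list
    dams: list

    def __post_init__(self):
        n = len(self.ids)
        if n == 0:
            raise ValueError("pedigree has no records")
        if len(self.sires) != n or len(self.dams) != n:
            raise ValueError("ids, sires and dams must have equal length")
        seen: dict = {}
        for i, (iid, s, d) in enumerate(zip(self.ids, self.sires, self.dams)):
            if iid in seen:
                raise ValueError(f"duplicate id {iid!r} in pedigree")
            if iid == UNKNOWN:
                raise ValueError("'0' is reserved for unknown parents")
            for p in (s, d):
                if p != UNKNOWN and p not in seen:
                    raise ValueError(
                        f"parent {p!r} of {iid!r} does not precede it in the pedigree"
                    )
            if s == iid or d == iid:
                raise ValueError(f"{iid!r} is recorded as its own parent")
            seen[iid] = i

    @classmethod
    def from_records(cls, records) -> "PedigreeTable":
        """Build from (id, sire, dam) triples, reordering parents first.

        Raises on cycles, duplicates, or parents never defined as records.
        """
        records = [(str(a), str(b), str(c)) for a, b, c in records]
        known = set()
        for r in records:
            if r[0] in known:
                raise ValueError(f"duplicate id {r[0]!r} in pedigree")
            known.add(r[0])
        for iid, s, d in records:
            for p in (s, d):
                if p != UNKNOWN and p not in known:
                    raise ValueError(f"parent {p!r} of {iid!r} has no pedigree record")
        by_id = {r[0]: r for r in records}
        order: list = []
        state: dict = {}  # 0 = visiting, 1 = done

        def visit(iid: str, stack: list):
            st = state.get(iid)
            if st == 1:
                return
            if st == 0:
                raise ValueError(f"pedigree cycle detected at {iid!r}")
            state[iid] = 0
            stack.append(iid)
            _, s, d = by_id[iid]
            for p in (s, d):
                if p != UNKNOWN:
                    visit(p, stack)
            state[iid] = 1
            order.append(iid)
            stack.pop()

        for iid, _, _ in records:
            visit(iid, [])
        ordered = [by_id[i] for i in order]
        return cls([r[0] for r in ordered], [r[1] for r in ordered], [r[2] for r in ordered])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PedigreeTable":
        cols = list(df.columns[:3])
        return cls.from_records(df[cols].astype(str).itertuples(index=False, name=None))

    def __len__(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "sire": self.sires, "dam": self.dams})


@dataclass(frozen=True)
class RelationshipMatrix:
    """Symmetric additive relationship matrix with an id index."""

    values: np.ndarray
    ids: list
    pedigree_based: bool = True
    parent_map: dict | None = field(default=None, repr=False, compare=False)
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("id index length does not match matrix")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        object.__setattr__(self, "_index", {str(i): k for k, i in enumerate(self.ids)})

    def loc(self, i, j) -> float:
        return float(self.values[self._index[str(i)], self._index[str(j)]])

    def indices(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[str(i)] for i in ids], dtype=np.int64)
        except KeyError as err:
            raise KeyError(f"id {err.args[0]!r} not present in relationship matrix") from None

    def submatrix(self, ids) -> "RelationshipMatrix":
        idx = self.indices(ids)
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], [str(i) for i in ids],
                                  self.pedigree_based)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass(frozen=True)
class ContributionVector:
    """Proportional gene contributions, non-negative and summing to one."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("contribution vector must be a non-empty 1-D array")
        if v.size != len(self.ids):
            raise ValueError("ids and values must have equal length")
        if np.any(v < 0):
            raise ValueError("contributions must be non-negative")
        if abs(v.sum() - 1.0) > 1e-12:
            raise ValueError("contributions must sum to 1 (within 1e-12)")


def build_numerator_relationship(ped: PedigreeTable) -> RelationshipMatrix:
    """Tabular-method A matrix over the whole pedigree.

    a_jj = 1 + 0.5 * a(sire_j, dam_j); a_ij = 0.5 * (a(i, sire_j) + a(i, dam_j))
    for earlier i, with unknown parents contributing zero. Row updates are
    vectorized so the build is O(n^2) in numpy operations.
    """
    n = len(ped)
    index = {iid: k for k, iid in enumerate(ped.ids)}
    A = np.zeros((n, n))
    for j in range(n):
        s, d = ped.sires[j], ped.dams[j]
        si = index[s] if s != UNKNOWN else -1
        di = index[d] if d != UNKNOWN else -1
        row = np.zeros(j)
        if si >= 0:
            row += 0.5 * A[si, :j]
        if di >= 0:
            row += 0.5 * A[di, :j]
        A[j, :j] = row
        A[:j, j] = row
        A[j, j] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    parent_map = {
        i: tuple(p for p in (s, d) if p != UNKNOWN)
        for i, s, d in zip(ped.ids, ped.sires, ped.dams)
    }
    return RelationshipMatrix(A, list(ped.ids), pedigree_based=True,
                              parent_map=parent_map)


def inbreeding_coefficients(A: RelationshipMatrix) -> pd.Series:
    """Per-individual inbreeding coefficient F_i = a_ii - 1."""
    return pd.Series(np.diag(A.values) - 1.0, index=A.ids, name="F")


def status_number(A: RelationshipMatrix, c: ContributionVector) -> float:
    """Status number Ns = 0.5 / group coancestry.

    Group coancestry is Theta = c' (A/2) c for contribution vector c indexed
    to A. Equals the census number for equal contributions of unrelated,
    non-inbred individuals, and shrinks as contributions concentrate or
    contributors become related.
    """
    idx = A.indices(c.ids)
    theta = float(c.values @ (A.values[np.ix_(idx, idx)] / 2.0) @ c.values)
    if theta <= 0:
        raise ValueError("group coancestry must be positive")
    return 0.5 / theta
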