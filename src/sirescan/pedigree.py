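"""Pedigree relationship structures.

Builds the numerator relationship matrix A by the tabular method,
inbreeding coefficients by the Meuwissen–Luo recursion, the sparse
inverse of A by Henderson's rules, and the genotyped-animal block A22.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

UNKNOWN = -1


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree: parents always precede offspring.

    ``sire``/``dam`` hold positional indices into ``ids`` (or ``UNKNOWN``).
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise PedigreeError("parent arrays must match the ID list length")
        if len(set(self.ids)) != n:
            raise PedigreeError("animal IDs must be unique")
        for i in range(n):
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN and not (0 <= p < i):
                    raise PedigreeError(
                        f"animal {self.ids[i]!r}: parent index {p} does not "
                        "precede offspring (pedigree not topologically ordered)"
                    )
        self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        """Positional indices of external IDs; raises listing unknown IDs."""
        missing = [a for a in animal_ids if a not in self._index]
        if missing:
            raise PedigreeError(f"IDs absent from pedigree: {missing}")
        return np.array([self._index[a] for a in animal_ids], dtype=np.int64)

    @classmethod
    def from_records(cls, records, warn=None) -> "Pedigree":
        """Build from (animal, sire, dam) string triples in any order.

        '0', '', 'NA' and None mean unknown. Parents never listed as animals
        are appended as founders (``warn`` callback is invoked if given).
        Cycles raise :class:`PedigreeError` naming an animal on the cycle.
        """

        def norm(v):
            v = "" if v is None else str(v).strip()
            return None if v in ("", "0", "NA", "na", "nan") else v

        parents: dict[str, tuple] = {}
        order: list[str] = []
        for a, s, d in records:
            a = norm(a)
            if a is None:
                raise PedigreeError("animal ID may not be missing")
            if a in parents:
                raise PedigreeError(f"duplicate animal ID {a!r}")
            parents[a] = (norm(s), norm(d))
            order.append(a)
        # implicit founders
        for a in list(order):
            for p in parents[a]:
                if p is not None and p not in parents:
                    parents[p] = (None, None)
                    order.append(p)
                    if warn is not None:
                        warn(f"parent {p!r} not listed; added as founder")

        # Kahn topological sort, stable in input order
        state: dict[str, int] = {}
        sorted_ids: list[str] = []

        def visit(a: str, stack: list[str]) -> None:
            if state.get(a) == 2:
                return
            if state.get(a) == 1:
                raise PedigreeError(f"pedigree cycle detected involving {a!r}")
            state[a] = 1
            stack.append(a)
            for p in parents[a]:
                if p is not None:
                    visit(p, stack)
            stack.pop()
            state[a] = 2
            sorted_ids.append(a)

        for a in order:
            visit(a, [])

        idx = {a: i for i, a in enumerate(sorted_ids)}
        sire = np.array(
            [UNKNOWN if parents[a][0] is None else idx[parents[a][0]] for a in sorted_ids]
        )
        dam = np.array(
            [UNKNOWN if parents[a][1] is None else idx[parents[a][1]] for a in sorted_ids]
        )
        return cls(sorted_ids, sire, dam)


def read_pedigree(path, warn=None) -> Pedigree:
    """Read an ``animal,sire,dam`` CSV (0/empty = unknown parent)."""
    df = pd.read_csv(path, dtype=str, comment="#")
    cols = [c.strip().lower() for c in df.columns]
    for required in ("animal", "sire", "dam"):
        if required not in cols:
            raise PedigreeError(f"pedigree file missing column {required!r}")
    df.columns = cols
    return Pedigree.from_records(
        df[["animal", "sire", "dam"]].itertuples(index=False, name=None), warn=warn
    )


def write_pedigree(ped: Pedigree, path) -> None:
    rows = []
    for i, a in enumerate(ped.ids):
        s = ped.ids[ped.sire[i]] if ped.sire[i] != UNKNOWN else "0"
        d = ped.ids[ped.dam[i]] if ped.dam[i] != UNKNOWN else "0"
        rows.append((a, s, d))
    pd.DataFrame(rows, columns=["animal", "sire", "dam"]).to_csv(path, index=False)


def build_A(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method."""
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        asd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        if i:
            row = np.zeros(i)
            if s != UNKNOWN:
                row += A[s, :i]
            if d != UNKNOWN:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients via the Meuwissen & Luo (1992) recursion.

    Avoids materializing A: for each animal, L-row generation over its
    ancestors gives F_i = sum(L_ij^2 d_j) - 1.
    """
    n = len(ped)
    F = np.zeros(n)
    dvec = np.zeros(n)  # Mendelian sampling variance per animal
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        fs = F[s] if s != UNKNOWN else -1.0  # -1 encodes unknown in the d formula
        fd = F[d] if d != UNKNOWN else -1.0
        dvec[i] = 0.5 - 0.25 * (fs + fd)
        if s != UNKNOWN and d != UNKNOWN:
            F[i] = _a_between(ped, dvec, s, d) / 2.0
    return F


def _a_between(ped: Pedigree, dvec: np.ndarray, s: int, d: int) -> float:
    """Relationship a(s,d) from L-decomposition rows of s and d."""
    Ls = _l_row(ped, s)
    Ld = _l_row(ped, d)
    common = set(Ls) & set(Ld)
    return sum(Ls[j] * Ld[j] * dvec[j] for j in common)


def _l_row(ped: Pedigree, i: int) -> dict[int, float]:
    L: dict[int, float] = {}
    pending = {i: 1.0}
    for j in range(i, -1, -1):
        v = pending.pop(j, 0.0)
        if v == 0.0:
            continue
        L[j] = L.get(j, 0.0) + v
        s, d = ped.sire[j], ped.dam[j]
        if s != UNKNOWN:
            pending[s] = pending.get(s, 0.0) + 0.5 * v
        if d != UNKNOWN:
            pending[d] = pending.get(d, 0.0) + 0.5 * v
    return L


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    For each animal i with Mendelian sampling variance
    d_i = 0.5 - 0.25 (F_s + F_d) (unknown parent contributes F = -1, i.e.
    d = 0.75 with one parent known, 1 with none), add 1/d_i times the
    outer product of (1, -0.5, -0.5) on (i, sire, dam).
    """
    if F is None:
        F = inbreeding(ped)
    n = len(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        fs = F[s] if s != UNKNOWN else -1.0
        fd = F[d] if d != UNKNOWN else -1.0
        inv_d = 1.0 / (0.5 - 0.25 * (fs + fd))
        add(i, i, inv_d)
        for p in (s, d):
            if p != UNKNOWN:
                add(i, p, -0.5 * inv_d)
                add(p, i, -0.5 * inv_d)
        for p in (s, d):
            for q in (s, d):
                if p != UNKNOWN and q != UNKNOWN:
                    add(p, q, 0.25 * inv_d)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def subset_A22(ped: Pedigree, genotyped_ids) -> np.ndarray:
    """A restricted to genotyped animals, in the given ID order.

    Computed from sparse A^-1 by solving for the needed columns, so a
    dense A over the full pedigree is never formed.
    """
    idx = ped.index_of(genotyped_ids)
    ainv = build_A_inverse(ped).tocsc()
    lu = splu(ainv)
    n = len(ped)
    rhs = np.zeros((n, len(idx)))
    rhs[idx, np.arange(len(idx))] = 1.0
    cols = lu.solve(rhs)
    a22 = cols[idx, :]
    return 0.5 * (a22 + a22.T)  # symmetrize tiny solver asymmetry
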