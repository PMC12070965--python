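"""Pedigree handling and pedigree-based (numerator) relationship matrices.

A pedigree is a list of (animal, sire, dam) triples with unknown parents
allowed.  From it we build the additive relationship matrix ``A`` (tabular
method, with inbreeding), its sparse inverse (Henderson's rules with
inbreeding coefficients from the Meuwissen-Luo algorithm), and the
partition of ``A`` into non-genotyped / genotyped blocks used by the
single-step machinery.

Unknown parents are treated as unrelated, non-inbred founders; there is no
genetic-group modelling.  Input records need not be sorted: the pedigree is
re-ordered internally by a stable topological sort so that every animal
follows both of its known parents.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1

#: dense-A size guard: above this many animals the full tabular matrix is
#: refused and callers must work with A-inverse / restricted blocks.
DENSE_A_LIMIT = 20_000


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    ids : ndarray of object
        Animal identifiers in internal (topological) order.
    sire, dam : ndarray of int
        Index of each animal's sire/dam in ``ids``; ``UNKNOWN`` (-1) when
        the parent is not recorded.
    genotyped : ndarray of bool
        Flag per animal.
    sex : ndarray of object or None
        Optional per-animal label, aligned with ``ids``.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    genotyped: np.ndarray
    sex: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise PedigreeError("duplicate animal id in pedigree")
        # parents must precede offspring
        order = np.arange(self.n)
        for par in (self.sire, self.dam):
            known = par >= 0
            if np.any(par[known] >= order[known]):
                raise PedigreeError("pedigree not topologically sorted")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids: Iterable) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in animal_ids], dtype=int)
        except KeyError as e:
            raise PedigreeError(f"animal {e.args[0]!r} not in pedigree") from None

    @classmethod
    def from_records(
        cls,
        records: Sequence[tuple],
        genotyped: Iterable = (),
        sex: dict | None = None,
        unknown_codes: tuple = (0, "0", "NA", "", None),
    ) -> "Pedigree":
        """Build a Pedigree from (id, sire, dam) triples.

        Parents referenced but never listed as animals are inserted as
        founders.  Records may come in any order; a stable Kahn topological
        sort (input order as tie-break) fixes the internal ordering.
        """
        unknown = set(unknown_codes)
        seen: dict = {}
        for a, s, d in records:
            if a in unknown:
                raise PedigreeError(f"animal id {a!r} uses an unknown-parent code")
            if a in seen:
                raise PedigreeError(f"duplicate animal id {a!r}")
            seen[a] = (s if s not in unknown else None, d if d not in unknown else None)
        # founder insertion, preserving first-reference order
        extra = []
        for a, (s, d) in list(seen.items()):
            for p in (s, d):
                if p is not None and p not in seen and p not in (x[0] for x in extra):
                    extra.append((p, None, None))
        for p, s, d in extra:
            seen[p] = (s, d)
        order = _kahn_sort(seen)
        idx = {a: i for i, a in enumerate(order)}
        n = len(order)
        sire = np.full(n, UNKNOWN, dtype=int)
        dam = np.full(n, UNKNOWN, dtype=int)
        for a, (s, d) in seen.items():
            i = idx[a]
            if s is not None:
                sire[i] = idx[s]
            if d is not None:
                dam[i] = idx[d]
        gset = set(genotyped)
        missing = gset - set(order)
        if missing:
            raise PedigreeError(f"genotyped ids absent from pedigree: {sorted(map(str, missing))[:5]}")
        gflag = np.array([a in gset for a in order], dtype=bool)
        sex_arr = None
        if sex:
            sex_arr = np.array([sex.get(a) for a in order], dtype=object)
        return cls(np.array(order, dtype=object), sire, dam, gflag, sex_arr)

    def with_genotyped(self, genotyped: Iterable) -> "Pedigree":
        gset = set(genotyped)
        missing = gset - set(self.ids)
        if missing:
            raise PedigreeError(f"genotyped ids absent from pedigree: {sorted(map(str, missing))[:5]}")
        gflag = np.array([a in gset for a in self.ids], dtype=bool)
        return Pedigree(self.ids, self.sire, self.dam, gflag, self.sex, dict(self._index))


def _kahn_sort(seen: dict) -> list:
    """Stable topological sort; raises PedigreeError naming a cycle member."""
    input_rank = {a: i for i, a in enumerate(seen)}
    children: dict = {a: [] for a in seen}
    indeg = {a: 0 for a in seen}
    for a, (s, d) in seen.items():
        for p in {s, d} - {None}:
            children[p].append(a)
            indeg[a] += 1
    ready = [(input_rank[a], a) for a in seen if indeg[a] == 0]
    heapq.heapify(ready)
    order = []
    while ready:
        _, a = heapq.heappop(ready)
        order.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, (input_rank[c], c))
    if len(order) != len(seen):
        cyc = sorted((str(a) for a in seen if indeg[a] > 0))
        raise PedigreeError(f"pedigree contains a cycle involving: {cyc[:5]}")
    return order


@dataclass
class RelationshipMatrix:
    """Square symmetric relationship matrix with an animal-id index."""

    values: np.ndarray
    ids: np.ndarray
    kind: str = "A"

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("relationship matrix / id index dimension mismatch")

    @property
    def n(self) -> int:
        return len(self.ids)


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV/TSV with columns ``id,sire,dam[,sex]``.

    0 or NA encode an unknown parent.  The separator (comma or tab) is
    sniffed.  Returns a topologically sorted :class:`Pedigree`.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    for c in ("id", "sire", "dam"):
        if c not in cols:
            raise PedigreeError(f"pedigree file lacks required column {c!r}")
    recs = list(zip(df["id"].str.strip(), df["sire"].str.strip(), df["dam"].str.strip()))
    sex = None
    if "sex" in cols:
        sex = {a: s for a, s in zip(df["id"].str.strip(), df["sex"].str.strip())}
    return Pedigree.from_records(recs, sex=sex, unknown_codes=(0, "0", "NA", "na", "", None))


def write_pedigree(ped: Pedigree, path) -> None:
    def code(i):
        return "0" if i < 0 else str(ped.ids[i])

    df = pd.DataFrame(
        {
            "id": [str(a) for a in ped.ids],
            "sire": [code(s) for s in ped.sire],
            "dam": [code(d) for d in ped.dam],
        }
    )
    if ped.sex is not None:
        df["sex"] = [s if s is not None else "NA" for s in ped.sex]
    df.to_csv(path, index=False)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular (recursive) method.

    a_ii = 1 + 0.5 * a_{sire,dam}; a_ij = 0.5 * (a_{j,sire} + a_{j,dam}) for
    j preceding i; an unknown parent contributes 0.
    """
    n = ped.n
    if n > DENSE_A_LIMIT:
        raise MemoryError(
            f"dense A refused for {n} animals (> {DENSE_A_LIMIT}); "
            "work with A-inverse or restricted blocks"
        )
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(A, ped.ids, "A")


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo algorithm.

    Uses the L-D-L' decomposition of A: a_ii = sum_j L_ij^2 D_j is
    accumulated by walking each animal's ancestors, so only the diagonal is
    ever formed (O(n * ancestors) time, O(n) memory).
    """
    n = ped.n
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        n_known = int(s >= 0) + int(d >= 0)
        if n_known == 0:
            D[i] = 1.0
        elif n_known == 1:
            D[i] = 0.75 - 0.25 * F[max(s, d)]
        else:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        if n_known < 2:
            F[i] = 0.0  # founder or single known parent of a non-inbred line
            if n_known == 1:
                # single known parent: a_ii = 1 + 0.5*a_{s,unknown} = 1
                F[i] = 0.0
            continue
        # accumulate a_ii = sum_j c_j^2 D_j over ancestors j (heap by index)
        coef = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            c = coef.pop(j)
            a_ii += c * c * D[j]
            for p in (ped.sire[j], ped.dam[j]):
                if p >= 0:
                    if p in coef:
                        coef[p] += 0.5 * c
                    else:
                        coef[p] = 0.5 * c
                        heapq.heappush(heap, -p)
        F[i] = a_ii - 1.0
    return F


def build_A_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse A^-1 assembled directly by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of animal i is
    m_i = 0.5 - 0.25 (F_s + F_d) with both parents known,
    0.75 - 0.25 F_p with one, and 1 with none; each animal contributes
    alpha = 1/m_i times the usual (-1, 0.5) stencil.  Never formed by dense
    inversion.
    """
    F = inbreeding(ped)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        parents = [p for p in (s, d) if p >= 0]
        if len(parents) == 2:
            m = 0.5 - 0.25 * (F[s] + F[d])
        elif len(parents) == 1:
            m = 0.75 - 0.25 * F[parents[0]]
        else:
            m = 1.0
        alpha = 1.0 / m
        add(i, i, alpha)
        for p in parents:
            add(i, p, -alpha / 2.0)
            add(p, i, -alpha / 2.0)
        for p in parents:
            for q_ in parents:
                add(p, q_, alpha / 4.0)
    return sp.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n)).tocsr()


def partition_indices(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Indices of non-genotyped and genotyped animals (disjoint, exhaustive).

    Slicing A with them yields the Ann / Ang / Agg blocks of the single-step
    relationship machinery.
    """
    g = np.flatnonzero(ped.genotyped)
    ng = np.flatnonzero(~ped.genotyped)
    if g.size == 0:
        raise PedigreeError("no genotyped animals: single-step H is undefined")
    if ng.size == 0:
        warnings.warn("all animals genotyped; H reduces to the genomic matrix alone")
    return ng, g
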