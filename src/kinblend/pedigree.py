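"""Pedigrees, the numerator relationship matrix A, and inbreeding.

The numerator relationship matrix A holds the *expected* additive
relatedness implied by the genealogy: ``a_ij`` is twice the kinship
coefficient between individuals i and j, and the diagonal is ``1 + F_i``
where ``F_i`` is the pedigree inbreeding coefficient.  A is built with the
tabular (recursive) method, which for the population sizes handled here
(order 10^3) is both the simplest and a perfectly adequate dense
construction.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix

logger = logging.getLogger("kinblend")

__all__ = ["Pedigree", "PedigreeError", "load_pedigree", "build_A", "inbreeding"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass(frozen=True)
class Pedigree:
    """A parent-ordered pedigree.

    Parameters
    ----------
    ids
        Individual labels, topologically ordered: every parent appears
        before any of its offspring.
    sire, dam
        Integer positions of each individual's parents within ``ids``;
        ``-1`` encodes an unknown parent (base-population founder side).
    """

    ids: tuple[str, ...]
    sire: np.ndarray
    dam: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = pd.Series(self.ids).pipe(lambda s: s[s.duplicated()]).tolist()
            raise PedigreeError(f"duplicate individual ids: {dupes[:5]}")
        for name in ("sire", "dam"):
            par = getattr(self, name)
            if par.shape != (len(self.ids),):
                raise PedigreeError(f"{name} array has wrong length")
            bad = np.nonzero(par >= np.arange(len(self.ids)))[0]
            if bad.size and np.any(par[bad] >= 0):
                i = bad[np.argmax(par[bad] >= 0)]
                raise PedigreeError(
                    f"pedigree not parent-ordered: parent of {self.ids[i]!r} "
                    "does not precede it"
                )
        object.__setattr__(self, "_index", {x: i for i, x in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def position(self, individual: str) -> int:
        return self._index[individual]

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def records(self) -> list[tuple[str, str | None, str | None]]:
        """(individual, sire-id or None, dam-id or None) triplets in order."""
        out = []
        for i, ind in enumerate(self.ids):
            s = self.ids[self.sire[i]] if self.sire[i] >= 0 else None
            d = self.ids[self.dam[i]] if self.dam[i] >= 0 else None
            out.append((ind, s, d))
        return out

    @classmethod
    def from_records(
        cls, records: list[tuple[str | None, ...]], sort: bool = True
    ) -> "Pedigree":
        """Build a pedigree from (id, sire, dam) triplets.

        Missing parents are ``None``.  Parents that never appear in the id
        column are auto-created as founder records (logged).  Records are
        topologically sorted so parents precede offspring; cycles raise
        :class:`PedigreeError` naming the individuals involved.
        """
        ids = [r[0] for r in records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dupes = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
            raise PedigreeError(f"duplicate individual ids: {dupes[:5]}")
        parents: dict[str, tuple[str | None, str | None]] = {
            r[0]: (r[1], r[2]) for r in records  # type: ignore[misc]
        }
        phantom = []
        for s, d in list(parents.values()):
            for p in (s, d):
                if p is not None and p not in parents:
                    parents[p] = (None, None)
                    phantom.append(p)
        if phantom:
            logger.warning(
                "auto-created %d founder record(s) for parents not listed as "
                "individuals: %s%s",
                len(phantom),
                phantom[:5],
                "..." if len(phantom) > 5 else "",
            )
        if sort:
            order = _stable_toposort(parents)
        else:
            order = list(parents)
        pos = {x: i for i, x in enumerate(order)}
        sire = np.array(
            [pos[parents[x][0]] if parents[x][0] is not None else -1 for x in order],
            dtype=np.int64,
        )
        dam = np.array(
            [pos[parents[x][1]] if parents[x][1] is not None else -1 for x in order],
            dtype=np.int64,
        )
        return cls(tuple(order), sire, dam)


def _stable_toposort(parents: dict) -> list:
    """Topological order that preserves the input order whenever it is
    already consistent (Kahn's algorithm with an input-position heap)."""
    pos = {x: i for i, x in enumerate(parents)}
    children: dict[str, list[str]] = {x: [] for x in parents}
    indeg = {}
    for x, (s, d) in parents.items():
        ps = [p for p in (s, d) if p is not None]
        indeg[x] = len(ps)
        for p in ps:
            children[p].append(x)
    heap = [pos[x] for x in parents if indeg[x] == 0]
    heapq.heapify(heap)
    ids = list(parents)
    order = []
    while heap:
        x = ids[heapq.heappop(heap)]
        order.append(x)
        for c in children[x]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, pos[c])
    if len(order) < len(parents):
        stuck = [x for x in parents if indeg[x] > 0]
        raise PedigreeError(f"pedigree contains a cycle involving: {stuck[:5]}")
    return order


def load_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with columns ``id,sire,dam``.

    Unknown parents are coded ``"0"`` or left empty.  The result is
    topologically sorted; undeclared parents become founder records.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["id", "sire", "dam"]
    if list(df.columns[:3]) != expected:
        raise PedigreeError(
            f"pedigree file must have columns {expected}, got {list(df.columns)}"
        )

    def _clean(v: str) -> str | None:
        v = v.strip()
        return None if v in ("", "0", "NA") else v

    records = [
        (row.id.strip(), _clean(row.sire), _clean(row.dam))
        for row in df.itertuples(index=False)
    ]
    for i, r in enumerate(records):
        if not r[0]:
            raise PedigreeError(f"empty individual id at data line {i + 1}")
        if r[0] in (r[1], r[2]):
            raise PedigreeError(f"pedigree contains a cycle: {r[0]!r} is its own parent")
    return Pedigree.from_records(records)


def build_A(pedigree: Pedigree) -> KinshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``a_ii = 1 + 0.5 * a_{s(i),d(i)}`` and ``a_ij = 0.5 * (a_{j,s(i)} +
    a_{j,d(i)})`` for prior individuals j; an unknown parent contributes 0
    (unrelated, non-inbred base-population convention).
    """
    n = pedigree.n
    A = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return KinshipMatrix(values=A, ids=list(pedigree.ids), kind="A")


def inbreeding(pedigree: Pedigree) -> pd.Series:
    """Pedigree inbreeding coefficients ``F_i = diag(A)_i - 1``."""
    A = build_A(pedigree)
    return pd.Series(np.diag(A.values) - 1.0, index=list(pedigree.ids), name="F")
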