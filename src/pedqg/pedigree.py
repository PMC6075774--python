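"""Pedigree representation, validation, summaries, and additive relationship matrices.

A :class:`Pedigree` is a directed acyclic parent map over individual
identifiers.  Founders are the individuals with both parents unknown.  The
additive (numerator) relationship matrix ``A`` is computed by the standard
tabular method in topological order; its diagonal is ``1 + F`` where ``F``
is the inbreeding coefficient.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: accepted spellings of an unknown parent / unknown sex in input files
_UNKNOWN_TOKENS = {"", "0", "na", "nan", "none", "unknown", "u"}

FEMALE = "F"
MALE = "M"
UNKNOWN_SEX = "U"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


def _parse_sex(token: str | None) -> str:
    if token is None:
        return UNKNOWN_SEX
    t = str(token).strip().lower()
    if t in _UNKNOWN_TOKENS:
        return UNKNOWN_SEX
    if t in {"f", "female", "2"}:
        return FEMALE
    if t in {"m", "male", "1"}:
        return MALE
    raise PedigreeError(f"unrecognized sex code: {token!r}")


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    dam: str | None
    sire: str | None
    sex: str = UNKNOWN_SEX


class Pedigree:
    """Validated parent map.

    Parameters
    ----------
    records
        Iterable of ``(id, dam, sire, sex)`` tuples or :class:`PedigreeRecord`;
        ``dam``/``sire`` may be ``None`` for unknown.
    add_missing_parents
        When True, parents that are referenced but not listed are appended as
        founders with unknown sex (logged); otherwise this is an error.
    """

    def __init__(
        self,
        records: Iterable[PedigreeRecord | tuple],
        *,
        add_missing_parents: bool = False,
    ) -> None:
        recs: list[PedigreeRecord] = []
        for r in records:
            if not isinstance(r, PedigreeRecord):
                r = PedigreeRecord(*r)
            recs.append(r)

        seen: dict[str, int] = {}
        for r in recs:
            if r.id in seen:
                raise PedigreeError(f"duplicate individual id: {r.id!r}")
            seen[r.id] = len(seen)

        referenced = []
        for r in recs:
            for p in (r.dam, r.sire):
                if p is not None and p not in seen:
                    referenced.append(p)
        if referenced:
            if not add_missing_parents:
                raise PedigreeError(
                    f"parents referenced but not listed: {sorted(set(referenced))}"
                )
            for p in dict.fromkeys(referenced):  # preserve first-reference order
                recs.append(PedigreeRecord(p, None, None, UNKNOWN_SEX))
                seen[p] = len(seen)
                logger.info("auto-added referenced parent %r as founder", p)

        self._records = recs
        self._index = seen
        self.ids: list[str] = [r.id for r in recs]
        self._validate()
        self._topo_idx = self._topological_indices()

    # -- construction helpers ------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def __iter__(self):
        return iter(self._records)

    def record(self, iid: str) -> PedigreeRecord:
        return self._records[self._index[iid]]

    def index(self, iid: str) -> int:
        return self._index[iid]

    @property
    def records(self) -> list[PedigreeRecord]:
        return list(self._records)

    @property
    def founders(self) -> list[str]:
        return [r.id for r in self._records if r.dam is None and r.sire is None]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Dam and sire positions per record, -1 for unknown."""
        dam = np.full(len(self), -1, dtype=np.int64)
        sire = np.full(len(self), -1, dtype=np.int64)
        for i, r in enumerate(self._records):
            if r.dam is not None:
                dam[i] = self._index[r.dam]
            if r.sire is not None:
                sire[i] = self._index[r.sire]
        return dam, sire

    def _validate(self) -> None:
        for r in self._records:
            if r.dam is not None:
                dsex = self._records[self._index[r.dam]].sex
                if dsex == MALE:
                    raise PedigreeError(f"dam {r.dam!r} of {r.id!r} has sex M")
            if r.sire is not None:
                ssex = self._records[self._index[r.sire]].sex
                if ssex == FEMALE:
                    raise PedigreeError(f"sire {r.sire!r} of {r.id!r} has sex F")
            if r.dam == r.id or r.sire == r.id:
                raise PedigreeError(f"individual {r.id!r} is its own parent")

    def _topological_indices(self) -> list[int]:
        """Kahn's algorithm; founders first, ties broken by input order."""
        n = len(self)
        dam, sire = self.parent_indices()
        children: list[list[int]] = [[] for _ in range(n)]
        n_parents = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for p in (dam[i], sire[i]):
                if p >= 0:
                    children[p].append(i)
                    n_parents[i] += 1
        # process founders first (input order), then remaining by input order
        import heapq

        order = [i for i in range(n) if n_parents[i] == 0]
        remaining = np.array(n_parents)
        heap: list[int] = []
        for i in order:
            for j in children[i]:
                remaining[j] -= 1
                if remaining[j] == 0:
                    heapq.heappush(heap, j)
        out = list(order)
        while heap:
            i = heapq.heappop(heap)
            out.append(i)
            for j in children[i]:
                remaining[j] -= 1
                if remaining[j] == 0:
                    heapq.heappush(heap, j)
        if len(out) != n:
            stuck = [self.ids[i] for i in range(n) if remaining[i] > 0]
            raise PedigreeError(f"pedigree contains a cycle through {stuck[0]!r}")
        return out

    def topological_order(self) -> list[str]:
        """Ids ordered so every parent precedes all of its offspring."""
        return [self.ids[i] for i in self._topo_idx]


@dataclass
class RelationshipMatrix:
    """Symmetric additive relationship matrix indexed by pedigree ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self._index = {iid: i for i, iid in enumerate(self.ids)}

    def __getitem__(self, key: tuple[str, str]) -> float:
        i, j = key
        return float(self.values[self._index[i], self._index[j]])

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = [self._index[i] for i in ids]
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)].copy())

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_square_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id"] + self.ids)
            for i, iid in enumerate(self.ids):
                w.writerow([iid] + [repr(float(v)) for v in self.values[i]])

    def to_triplet_csv(self, path) -> None:
        """Nonzero entries of the upper triangle as ``id_i,id_j,a``."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id_i", "id_j", "a"])
            n = len(self.ids)
            for i in range(n):
                for j in range(i, n):
                    if self.values[i, j] != 0.0:
                        w.writerow([self.ids[i], self.ids[j], repr(float(self.values[i, j]))])


@dataclass(frozen=True)
class PedigreeSummary:
    n_individuals: int
    n_founders: int
    n_maternities: int
    n_paternities: int
    n_full_sib_pairs: int
    n_maternal_half_sib_pairs: int
    n_paternal_half_sib_pairs: int
    max_pedigree_depth: int


# ---------------------------------------------------------------------------
# operations


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with header ``id,dam,sire,sex`` (case-insensitive).

    Unknown parents may be encoded as empty, ``0`` or ``NA``.  Parents
    referenced but not listed are auto-added as founders (logged).
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise PedigreeError(f"empty pedigree file: {path}")
        cols = {c.strip().lower(): i for i, c in enumerate(header)}
        for required in ("id", "dam", "sire"):
            if required not in cols:
                raise PedigreeError(f"pedigree file missing column {required!r}")
        recs = []
        for row in reader:
            if not row or not any(cell.strip() for cell in row):
                continue
            iid = row[cols["id"]].strip()
            dam = row[cols["dam"]].strip()
            sire = row[cols["sire"]].strip()
            sex = row[cols["sex"]].strip() if "sex" in cols and len(row) > cols["sex"] else ""
            dam = None if dam.lower() in _UNKNOWN_TOKENS else dam
            sire = None if sire.lower() in _UNKNOWN_TOKENS else sire
            recs.append(PedigreeRecord(iid, dam, sire, _parse_sex(sex)))
    return Pedigree(recs, add_missing_parents=True)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write ``id,dam,sire,sex`` CSV; unknown emitted as ``0``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "dam", "sire", "sex"])
        for r in ped:
            w.writerow([r.id, r.dam or "0", r.sire or "0", r.sex if r.sex != UNKNOWN_SEX else "0"])


def topological_order(ped: Pedigree) -> list[str]:
    return ped.topological_order()


def additive_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix ``A`` by the tabular (recursive) method.

    ``A(i,j) = 0.5 * (A(j, dam_i) + A(j, sire_i))`` for ``j`` processed before
    ``i``; ``A(i,i) = 1 + 0.5 * A(dam_i, sire_i)``; an unknown parent
    contributes 0.
    """
    n = len(ped)
    dam, sire = ped.parent_indices()
    A = np.zeros((n, n))
    for i in ped._topo_idx:
        d, s = dam[i], sire[i]
        row = np.zeros(n)
        if d >= 0:
            row += A[d]
        if s >= 0:
            row += A[s]
        row *= 0.5
        A[i, :] = row
        A[:, i] = row
        A[i, i] = 1.0 + (0.5 * A[d, s] if (d >= 0 and s >= 0) else 0.0)
    return RelationshipMatrix(list(ped.ids), A)


def inbreeding_coefficients(ped: Pedigree) -> dict[str, float]:
    """``F(i) = 0.5 * A(dam_i, sire_i)``; 0 for founders or unknown parents.

    Computed by a memoized kinship recursion so that only the ancestor pairs
    actually needed are touched (no dense matrix).
    """
    dam, sire = ped.parent_indices()
    pos = {i: k for k, i in enumerate(ped._topo_idx)}
    memo: dict[tuple[int, int], float] = {}

    def kinship(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        key = (i, j) if pos[i] >= pos[j] else (j, i)
        if key in memo:
            return memo[key]
        a, b = key  # a is topologically later (or equal)
        if a == b:
            val = 0.5 * (1.0 + kinship(dam[a], sire[a]))
        else:
            val = 0.5 * (kinship(dam[a], b) + kinship(sire[a], b))
        memo[key] = val
        return val

    out: dict[str, float] = {}
    for i, iid in enumerate(ped.ids):
        d, s = dam[i], sire[i]
        out[iid] = kinship(d, s) if (d >= 0 and s >= 0) else 0.0
    return out


def pedigree_depths(ped: Pedigree) -> dict[str, int]:
    """Generation depth per individual (founders have depth 0)."""
    dam, sire = ped.parent_indices()
    depth = np.zeros(len(ped), dtype=np.int64)
    for i in ped._topo_idx:
        d, s = dam[i], sire[i]
        parents = [p for p in (d, s) if p >= 0]
        if parents:
            depth[i] = 1 + max(depth[p] for p in parents)
    return {iid: int(depth[i]) for i, iid in enumerate(ped.ids)}


def pedigree_summary(ped: Pedigree) -> PedigreeSummary:
    """Counts of parent links, sib pairs and depth.

    A full-sib pair shares a known dam AND a known sire; a half-sib pair
    shares exactly one known parent.
    """
    dam, sire = ped.parent_indices()
    n = len(ped)
    n_mat = int(np.sum(dam >= 0))
    n_pat = int(np.sum(sire >= 0))

    def _pairs(counts: Mapping) -> int:
        return sum(k * (k - 1) // 2 for k in counts.values())

    from collections import Counter

    both = Counter(
        (dam[i], sire[i]) for i in range(n) if dam[i] >= 0 and sire[i] >= 0
    )
    by_dam = Counter(dam[i] for i in range(n) if dam[i] >= 0)
    by_sire = Counter(sire[i] for i in range(n) if sire[i] >= 0)

    full = _pairs(both)
    # pairs sharing a known dam minus those also sharing a known sire
    mat_half = _pairs(by_dam) - full
    pat_half = _pairs(by_sire) - full
    depths = pedigree_depths(ped)
    return PedigreeSummary(
        n_individuals=n,
        n_founders=len(ped.founders),
        n_maternities=n_mat,
        n_paternities=n_pat,
        n_full_sib_pairs=full,
        n_maternal_half_sib_pairs=mat_half,
        n_paternal_half_sib_pairs=pat_half,
        max_pedigree_depth=max(depths.values()) if depths else 0,
    )
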