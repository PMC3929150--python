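"""Pedigree representation, I/O, relationship coefficients and relative classes.

A pedigree is an ordered sequence of individuals in which every recorded
parent precedes its offspring (topological order).  The additive (numerator)
relationship between two individuals is twice their kinship coefficient and
is the covariance scale for gene content between relatives; it is computed
by the standard recursive kinship rules with unknown parents treated as
unrelated, non-inbred founders.

Test individuals are classified by their most recent genotyped ancestors
(both parents, sire + maternal grandsire, dam + paternal grandsire, sire
only, dam only, or other), which is the grouping used throughout the
accuracy reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "UNKNOWN",
    "Individual",
    "Pedigree",
    "RelativeCategory",
    "PedigreeError",
    "read_pedigree",
    "classify_relatives",
    "additive_relationship",
]

#: Token denoting an unknown parent in pedigree files.
UNKNOWN = "0"


class PedigreeError(ValueError):
    """Raised for malformed pedigrees (cycles, duplicate ids, unknown ids)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree record: an id and its sire/dam links ("0" = unknown)."""

    id: str
    sire_id: str = UNKNOWN
    dam_id: str = UNKNOWN
    sex: Optional[str] = None  # "male" | "female" | None

    def __post_init__(self) -> None:
        if not self.id or self.id == UNKNOWN:
            raise PedigreeError(f"invalid individual id {self.id!r}")
        if self.id in (self.sire_id, self.dam_id):
            raise PedigreeError(f"individual {self.id!r} is its own parent")


class Pedigree:
    """An ordered, validated pedigree with memoized kinship computation.

    Parents always precede their offspring in ``self.individuals``; parents
    referenced but never given their own record are appended automatically
    as founders at construction time.
    """

    def __init__(self, individuals: Iterable[Individual]):
        records = list(individuals)
        seen: dict[str, Individual] = {}
        for ind in records:
            if ind.id in seen:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            seen[ind.id] = ind
        # Parents that never appear as a row become founders.
        implied: dict[str, Individual] = {}
        for ind in records:
            for pid, sex in ((ind.sire_id, "male"), (ind.dam_id, "female")):
                if pid != UNKNOWN and pid not in seen and pid not in implied:
                    implied[pid] = Individual(pid, sex=sex)
        records = list(implied.values()) + records
        seen.update(implied)

        self.individuals: list[Individual] = self._toposort(records, seen)
        self._pos: dict[str, int] = {
            ind.id: i for i, ind in enumerate(self.individuals)
        }
        n = len(self.individuals)
        self._sire = [
            self._pos.get(ind.sire_id, -1) if ind.sire_id != UNKNOWN else -1
            for ind in self.individuals
        ]
        self._dam = [
            self._pos.get(ind.dam_id, -1) if ind.dam_id != UNKNOWN else -1
            for ind in self.individuals
        ]
        self._kin_cache: dict[tuple[int, int], float] = {}

    @staticmethod
    def _toposort(
        records: list[Individual], seen: dict[str, Individual]
    ) -> list[Individual]:
        order: list[Individual] = []
        state: dict[str, int] = {}  # 0 unvisited / 1 on stack / 2 done
        for root in records:
            if state.get(root.id, 0) == 2:
                continue
            stack: list[tuple[Individual, int]] = [(root, 0)]
            while stack:
                ind, phase = stack.pop()
                if phase == 0:
                    if state.get(ind.id, 0) == 2:
                        continue
                    if state.get(ind.id, 0) == 1:
                        raise PedigreeError(
                            f"pedigree cycle detected at individual {ind.id!r}"
                        )
                    state[ind.id] = 1
                    stack.append((ind, 1))
                    for pid in (ind.dam_id, ind.sire_id):
                        if pid != UNKNOWN and state.get(pid, 0) != 2:
                            if state.get(pid, 0) == 1:
                                raise PedigreeError(
                                    f"pedigree cycle detected at individual {pid!r}"
                                )
                            stack.append((seen[pid], 0))
                else:
                    state[ind.id] = 2
                    order.append(ind)
        return order

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._pos

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def position(self, ind_id: str) -> int:
        try:
            return self._pos[ind_id]
        except KeyError:
            raise PedigreeError(f"unknown individual id {ind_id!r}") from None

    def individual(self, ind_id: str) -> Individual:
        return self.individuals[self.position(ind_id)]

    def sire_of(self, ind_id: str) -> Optional[str]:
        i = self._sire[self.position(ind_id)]
        return None if i < 0 else self.individuals[i].id

    def dam_of(self, ind_id: str) -> Optional[str]:
        i = self._dam[self.position(ind_id)]
        return None if i < 0 else self.individuals[i].id

    def is_founder(self, ind_id: str) -> bool:
        p = self.position(ind_id)
        return self._sire[p] < 0 and self._dam[p] < 0

    def parent_positions(self) -> tuple[list[int], list[int]]:
        """(sire, dam) position arrays, -1 for unknown; aligned with order."""
        return list(self._sire), list(self._dam)

    # -- relationships -------------------------------------------------------

    def _kinship(self, i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        cached = self._kin_cache.get(key)
        if cached is not None:
            return cached
        if i == j:
            f = 0.5 * (1.0 + self._kinship(self._sire[i], self._dam[i]))
        else:
            # j is the later-born: recurse on its parents.
            f = 0.5 * (
                self._kinship(i, self._sire[j]) + self._kinship(i, self._dam[j])
            )
        self._kin_cache[key] = f
        return f

    def kinship(self, a_id: str, b_id: str) -> float:
        return self._kinship(self.position(a_id), self.position(b_id))

    def additive_relationship(self, a_id: str, b_id: str) -> float:
        """Numerator additive relationship a = 2 x kinship, in [0, 2]."""
        return 2.0 * self.kinship(a_id, b_id)

    def inbreeding(self, ind_id: str) -> float:
        """Inbreeding coefficient F = kinship of the parents (0 for founders)."""
        p = self.position(ind_id)
        return self._kinship(self._sire[p], self._dam[p])

    # -- classification ------------------------------------------------------

    def classify_relatives(
        self, genotyped: set[str], ind_id: str
    ) -> "RelativeCategory":
        """Category of ``ind_id`` by its most recent genotyped ancestors.

        Precedence: BothParents > SireMGS > DamPGS > Sire > Dam > Other.
        """
        sire = self.sire_of(ind_id)
        dam = self.dam_of(ind_id)
        sire_g = sire is not None and sire in genotyped
        dam_g = dam is not None and dam in genotyped
        if sire_g and dam_g:
            return RelativeCategory.BOTH_PARENTS
        mgs = self.sire_of(dam) if dam is not None else None
        pgs = self.sire_of(sire) if sire is not None else None
        if sire_g and not dam_g and mgs is not None and mgs in genotyped:
            return RelativeCategory.SIRE_MGS
        if dam_g and not sire_g and pgs is not None and pgs in genotyped:
            return RelativeCategory.DAM_PGS
        if sire_g:
            return RelativeCategory.SIRE
        if dam_g:
            return RelativeCategory.DAM
        return RelativeCategory.OTHER

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def read(cls, path: str | Path) -> "Pedigree":
        """Read a whitespace- or comma-delimited id/sire/dam(/sex) file."""
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tokens = line.replace(",", " ").split()
                if len(tokens) < 3:
                    raise PedigreeError(
                        f"{path}:{lineno}: expected at least 3 columns, "
                        f"got {len(tokens)}"
                    )
                sex = None
                if len(tokens) >= 4 and tokens[3] in ("male", "female", "M", "F"):
                    sex = {"M": "male", "F": "female"}.get(tokens[3], tokens[3])
                records.append(Individual(tokens[0], tokens[1], tokens[2], sex))
        return cls(records)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ind in self.individuals:
                fh.write(f"{ind.id} {ind.sire_id} {ind.dam_id}\n")


class RelativeCategory(enum.Enum):
    """Most recent genotyped ancestor(s) of a test individual."""

    BOTH_PARENTS = "BothParents"
    SIRE_MGS = "SireMGS"
    DAM_PGS = "DamPGS"
    SIRE = "Sire"
    DAM = "Dam"
    OTHER = "Other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Functional aliases matching the operation-style API.

def read_pedigree(path: str | Path) -> Pedigree:
    """Read and validate a pedigree file (see :meth:`Pedigree.read`)."""
    return Pedigree.read(path)


def additive_relationship(ped: Pedigree, a_id: str, b_id: str) -> float:
    return ped.additive_relationship(a_id, b_id)


def classify_relatives(
    ped: Pedigree, genotyped: set[str], ind_id: str
) -> RelativeCategory:
    return ped.classify_relatives(genotyped, ind_id)
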