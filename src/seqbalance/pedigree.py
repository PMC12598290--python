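"""Pedigree structure enumeration: duos, trios and hepta-families.

A three-generation cohort (children, parents, grandparents) yields a mix of
family structures once sequenced. This module enumerates them from standard
6-column PED input:

* **trio** — an individual together with both parents, both present in the
  dataset. Because a parent is itself someone's child, this definition covers
  parent–child trios and grandparent–parent trios uniformly; trios are
  counted per child.
* **hepta-family** — a seven-member, three-generation unit: a child, both
  parents, and both sets of grandparents, all present. Each hepta-family
  contains exactly three trios (the child's and each parent's).
* **duo (pair)** — an individual with exactly one parent present. By default
  only maternal-line duos are counted (mother or, one generation up,
  grandmother as the reference individual), and a both-parents child is a
  trio, not two duos.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InvalidPedigreeError

__all__ = [
    "Individual",
    "PedigreeGraph",
    "Trio",
    "HeptaFamily",
    "Duo",
    "find_trios",
    "find_hepta_families",
    "find_duos",
    "read_ped",
]

MISSING = "0"


@dataclass(frozen=True)
class Individual:
    iid: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = 0  # 1 male, 2 female, 0 unknown
    family_id: str = ""


@dataclass(frozen=True)
class Trio:
    child: str
    father: str
    mother: str


@dataclass(frozen=True)
class HeptaFamily:
    child: str
    father: str
    mother: str
    paternal_grandfather: str
    paternal_grandmother: str
    maternal_grandfather: str
    maternal_grandmother: str

    def members(self) -> tuple[str, ...]:
        return (
            self.child, self.father, self.mother,
            self.paternal_grandfather, self.paternal_grandmother,
            self.maternal_grandfather, self.maternal_grandmother,
        )


@dataclass(frozen=True)
class Duo:
    child: str
    parent: str
    line: str  # "maternal" | "paternal"


@dataclass(frozen=True)
class PedigreeGraph:
    """Individuals keyed by id, with parent links.

    Parent ids referencing individuals absent from the dataset are kept (they
    are real people, just unsequenced) but never contribute to structures.
    Construction rejects duplicate ids and ancestry cycles.
    """

    individuals: dict[str, Individual] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Iterative DFS over parent links; a back edge means someone is their
        # own ancestor.
        WHITE, GREY, BLACK = 0, 1, 2
        color = {iid: WHITE for iid in self.individuals}
        for root in self.individuals:
            if color[root] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(root, 0)]
            color[root] = GREY
            while stack:
                iid, pi = stack[-1]
                parents = self._present_parents(iid)
                if pi < len(parents):
                    stack[-1] = (iid, pi + 1)
                    nxt = parents[pi]
                    if color[nxt] == GREY:
                        raise InvalidPedigreeError(f"ancestry cycle through {nxt!r}")
                    if color[nxt] == WHITE:
                        color[nxt] = GREY
                        stack.append((nxt, 0))
                else:
                    color[iid] = BLACK
                    stack.pop()

    def _present_parents(self, iid: str) -> list[str]:
        ind = self.individuals[iid]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None and p in self.individuals]

    def present(self, iid: str | None) -> bool:
        return iid is not None and iid in self.individuals

    def __len__(self) -> int:
        return len(self.individuals)

    @classmethod
    def from_individuals(cls, individuals: list[Individual]) -> "PedigreeGraph":
        table: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in table:
                raise InvalidPedigreeError(f"duplicate individual id {ind.iid!r}")
            table[ind.iid] = ind
        return cls(individuals=table)


def read_ped(path: str | Path) -> PedigreeGraph:
    """Read a 6-column PED file (FID IID father mother sex phenotype).

    Whitespace-delimited; parent id "0" means unknown.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 6:
        raise InvalidPedigreeError(f"{path}: PED needs 6 columns, found {df.shape[1]}")
    individuals = []
    for _, row in df.iterrows():
        fid, iid, father, mother, sex = row[0], row[1], row[2], row[3], row[4]
        individuals.append(
            Individual(
                iid=iid,
                father_id=None if father == MISSING else father,
                mother_id=None if mother == MISSING else mother,
                sex=int(sex) if sex in ("1", "2") else 0,
                family_id=fid,
            )
        )
    return PedigreeGraph.from_individuals(individuals)


def find_trios(g: PedigreeGraph) -> list[Trio]:
    """All (child, father, mother) triples with both parents present.

    One trio per child; parent–child and grandparent–parent trios fall out of
    the same rule because the "child" slot ranges over every individual.
    """
    trios = []
    for ind in g.individuals.values():
        if g.present(ind.father_id) and g.present(ind.mother_id):
            trios.append(Trio(ind.iid, ind.father_id, ind.mother_id))
    return trios


def find_hepta_families(g: PedigreeGraph) -> list[HeptaFamily]:
    """Seven-member families: child + parents + both sets of grandparents.

    Enumerated per child: a child qualifies when both parents are present and
    each parent's own parents are both present.
    """
    families = []
    for ind in g.individuals.values():
        if not (g.present(ind.father_id) and g.present(ind.mother_id)):
            continue
        father = g.individuals[ind.father_id]
        mother = g.individuals[ind.mother_id]
        if not (g.present(father.father_id) and g.present(father.mother_id)):
            continue
        if not (g.present(mother.father_id) and g.present(mother.mother_id)):
            continue
        families.append(
            HeptaFamily(
                child=ind.iid,
                father=father.iid,
                mother=mother.iid,
                paternal_grandfather=father.father_id,
                paternal_grandmother=father.mother_id,
                maternal_grandfather=mother.father_id,
                maternal_grandmother=mother.mother_id,
            )
        )
    return families


def find_duos(g: PedigreeGraph, reference_role: str = "maternal") -> list[Duo]:
    """Parent–offspring pairs where exactly one parent is present.

    ``reference_role`` selects which line counts: ``"maternal"`` (default —
    mothers/grandmothers as the reference individual), ``"paternal"``, or
    ``"any"``. Children with both parents present form trios and are not
    double-counted as duos.
    """
    if reference_role not in ("maternal", "paternal", "any"):
        raise InvalidPedigreeError(f"unknown reference_role {reference_role!r}")
    duos = []
    for ind in g.individuals.values():
        has_f = g.present(ind.father_id)
        has_m = g.present(ind.mother_id)
        if has_f and has_m:
            continue  # trio, not a duo
        if has_m and reference_role in ("maternal", "any"):
            duos.append(Duo(ind.iid, ind.mother_id, "maternal"))
        if has_f and reference_role in ("paternal", "any"):
            duos.append(Duo(ind.iid, ind.father_id, "paternal"))
    return duos
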