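"""Pedigree container and standard family topologies.

A :class:`Pedigree` is an ordered collection of individuals with optional
parent links, sex, affection status and an analysis role.  Roles drive the
downstream filter cascade (``affected``, ``parent``) and the control-exome
exclusion (``pop_control``).

Builders are provided for the study design this package emulates: a nuclear
family with two affected children whose parents are related through a
configurable consanguinity loop, plus a panel of unrelated population
controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

ROLES = ("affected", "parent", "pop_control", "other")

#: Pedigree-analytic inbreeding coefficient of the offspring for each
#: supported consanguinity loop between the parents.
LOOP_INBREEDING = {
    "none": 0.0,
    "first_cousin": 1.0 / 16.0,
    "second_cousin": 1.0 / 64.0,
    "avuncular": 1.0 / 8.0,
}


@dataclass(frozen=True)
class Individual:
    iid: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: int = 0  # 1 male, 2 female, 0 unknown
    affected: bool = False
    role: str = "other"
    fid: str = "FAM1"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if (self.father is None) != (self.mother is None):
            raise ValueError(f"{self.iid}: either both or neither parent must be set")

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class Pedigree:
    """Ordered set of individuals with resolved parent links."""

    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- queries -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        for ind in self.individuals:
            if ind.iid == iid:
                return ind
        raise KeyError(iid)

    @property
    def ids(self) -> list[str]:
        return [ind.iid for ind in self.individuals]

    def by_role(self, role: str) -> list[Individual]:
        return [ind for ind in self.individuals if ind.role == role]

    @property
    def affecteds(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.affected]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def children_of(self, iid: str) -> list[Individual]:
        return [i for i in self.individuals if iid in (i.father, i.mother)]

    def trios(self) -> list[tuple[Individual, Individual, Individual]]:
        """(child, father, mother) for every non-founder whose parents are present."""
        idx = {i.iid: i for i in self.individuals}
        out = []
        for ind in self.individuals:
            if not ind.is_founder and ind.father in idx and ind.mother in idx:
                out.append((ind, idx[ind.father], idx[ind.mother]))
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        idx = {i.iid: i for i in self.individuals}
        if len(idx) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        for ind in self.individuals:
            for pid in (ind.father, ind.mother):
                if pid is not None and pid not in idx:
                    raise ValueError(f"{ind.iid}: parent {pid} not in pedigree")
        self._check_acyclic(idx)

    def _check_acyclic(self, idx: dict[str, Individual]) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ValueError(f"pedigree cycle involving {iid}: {' -> '.join(stack)}")
            state[iid] = 0
            ind = idx[iid]
            for pid in (ind.father, ind.mother):
                if pid is not None:
                    visit(pid, stack + [pid])
            state[iid] = 1

        for iid in idx:
            visit(iid, [iid])

    def topological_order(self) -> list[Individual]:
        """Founders first; every individual after both of its parents."""
        done: set[str] = set()
        order: list[Individual] = []
        pending = list(self.individuals)
        while pending:
            progress = False
            remaining = []
            for ind in pending:
                if ind.is_founder or {ind.father, ind.mother} <= done:
                    order.append(ind)
                    done.add(ind.iid)
                    progress = True
                else:
                    remaining.append(ind)
            if not progress:  # validate() makes this unreachable
                raise ValueError("pedigree is not acyclic")
            pending = remaining
        return order


def _loop_ancestry(loop: str) -> list[Individual]:
    """Ancestors making the two family parents related by the requested loop.

    Returns individuals (topologically ordered) ending with the two parents
    ``FA`` (father) and ``MO`` (mother).
    """
    I = Individual
    if loop == "none":
        return [I("FA", sex=1, role="parent"), I("MO", sex=2, role="parent")]
    if loop == "avuncular":
        # FA is a son of GP1xGP2; MO is FA's niece (daughter of his sibling C1).
        return [
            I("GP1", sex=1), I("GP2", sex=2), I("S1", sex=2),
            I("FA", "GP1", "GP2", sex=1, role="parent"),
            I("C1", "GP1", "GP2", sex=1),
            I("MO", "C1", "S1", sex=2, role="parent"),
        ]
    if loop == "first_cousin":
        return [
            I("GP1", sex=1), I("GP2", sex=2), I("S1", sex=2), I("S2", sex=1),
            I("C1", "GP1", "GP2", sex=1),
            I("C2", "GP1", "GP2", sex=2),
            I("FA", "C1", "S1", sex=1, role="parent"),
            I("MO", "S2", "C2", sex=2, role="parent"),
        ]
    if loop == "second_cousin":
        return [
            I("GGP1", sex=1), I("GGP2", sex=2), I("S1", sex=2), I("S2", sex=1),
            I("S3", sex=2), I("S4", sex=1),
            I("C1", "GGP1", "GGP2", sex=1),
            I("C2", "GGP1", "GGP2", sex=2),
            I("D1", "C1", "S1", sex=1),
            I("D2", "S2", "C2", sex=2),
            I("FA", "D1", "S3", sex=1, role="parent"),
            I("MO", "S4", "D2", sex=2, role="parent"),
        ]
    raise ValueError(f"unknown consanguinity loop {loop!r}")


def quad_family(
    consanguinity_loop: str = "first_cousin",
    n_affected: int = 2,
    n_pop_controls: int = 0,
) -> Pedigree:
    """Two affected sibs, one set of parents, optional consanguinity loop.

    The relationship between the affecteds is configurable through
    ``n_affected`` full sibs; population controls are unrelated singletons in
    their own family ids.
    """
    if consanguinity_loop not in LOOP_INBREEDING:
        raise ValueError(f"unknown consanguinity loop {consanguinity_loop!r}")
    inds = _loop_ancestry(consanguinity_loop)
    for k in range(n_affected):
        inds.append(
            Individual(f"AFF{k + 1}", "FA", "MO", sex=1 + k % 2,
                       affected=True, role="affected")
        )
    for k in range(n_pop_controls):
        inds.append(
            Individual(f"CTRL{k + 1}", sex=1 + k % 2, role="pop_control",
                       fid=f"CTRLFAM{k + 1}")
        )
    return Pedigree(inds)


def infer_roles(individuals: Iterable[Individual]) -> list[Individual]:
    """Assign roles from pedigree structure and affection status.

    Affection wins; parents of an affected individual are ``parent``;
    unrelated singletons (no parents, no children, alone in their family id)
    are ``pop_control``; the rest (e.g. ancestors in a consanguinity loop)
    are ``other``.
    """
    inds = list(individuals)
    has_child = {pid for i in inds if i.affected
                 for pid in (i.father, i.mother) if pid}
    fid_counts: dict[str, int] = {}
    for i in inds:
        fid_counts[i.fid] = fid_counts.get(i.fid, 0) + 1
    out = []
    for i in inds:
        if i.affected:
            role = "affected"
        elif i.iid in has_child:
            role = "parent"
        elif i.is_founder and fid_counts[i.fid] == 1:
            role = "pop_control"
        else:
            role = "other"
        out.append(Individual(i.iid, i.father, i.mother, i.sex, i.affected, role, i.fid))
    return out
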