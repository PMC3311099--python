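"""Pedigree data model, PED/.fam I/O, validation and graph utilities.

A pedigree is a directed acyclic graph whose nodes are individuals and whose
edges run parent -> child.  Individuals carry at most one father and one
mother; a founder has no recorded parent.  All downstream label algorithms
assume a *rooted* pedigree, obtained by adding a virtual progenitor with a
tree edge to every founder.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from typing import Iterable, Optional, TextIO, Union

import networkx as nx

__all__ = [
    "Sex",
    "Individual",
    "Pedigree",
    "RootedPedigree",
    "Violation",
    "PedigreeError",
    "PedigreeParseError",
    "CycleError",
    "VIRTUAL_ROOT_ID",
    "load_ped",
    "load_ped_families",
    "write_ped",
    "validate",
    "topological_order",
    "add_virtual_root",
]

#: Reserved identifier of the synthetic progenitor added by :func:`add_virtual_root`.
VIRTUAL_ROOT_ID = "__root__"


class PedigreeError(Exception):
    """Base class for pedigree data errors."""


class PedigreeParseError(PedigreeError):
    """Malformed PED input; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class CycleError(PedigreeError):
    """The parent->child graph contains a directed cycle."""


class Sex(enum.Enum):
    """Sex of an individual; the value doubles as the label delimiter mark."""

    FEMALE = "."
    MALE = ","
    UNKNOWN = ";"

    @property
    def mark(self) -> str:
        return self.value


#: PED column codes 1/2/0 <-> sexes.
_SEX_FROM_CODE = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_CODE_FROM_SEX = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}

#: Missing-parent marker in PED files.
MISSING = "0"


@dataclass(frozen=True)
class Individual:
    """One pedigree member: an opaque id, optional parent ids and a sex."""

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("individual id must be a non-empty token")
        if self.id in (self.father_id, self.mother_id):
            raise PedigreeError(f"individual {self.id!r} is its own parent")
        if self.father_id is not None and self.father_id == self.mother_id:
            raise PedigreeError(
                f"individual {self.id!r} lists the same id in both parent slots"
            )

    @property
    def parent_ids(self) -> tuple[str, ...]:
        """Recorded parent ids, father slot first."""
        return tuple(p for p in (self.father_id, self.mother_id) if p is not None)


class Pedigree:
    """An ordered collection of individuals with derived graph indexes.

    Input order is semantically relevant: child order within each parent (and
    hence every sibling index assigned by the encoders) follows it.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self._by_id: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        # children index: parent id -> child ids in input order
        self.children: dict[str, list[str]] = {ind.id: [] for ind in self.individuals}
        for ind in self.individuals:
            for pid in ind.parent_ids:
                if pid in self.children:
                    self.children[pid].append(ind.id)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, id: str) -> bool:
        return id in self._by_id

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, id: str) -> Individual:
        try:
            return self._by_id[id]
        except KeyError:
            raise PedigreeError(f"unknown individual {id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def founders(self) -> list[str]:
        """Ids of individuals with no recorded parent, in input order."""
        return [ind.id for ind in self.individuals if not ind.parent_ids]

    def parents(self, id: str) -> tuple[str, ...]:
        return self[id].parent_ids

    def to_networkx(self) -> "nx.DiGraph":
        """Parent->child digraph (known parents only)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.ids)
        for ind in self.individuals:
            for pid in ind.parent_ids:
                if pid in self._by_id:
                    g.add_edge(pid, ind.id)
        return g


@dataclass
class RootedPedigree:
    """A pedigree plus a virtual progenitor parenting every founder."""

    pedigree: Pedigree
    root_id: str = VIRTUAL_ROOT_ID

    @property
    def root_children(self) -> list[str]:
        return self.pedigree.founders

    def parents(self, id: str) -> tuple[str, ...]:
        """Parents in the rooted graph: founders report the virtual root."""
        ps = self.pedigree.parents(id)
        return ps if ps else (self.root_id,)


@dataclass(frozen=True)
class Violation:
    """One validation finding; severity is ``"error"`` or ``"warning"``."""

    severity: str
    kind: str
    message: str


def _tokenize(source: Union[str, TextIO]) -> Iterable[tuple[int, list[str]]]:
    if isinstance(source, str):
        source = io.StringIO(source)
    for lineno, raw in enumerate(source, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        yield lineno, line.split()


def load_ped_families(source: Union[str, TextIO]) -> dict[str, Pedigree]:
    """Parse a 5-column PED/.fam text into one :class:`Pedigree` per family.

    Columns: family_id, individual_id, father_id, mother_id, sex
    (1 = male, 2 = female, 0 = unknown; parent ``"0"`` = missing).
    ``#`` starts a comment; blank lines are ignored.
    """
    rows: dict[str, list[Individual]] = {}
    seen: dict[tuple[str, str], int] = {}
    for lineno, fields in _tokenize(source):
        if len(fields) < 5:
            raise PedigreeParseError(
                f"expected >=5 whitespace-delimited columns, got {len(fields)}", lineno
            )
        fam, iid, fid, mid, sex_code = fields[:5]
        if sex_code not in _SEX_FROM_CODE:
            raise PedigreeParseError(f"malformed sex code {sex_code!r}", lineno)
        if (fam, iid) in seen:
            raise PedigreeParseError(
                f"duplicate individual id {iid!r} (first seen on line {seen[(fam, iid)]})",
                lineno,
            )
        seen[(fam, iid)] = lineno
        if iid in (fid, mid):
            raise PedigreeParseError(f"individual {iid!r} listed as its own parent", lineno)
        rows.setdefault(fam, []).append(
            Individual(
                id=iid,
                father_id=None if fid == MISSING else fid,
                mother_id=None if mid == MISSING else mid,
                sex=_SEX_FROM_CODE[sex_code],
            )
        )
    out: dict[str, Pedigree] = {}
    for fam, inds in rows.items():
        known = {ind.id for ind in inds}
        for ind in inds:
            for pid in ind.parent_ids:
                if pid not in known:
                    raise PedigreeParseError(
                        f"individual {ind.id!r} references unknown parent {pid!r}"
                    )
        out[fam] = Pedigree(inds)
    return out


def load_ped(source: Union[str, TextIO], family: Optional[str] = None) -> Pedigree:
    """Parse PED text and return one family's pedigree.

    With a single family in the input, ``family`` may be omitted.  An empty
    input yields an empty pedigree.
    """
    fams = load_ped_families(source)
    if not fams:
        return Pedigree([])
    if family is not None:
        if family not in fams:
            raise PedigreeError(f"family {family!r} not present in input")
        return fams[family]
    if len(fams) > 1:
        raise PedigreeError(
            f"input holds {len(fams)} families ({sorted(fams)}); pass family="
        )
    return next(iter(fams.values()))


def write_ped(p: Pedigree, sink: Optional[TextIO] = None, family_id: str = "FAM1") -> str:
    """Serialize a pedigree to 5-column PED text ("0" for missing parents)."""
    lines = []
    for ind in p:
        lines.append(
            "\t".join(
                [
                    family_id,
                    ind.id,
                    ind.father_id or MISSING,
                    ind.mother_id or MISSING,
                    _CODE_FROM_SEX[ind.sex],
                ]
            )
        )
    text = "\n".join(lines) + ("\n" if lines else "")
    if sink is not None:
        sink.write(text)
    return text


def validate(p: Pedigree) -> list[Violation]:
    """Report structural problems; an empty list means the pedigree is sound.

    Errors: directed parent->child cycles, unknown parent references.
    Warnings: a parent slot filled by an individual of the mismatching sex
    (nothing is reported when the parent's sex is unknown).
    """
    out: list[Violation] = []
    for ind in p:
        for slot, pid, want in (
            ("father", ind.father_id, Sex.MALE),
            ("mother", ind.mother_id, Sex.FEMALE),
        ):
            if pid is None:
                continue
            if pid not in p:
                out.append(
                    Violation("error", "unknown-parent", f"{ind.id}: unknown {slot} {pid!r}")
                )
                continue
            psex = p[pid].sex
            if psex is not Sex.UNKNOWN and psex is not want:
                out.append(
                    Violation(
                        "warning",
                        "sex-mismatch",
                        f"{ind.id}: {slot} slot filled by {psex.name.lower()}-sexed {pid!r}",
                    )
                )
    g = p.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        out.append(
            Violation(
                "error",
                "cycle",
                "parent->child cycle: " + " -> ".join(u for u, _ in cyc),
            )
        )
    return out


def topological_order(p: Pedigree) -> list[str]:
    """Kahn-layer topological order with input-order tie-breaking.

    Every parent precedes all of its children; among simultaneously ready
    individuals, input-file order decides.  Deterministic by construction.
    """
    from collections import deque

    indeg = {ind.id: len(ind.parent_ids) for ind in p}
    queue = deque(iid for iid in p.ids if indeg[iid] == 0)
    order: list[str] = []
    while queue:
        u = queue.popleft()
        order.append(u)
        for c in p.children[u]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != len(p):
        raise CycleError("pedigree contains a parent->child cycle")
    return order


def add_virtual_root(p: Pedigree) -> RootedPedigree:
    """Attach the virtual progenitor; its children are the founders in input order."""
    if VIRTUAL_ROOT_ID in p:
        raise PedigreeError(f"reserved id {VIRTUAL_ROOT_ID!r} used by an individual")
    if len(p) == 0:
        raise PedigreeError("cannot root an empty pedigree")
    return RootedPedigree(pedigree=p)
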