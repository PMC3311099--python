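"""Label-only path algorithms.

Everything here operates on PET/CPE labels alone: tree-path reconstruction
from the prefix property, recursive enumeration of all ancestor->node paths
(each path classified by its first non-tree edge), parent identification,
ancestor sets from component prefixes, non-overlapping path-pair detection
through an inverted index, and the single-subgraph-child pruning of
nonessential common ancestors.  Individual ids enter only through the
:class:`~pedpaths.encode.LabelTable` when a caller asks for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .encode import LabelTable
from .labels import CpeLabel, EdgeCase, NonTreeEdge, PetLabel
from .pedigree import Pedigree, PedigreeError, Sex

__all__ = [
    "Path",
    "PathPair",
    "OverlapMatrix",
    "RoleAmbiguityError",
    "tree_path",
    "find_paths",
    "identify_parents",
    "split_parent_ntes",
    "ancestor_set",
    "common_ancestors",
    "prune_nonessential",
    "overlap_matrix",
    "find_path_pairs",
]


class RoleAmbiguityError(PedigreeError):
    """Parent sexes do not determine which parent is the father/mother."""


@dataclass(frozen=True)
class Path:
    """A directed path as the PET sequence from an ancestor down to a node."""

    nodes: Tuple[PetLabel, ...]

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.nodes) - 1

    @property
    def start(self) -> PetLabel:
        return self.nodes[0]

    @property
    def end(self) -> PetLabel:
        return self.nodes[-1]

    def __str__(self) -> str:
        return "->".join(str(n) for n in self.nodes)


@dataclass(frozen=True)
class PathPair:
    """Paths from one common ancestor to the father (length s) and mother (length r)."""

    ancestor: PetLabel
    to_father: Path
    to_mother: Path
    non_overlapping: bool

    @property
    def s(self) -> int:
        return self.to_father.length

    @property
    def r(self) -> int:
        return self.to_mother.length


def tree_path(from_pet: PetLabel, to_pet: PetLabel) -> Optional[Path]:
    """The unique spanning-tree path, as successive prefixes, or None.

    Exists iff ``from_pet`` is a component prefix of ``to_pet``; equal labels
    give a zero-length path.
    """
    if not from_pet.is_prefix_of(to_pet):
        return None
    nodes = tuple(
        PetLabel(to_pet.components[:j])
        for j in range(len(from_pet), len(to_pet) + 1)
    )
    return Path(nodes)


def find_paths(
    ancestor: PetLabel,
    target: CpeLabel,
    memo: Optional[Dict[Tuple[PetLabel, PetLabel], Tuple[Path, ...]]] = None,
) -> List[Path]:
    """All distinct directed paths ancestor -> target, from labels alone.

    A path either uses tree edges only (the unique tree path, when the
    ancestor's PET prefixes the target's) or is classified by its first
    non-tree edge (u, w): tree path ancestor->u, the edge, then any path
    w->target found recursively.  Distinct first edges give distinct paths,
    so the union is duplicate-free.  ``memo`` (keyed on (start, target PET))
    may be shared across ancestors of one query.
    """
    if memo is None:
        memo = {}
    key = (ancestor, target.pet)
    cached = memo.get(key)
    if cached is not None:
        return list(cached)
    paths: List[Path] = []
    tp = tree_path(ancestor, target.pet)
    if tp is not None:
        paths.append(tp)
    for e in target.ntes:
        if ancestor.is_prefix_of(e.source):
            head = tree_path(ancestor, e.source)
            assert head is not None
            for q in find_paths(e.dest, target, memo):
                paths.append(Path(head.nodes + q.nodes))
    memo[key] = tuple(paths)
    return paths


def _role_of(pet: PetLabel) -> Optional[str]:
    """'father'/'mother' from a label's final sex mark, None when unknown."""
    sex = pet.components[-1][1]
    if sex is Sex.MALE:
        return "father"
    if sex is Sex.FEMALE:
        return "mother"
    return None


def identify_parents(
    c: CpeLabel,
    table: Optional[LabelTable] = None,
) -> Dict[str, Optional[PetLabel]]:
    """PETs of the father and mother recovered from a node's own label.

    The tree parent's PET is the label minus its last component (a depth-1
    PET means the tree parent is the virtual root: a founder, no parents).
    The non-tree parent, if any, is the source of the edge whose destination
    is the node itself.  Roles follow each parent label's final sex mark;
    with ambiguous marks the pedigree records behind ``table`` break the tie.
    """
    out: Dict[str, Optional[PetLabel]] = {"father": None, "mother": None}
    if len(c.pet) <= 1:
        return out
    tree_parent = c.pet.parent()
    direct = c.direct_edge
    if direct is None:
        role = _role_of(tree_parent)
        if role is None:
            role = _slot_from_records(c, table, tree_parent) or "father"
        out[role] = tree_parent
        return out
    other = direct.source
    r1, r2 = _role_of(tree_parent), _role_of(other)
    if r1 is not None and r2 is not None and r1 != r2:
        out[r1], out[r2] = tree_parent, other
        return out
    # fall back to pedigree records
    if table is not None:
        s1 = _slot_from_records(c, table, tree_parent)
        s2 = _slot_from_records(c, table, other)
        if s1 and s2 and s1 != s2:
            out[s1], out[s2] = tree_parent, other
            return out
    raise RoleAmbiguityError(
        f"cannot assign father/mother roles for parents {tree_parent} and {other}"
    )


def _slot_from_records(
    c: CpeLabel, table: Optional[LabelTable], parent_pet: PetLabel
) -> Optional[str]:
    if table is None:
        return None
    try:
        child_id = table.id_of(c.pet)
        parent_id = table.id_of(parent_pet)
    except KeyError:
        return None
    ind = table.rooted.pedigree[child_id]
    if ind.father_id == parent_id:
        return "father"
    if ind.mother_id == parent_id:
        return "mother"
    return None


def split_parent_ntes(
    c: CpeLabel, table: Optional[LabelTable] = None
) -> Dict[str, CpeLabel]:
    """Reconstruct the parents' CPE labels from a two-parent node's label.

    The father inherits the paternal and both-tagged edges, the mother the
    maternal and both-tagged ones; the node's direct edge belongs to neither.
    Reconstructed labels carry the generic '%' tag — sufficient for ancestor
    and path queries, which never need case information.
    """
    roles = identify_parents(c, table)
    father_pet, mother_pet = roles["father"], roles["mother"]
    if father_pet is None or mother_pet is None:
        raise PedigreeError("split_parent_ntes requires a node with two parents")
    if c.direct_edge is None:
        raise PedigreeError(
            "corrupt label: two parents recorded but no direct non-tree edge"
        )

    def rebuild(pet: PetLabel, cases: Tuple[EdgeCase, ...]) -> CpeLabel:
        ntes = tuple(
            NonTreeEdge(e.source, e.dest, EdgeCase.GENERIC)
            for e in c.ntes
            if e.case in cases
        )
        return CpeLabel(pet=pet, ntes=ntes)

    return {
        "father": rebuild(father_pet, (EdgeCase.PATERNAL, EdgeCase.BOTH)),
        "mother": rebuild(mother_pet, (EdgeCase.MATERNAL, EdgeCase.BOTH)),
    }


def ancestor_set(c: CpeLabel) -> FrozenSet[PetLabel]:
    """PETs of every ancestor-or-self of a node, read off its label.

    Component prefixes of the node's PET (including the full PET) cover all
    tree-path ancestors; component prefixes of each non-tree edge source
    cover the rest.  The empty prefix (the virtual root) is excluded.
    """
    out: Set[PetLabel] = set(c.pet.prefixes())
    for e in c.ntes:
        out.update(e.source.prefixes())
    return frozenset(out)


def common_ancestors(cf: CpeLabel, cm: CpeLabel) -> FrozenSet[PetLabel]:
    """Ancestors-or-self shared by two labelled nodes (set intersection)."""
    return ancestor_set(cf) & ancestor_set(cm)


def prune_nonessential(
    ancestors: FrozenSet[PetLabel],
    cf: CpeLabel,
    cm: CpeLabel,
    table: LabelTable,
) -> FrozenSet[PetLabel]:
    """Drop common ancestors that cannot yield a non-overlapping path pair.

    If, inside the subgraph of all paths from ancestor u to the two parents,
    u has exactly one child, every u-path funnels through that child, so all
    path pairs from u overlap there.  A child of u lies in that subgraph iff
    it is an ancestor-or-self of either parent.  The parents themselves are
    never pruned: a zero-length path (parent as its own ancestor) does not
    pass through any child.
    """
    p = table.rooted.pedigree
    anc_f, anc_m = ancestor_set(cf), ancestor_set(cm)
    in_subgraph = anc_f | anc_m
    keep: Set[PetLabel] = set()
    for a in ancestors:
        if a in (cf.pet, cm.pet):
            keep.add(a)
            continue
        uid = table.id_of(a)
        nsub = sum(1 for ch in p.children[uid] if table.pet(ch) in in_subgraph)
        if nsub != 1:
            keep.add(a)
    return frozenset(keep)


@dataclass
class OverlapMatrix:
    """Pairwise non-overlap flags for paths to the father (rows) x mother (cols).

    ``index`` is the inverted index: common-ancestor PET -> ids of the paths
    containing it.  Path ids are ``q1..qn`` for father paths and ``p1..pm``
    for mother paths, numbered in enumeration order.
    """

    ancestor: PetLabel
    father_paths: List[Path]
    mother_paths: List[Path]
    cells: Dict[Tuple[str, str], bool] = field(default_factory=dict)
    index: Dict[PetLabel, List[str]] = field(default_factory=dict)

    @property
    def row_ids(self) -> List[str]:
        return [f"q{i + 1}" for i in range(len(self.father_paths))]

    @property
    def col_ids(self) -> List[str]:
        return [f"p{i + 1}" for i in range(len(self.mother_paths))]


def overlap_matrix(
    ancestor: PetLabel,
    father_paths: Sequence[Path],
    mother_paths: Sequence[Path],
    common: FrozenSet[PetLabel],
) -> OverlapMatrix:
    """Eliminate overlapping pairs through the common-ancestor inverted index.

    Any node shared by a father path and a mother path other than the queried
    ancestor is itself a common ancestor-or-self of the two parents, so
    scanning the common-ancestor set alone is exhaustive: a cell stays True
    iff no other common ancestor indexes both paths.
    """
    m = OverlapMatrix(ancestor, list(father_paths), list(mother_paths))
    rows, cols = m.row_ids, m.col_ids
    membership: Dict[str, FrozenSet[PetLabel]] = {}
    for pid, path in list(zip(rows, father_paths)) + list(zip(cols, mother_paths)):
        membership[pid] = frozenset(path.nodes)
    for c in sorted(common):
        hits = [pid for pid in rows + cols if c in membership[pid]]
        if hits:
            m.index[c] = hits
    for q in rows:
        for p in cols:
            m.cells[(q, p)] = True
    for c, hits in m.index.items():
        if c == ancestor:
            continue
        hit_rows = [h for h in hits if h.startswith("q")]
        hit_cols = [h for h in hits if h.startswith("p")]
        for q in hit_rows:
            for p in hit_cols:
                m.cells[(q, p)] = False
    return m


def find_path_pairs(
    ancestor: PetLabel,
    cf: CpeLabel,
    cm: CpeLabel,
    memo: Optional[Dict] = None,
    common: Optional[FrozenSet[PetLabel]] = None,
) -> List[PathPair]:
    """All (father path, mother path) pairs from one common ancestor, flagged.

    ``memo`` is the shared path cache of :func:`find_paths`; ``common`` may
    carry the precomputed *full* common-ancestor set to avoid recomputing it
    per ancestor.  Overlap detection must see the unpruned set: a pruned
    ancestor still marks crossovers for pairs rooted elsewhere.
    """
    full_common = common if common is not None else common_ancestors(cf, cm)
    fps = find_paths(ancestor, cf, memo)
    mps = find_paths(ancestor, cm, memo)
    if not fps or not mps:
        return []
    m = overlap_matrix(ancestor, fps, mps, full_common)
    out: List[PathPair] = []
    for qi, q in zip(m.row_ids, fps):
        for pi, p in zip(m.col_ids, mps):
            out.append(
                PathPair(
                    ancestor=ancestor,
                    to_father=q,
                    to_mother=p,
                    non_overlapping=m.cells[(qi, pi)],
                )
            )
    return out
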