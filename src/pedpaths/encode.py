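"""CPE and NodeCodes label generation, label tables and space accounting.

The CPE encoder walks the rooted pedigree in Kahn (topological) breadth-first
order so that both parents of a node are finalized before the node itself —
the non-tree-edge list of a node is inherited from its parents' finalized
lists.  Each non-founder's tree edge comes from one parent (the *tree
parent*); with two parents the other contributes the node's *direct*
non-tree edge.

Two tree-parent policies are supported:

``"first"`` (default)
    The parent finalized earliest donates the tree edge.  This is the queue
    discipline of the original encoding algorithm and reproduces its printed
    worked-example labels, but the resulting tree is not a shortest-path
    tree (a node may be discovered through a long chain that finalizes
    early).

``"shallowest"``
    The finalized parent with the shortest PET donates the tree edge
    (ties broken by finalization order).  This yields depth(PET(v)) equal to
    the BFS distance from the virtual root for every node, and hence the
    minimal total label size among valid encodings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .labels import (
    CpeLabel,
    EdgeCase,
    NonTreeEdge,
    PetLabel,
    serialize_cpe,
    serialize_pet,
)
from .pedigree import (
    Pedigree,
    RootedPedigree,
    Sex,
    add_virtual_root,
    topological_order,
)

__all__ = [
    "LabelTable",
    "NodeCodes",
    "SpaceReport",
    "encode_cpe",
    "encode_nodecodes",
    "space_report",
    "compare_space",
]


class LabelTable:
    """Bijection individual id <-> PET, plus each individual's CPE label."""

    def __init__(self, rooted: RootedPedigree):
        self.rooted = rooted
        self._cpe: Dict[str, CpeLabel] = {}
        self._id_of_pet: Dict[PetLabel, str] = {}
        self._pet_of_id: Dict[str, PetLabel] = {}

    def _add(self, id: str, label: CpeLabel) -> None:
        self._cpe[id] = label
        self._id_of_pet[label.pet] = id
        self._pet_of_id[id] = label.pet

    def cpe(self, id: str) -> CpeLabel:
        return self._cpe[id]

    def pet(self, id: str) -> PetLabel:
        return self._pet_of_id[id]

    def id_of(self, pet: PetLabel) -> str:
        return self._id_of_pet[pet]

    def __contains__(self, id: str) -> bool:
        return id in self._cpe

    def __iter__(self):
        return iter(self._cpe.items())

    @property
    def ids(self) -> List[str]:
        return list(self._cpe)

    def to_tsv(self, compress_case0: bool = False) -> str:
        """Rows: individual_id, pet, cpe (serialized)."""
        lines = ["individual_id\tpet\tcpe"]
        for id, label in self._cpe.items():
            lines.append(
                f"{id}\t{serialize_pet(label.pet)}\t{serialize_cpe(label, compress_case0)}"
            )
        return "\n".join(lines) + "\n"


def _finalization_order(rooted: RootedPedigree) -> List[str]:
    """Virtual root first, then individuals in Kahn order (input-order ties)."""
    return [rooted.root_id] + topological_order(rooted.pedigree)


def encode_cpe(rp: RootedPedigree, tree_policy: str = "first") -> LabelTable:
    """Assign PET + non-tree-edge labels to every individual.

    Case tags are recomputed per node: the node's own non-tree parent edge is
    *direct*; an inherited edge is *paternal*, *maternal* or *both* according
    to which parents' edge sets contain it.  A single parent's edges take the
    tag of that parent's slot.  Serialized edge order groups by case tag
    ($ < * < # < &) and is stable within a group (father's edges, then the
    mother's new ones, the direct edge last).
    """
    if tree_policy not in ("first", "shallowest"):
        raise ValueError(f"unknown tree_policy {tree_policy!r}")
    p = rp.pedigree
    order = _finalization_order(rp)
    rank = {id: i for i, id in enumerate(order)}
    table = LabelTable(rp)
    pets: Dict[str, PetLabel] = {rp.root_id: PetLabel()}
    # per node: non-tree edge pairs in first-inheritance (insertion) order;
    # the serialized label re-groups them by case tag
    edges: Dict[str, List[Tuple[PetLabel, PetLabel]]] = {rp.root_id: []}
    tree_child_count: Dict[str, int] = {}

    for v in order[1:]:
        ind = p[v]
        parents = rp.parents(v)  # father slot first; (root,) for founders
        finalized = [q for q in parents if q in pets]
        if len(finalized) != len(parents):
            raise RuntimeError(f"parent of {v!r} not finalized before the child")
        if tree_policy == "first":
            tree_parent = min(finalized, key=lambda q: rank[q])
        else:
            tree_parent = min(finalized, key=lambda q: (len(pets[q]), rank[q]))
        idx = tree_child_count.get(tree_parent, 0)
        tree_child_count[tree_parent] = idx + 1
        pet = pets[tree_parent].child(idx, ind.sex)

        father_pairs = set(edges.get(ind.father_id, ())) if ind.father_id else set()
        mother_pairs = set(edges.get(ind.mother_id, ())) if ind.mother_id else set()

        # inherit in father-list / mother-new order, direct edge appended last
        inherited: List[Tuple[PetLabel, PetLabel]] = []
        seen: set = set()
        for q in (ind.father_id, ind.mother_id):
            if q is None:
                continue
            for pair in edges[q]:
                if pair not in seen:
                    seen.add(pair)
                    inherited.append(pair)
        direct: Optional[Tuple[PetLabel, PetLabel]] = None
        if len(parents) == 2:
            non_tree_parent = next(q for q in parents if q != tree_parent)
            direct = (pets[non_tree_parent], pet)

        def tag(pair: Tuple[PetLabel, PetLabel]) -> EdgeCase:
            if pair == direct:
                return EdgeCase.DIRECT
            in_f, in_m = pair in father_pairs, pair in mother_pairs
            if in_f and in_m:
                return EdgeCase.BOTH
            return EdgeCase.PATERNAL if in_f else EdgeCase.MATERNAL

        all_pairs = inherited + ([direct] if direct else [])
        ntes = tuple(
            sorted(
                (NonTreeEdge(s, d, tag((s, d))) for s, d in all_pairs),
                key=lambda e: e.case,
            )
        )
        pets[v] = pet
        edges[v] = all_pairs
        table._add(v, CpeLabel(pet=pet, ntes=ntes))
    return table


class NodeCodes:
    """Per-individual sets of root->node path codes (one code per path)."""

    def __init__(self, rooted: RootedPedigree):
        self.rooted = rooted
        self.codes: Dict[str, frozenset] = {}
        self._id_of_code: Dict[PetLabel, str] = {}

    def __getitem__(self, id: str) -> frozenset:
        return self.codes[id]

    def __iter__(self):
        return iter(self.codes.items())

    def id_of(self, code: PetLabel) -> str:
        return self._id_of_code[code]

    def to_tsv(self) -> str:
        """Rows: individual_id, code — one row per code."""
        lines = ["individual_id\tcode"]
        for id, codes in self.codes.items():
            for c in sorted(codes):
                lines.append(f"{id}\t{serialize_pet(c)}")
        return "\n".join(lines) + "\n"


def encode_nodecodes(rp: RootedPedigree) -> NodeCodes:
    """Assign NodeCodes: child code = parent code + sibling index + sex mark.

    Sibling indices number *all* children of a parent in input order (unlike
    PET indices, which number tree children only).  Individuals are processed
    in the same finalization order as the CPE encoder so every parent's code
    set is complete before its children extend it.
    """
    p = rp.pedigree
    nc = NodeCodes(rp)
    codes: Dict[str, set] = {rp.root_id: {PetLabel()}}
    child_index: Dict[str, Dict[str, int]] = {
        rp.root_id: {c: i for i, c in enumerate(rp.root_children)}
    }
    for u in p.ids:
        child_index[u] = {c: i for i, c in enumerate(p.children[u])}
    for v in _finalization_order(rp)[1:]:
        sex = p[v].sex
        vset: set = set()
        for q in rp.parents(v):
            i = child_index[q][v]
            for x in codes[q]:
                vset.add(x.child(i, sex))
        codes[v] = vset
        nc.codes[v] = frozenset(vset)
        for c in vset:
            nc._id_of_code[c] = v
    return nc


@dataclass
class SpaceReport:
    """Label-size accounting for one encoding of one pedigree.

    ``space_total`` counts PET components (sex delimiters ignored):
    the sum of every node's PET length plus, for each distinct non-tree edge
    e = (vi, vj), its encoded length Len(e) = |PET(vi)| + |PET(vj)| times the
    number of labels that carry it, |Des(vj)| + 1 (vj and all its
    descendants).  ``serialized_char_total`` is the plain character count of
    the serialized labels.
    """

    scheme: str
    total_pet_units: int
    per_edge: List[dict] = field(default_factory=list)
    space_total: int = 0
    serialized_char_total: int = 0


def _descendant_counts(p: Pedigree) -> Dict[str, int]:
    """Strict descendant counts via reverse topological accumulation of sets."""
    desc: Dict[str, set] = {id: set() for id in p.ids}
    for v in reversed(topological_order(p)):
        s = desc[v]
        for c in p.children[v]:
            s.add(c)
            s |= desc[c]
    return {id: len(s) for id, s in desc.items()}


def space_report(labels) -> SpaceReport:
    """Size accounting for a :class:`LabelTable` (CPE) or :class:`NodeCodes`."""
    if isinstance(labels, NodeCodes):
        units = sum(len(c) for _, cs in labels for c in cs)
        chars = sum(len(serialize_pet(c)) for _, cs in labels for c in cs)
        return SpaceReport(
            scheme="nodecodes",
            total_pet_units=units,
            space_total=units,
            serialized_char_total=chars,
        )
    table: LabelTable = labels
    p = table.rooted.pedigree
    ndesc = _descendant_counts(p)
    pet_units = sum(len(table.pet(id)) for id in table.ids)
    distinct: Dict[Tuple[PetLabel, PetLabel], str] = {}
    for id, label in table:
        for e in label.ntes:
            distinct.setdefault(e.pair, table.id_of(e.dest))
    per_edge = []
    total_edges = 0
    for (src, dst), dst_id in distinct.items():
        length = len(src) + len(dst)
        contrib = length * (ndesc[dst_id] + 1)
        per_edge.append(
            {
                "edge": (table.id_of(src), dst_id),
                "len": length,
                "descendants": ndesc[dst_id],
                "contribution": contrib,
            }
        )
        total_edges += contrib
    chars = sum(len(serialize_cpe(label)) for _, label in table)
    return SpaceReport(
        scheme="cpe",
        total_pet_units=pet_units,
        per_edge=per_edge,
        space_total=pet_units + total_edges,
        serialized_char_total=chars,
    )


def compare_space(p: Pedigree, tree_policy: str = "first") -> dict:
    """Serialized-character totals of CPE vs NodeCodes and the relative saving."""
    rp = add_virtual_root(p)
    cpe_total = space_report(encode_cpe(rp, tree_policy=tree_policy)).serialized_char_total
    nc_total = space_report(encode_nodecodes(rp)).serialized_char_total
    improvement = 100.0 * (nc_total - cpe_total) / nc_total if nc_total else 0.0
    return {
        "cpe_total": cpe_total,
        "nodecodes_total": nc_total,
        "improvement_percent": improvement,
    }
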