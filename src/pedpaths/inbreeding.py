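"""Inbreeding coefficients by path counting, plus a recursive kinship oracle.

Wright's path-counting formula expresses the inbreeding coefficient of an
individual n with father f and mother m as

    F_n = sum over common ancestors A of f, m
          sum over non-overlapping path pairs from A
              (1/2)^(s + r + 1) * (1 + F_A)

where s and r are the edge counts of the pair's paths A->f and A->m, and a
pair is non-overlapping when the two paths share no node besides A.  F_n
equals the kinship coefficient of f and m, which gives the independent
recursive check implemented in :func:`kinship_recursive`.

All arithmetic is exact (``fractions.Fraction``); floats appear only in
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .encode import LabelTable, NodeCodes, encode_cpe, encode_nodecodes
from .labels import PetLabel
from .paths import (
    PathPair,
    common_ancestors,
    find_path_pairs,
    prune_nonessential,
    split_parent_ntes,
)
from .pedigree import Pedigree, add_virtual_root, topological_order

__all__ = [
    "Contribution",
    "InbreedingResult",
    "wright_term",
    "kinship_recursive",
    "inbreeding_cpe",
    "inbreeding_nodecodes",
    "inbreeding_all",
    "inbreeding_table",
    "CpeInbreeding",
    "NodeCodesInbreeding",
]


@dataclass(frozen=True)
class Contribution:
    """One common ancestor's share of a coefficient."""

    ancestor_id: str
    n_pairs: int          # non-overlapping pairs through this ancestor
    term: Fraction        # summed Wright terms

    @property
    def value(self) -> float:
        return float(self.term)


@dataclass(frozen=True)
class InbreedingResult:
    """Coefficient F of one individual with its per-ancestor breakdown."""

    id: str
    F: Fraction
    contributions: Tuple[Contribution, ...] = ()
    method: str = ""

    @property
    def coefficient(self) -> float:
        return float(self.F)

    @property
    def n_common_ancestors(self) -> int:
        """Ancestors evaluated (after any pruning)."""
        return len(self.contributions)

    @property
    def n_pairs(self) -> int:
        """Total non-overlapping path pairs across ancestors."""
        return sum(c.n_pairs for c in self.contributions)


def wright_term(pair: PathPair, F_A: Fraction = Fraction(0)) -> Fraction:
    """One non-overlapping pair's term, (1/2)^(s+r+1) * (1 + F_A)."""
    if not pair.non_overlapping:
        raise ValueError("wright_term is defined for non-overlapping pairs only")
    return Fraction(1, 2 ** (pair.s + pair.r + 1)) * (1 + Fraction(F_A))


# ---------------------------------------------------------------------------
# recursive kinship oracle


def kinship_recursive(
    a: str,
    b: str,
    p: Pedigree,
    memo: Optional[Dict] = None,
) -> Fraction:
    """Kinship coefficient phi(a, b) by the classical parent recursion.

    phi(a, a) = (1 + phi(father_a, mother_a)) / 2; for distinct individuals
    the one later in topological order (never an ancestor of the other) is
    expanded into its parents, a missing parent contributing zero; distinct
    founders are unrelated.  Exact rational arithmetic, memoized on
    unordered pairs.
    """
    if memo is None:
        memo = {}
    if "__rank__" not in memo:
        memo["__rank__"] = {id: i for i, id in enumerate(topological_order(p))}
    rank = memo["__rank__"]

    def phi(x: str, y: str) -> Fraction:
        key = (x, y) if x <= y else (y, x)
        if key in memo:
            return memo[key]
        if x == y:
            ind = p[x]
            if ind.father_id is not None and ind.mother_id is not None:
                val = (1 + phi(ind.father_id, ind.mother_id)) / 2
            else:
                val = Fraction(1, 2)
        else:
            # expand the non-ancestor (the later one in topological order)
            if rank[x] < rank[y]:
                x, y = y, x
            ind = p[x]
            val = Fraction(0)
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    val += phi(pid, y) / 2
        memo[key] = val
        return val

    return phi(a, b)


def _recursive_F(n: str, p: Pedigree, memo: Optional[Dict] = None) -> Fraction:
    ind = p[n]
    if ind.father_id is None or ind.mother_id is None:
        return Fraction(0)
    return kinship_recursive(ind.father_id, ind.mother_id, p, memo)


# ---------------------------------------------------------------------------
# CPE pipeline


class CpeInbreeding:
    """Path-counting inbreeding over one pedigree's CPE label table.

    Ancestor coefficients F_A are computed by the same path-counting method,
    memoized per individual; the path cache is shared across the ancestors of
    one query and cleared between individuals.
    """

    method = "cpe"

    def __init__(self, table: LabelTable, improved: bool = False):
        self.table = table
        self.improved = improved
        if improved:
            self.method = "icpe"
        self._F: Dict[str, Fraction] = {}

    def coefficient(self, n: str) -> InbreedingResult:
        p = self.table.rooted.pedigree
        ind = p[n]
        if ind.father_id is None or ind.mother_id is None:
            return InbreedingResult(id=n, F=Fraction(0), method=self.method)
        cpe_n = self.table.cpe(n)
        parents = split_parent_ntes(cpe_n, self.table)
        cf, cm = parents["father"], parents["mother"]
        full = common_ancestors(cf, cm)
        evaluated = (
            prune_nonessential(full, cf, cm, self.table) if self.improved else full
        )
        memo: Dict = {}  # shared path cache for this individual's query
        contribs: List[Contribution] = []
        total = Fraction(0)
        for a_pet in sorted(evaluated):
            pairs = find_path_pairs(a_pet, cf, cm, memo=memo, common=full)
            nonov = [pr for pr in pairs if pr.non_overlapping]
            term = Fraction(0)
            if nonov:
                F_A = self._coefficient_value(self.table.id_of(a_pet))
                for pr in nonov:
                    term += wright_term(pr, F_A)
            contribs.append(
                Contribution(self.table.id_of(a_pet), len(nonov), term)
            )
            total += term
        return InbreedingResult(
            id=n, F=total, contributions=tuple(contribs), method=self.method
        )

    def _coefficient_value(self, n: str) -> Fraction:
        if n not in self._F:
            self._F[n] = self.coefficient(n).F
        return self._F[n]


def inbreeding_cpe(
    n: str,
    table: LabelTable,
    improved: bool = False,
) -> InbreedingResult:
    """Inbreeding coefficient of one individual from CPE labels."""
    return CpeInbreeding(table, improved=improved).coefficient(n)


# ---------------------------------------------------------------------------
# NodeCodes pipeline


class NodeCodesInbreeding:
    """Path-counting inbreeding over NodeCodes labels.

    A path from ancestor a to node n corresponds to a code pair (x, y) with
    x in NC(a) a component prefix of y in NC(n); intermediate nodes are read
    off y's prefixes.  Common ancestors come from prefix matching; overlap
    elimination and the Wright terms mirror the CPE pipeline on node-id
    sequences.
    """

    method = "nodecodes"

    def __init__(self, nc: NodeCodes):
        self.nc = nc
        self._F: Dict[str, Fraction] = {}
        self._anc: Dict[str, frozenset] = {}

    def _ancestors_or_self(self, n: str) -> frozenset:
        if n not in self._anc:
            out = set()
            for y in self.nc[n]:
                for pre in y.prefixes():
                    out.add(self.nc.id_of(pre))
            self._anc[n] = frozenset(out)
        return self._anc[n]

    def _paths(self, a: str, n: str, memo: Dict) -> List[Tuple[str, ...]]:
        key = (a, n)
        if key not in memo:
            seqs = set()
            for y in self.nc[n]:
                for x in self.nc[a]:
                    if x.is_prefix_of(y):
                        seqs.add(
                            tuple(
                                self.nc.id_of(PetLabel(y.components[:t]))
                                for t in range(len(x), len(y) + 1)
                            )
                        )
            memo[key] = sorted(seqs)
        return memo[key]

    def coefficient(self, n: str) -> InbreedingResult:
        p = self.nc.rooted.pedigree
        ind = p[n]
        if ind.father_id is None or ind.mother_id is None:
            return InbreedingResult(id=n, F=Fraction(0), method=self.method)
        f, m = ind.father_id, ind.mother_id
        common = self._ancestors_or_self(f) & self._ancestors_or_self(m)
        memo: Dict = {}
        contribs: List[Contribution] = []
        total = Fraction(0)
        for a in sorted(common):
            fps = self._paths(a, f, memo)
            mps = self._paths(a, m, memo)
            n_pairs = 0
            term = Fraction(0)
            f_a: Optional[Fraction] = None
            for q in fps:
                qset = set(q)
                for pp in mps:
                    shared = qset.intersection(pp)
                    if shared == {a}:
                        if f_a is None:
                            f_a = self._coefficient_value(a)
                        n_pairs += 1
                        s, r = len(q) - 1, len(pp) - 1
                        term += Fraction(1, 2 ** (s + r + 1)) * (1 + f_a)
            contribs.append(Contribution(a, n_pairs, term))
            total += term
        return InbreedingResult(
            id=n, F=total, contributions=tuple(contribs), method=self.method
        )

    def _coefficient_value(self, n: str) -> Fraction:
        if n not in self._F:
            self._F[n] = self.coefficient(n).F
        return self._F[n]


def inbreeding_nodecodes(n: str, nc: NodeCodes) -> InbreedingResult:
    """Inbreeding coefficient of one individual from NodeCodes labels."""
    return NodeCodesInbreeding(nc).coefficient(n)


# ---------------------------------------------------------------------------
# whole-pedigree driver


def inbreeding_all(
    p: Pedigree,
    method: str = "cpe",
    tree_policy: str = "first",
) -> Dict[str, InbreedingResult]:
    """Coefficients for every individual, in topological order.

    Methods: ``cpe``, ``icpe`` (nonessential-ancestor pruning), ``nodecodes``,
    ``recursive``.  Processing parents before children makes every ancestor
    coefficient final before use, and full siblings (same father and mother)
    are computed once and shared.
    """
    engine: Optional[object] = None
    if method in ("cpe", "icpe"):
        table = encode_cpe(add_virtual_root(p), tree_policy=tree_policy)
        engine = CpeInbreeding(table, improved=(method == "icpe"))
    elif method == "nodecodes":
        engine = NodeCodesInbreeding(encode_nodecodes(add_virtual_root(p)))
    elif method != "recursive":
        raise ValueError(f"unknown method {method!r}")

    results: Dict[str, InbreedingResult] = {}
    couple_cache: Dict[Tuple[Optional[str], Optional[str]], InbreedingResult] = {}
    rec_memo: Dict = {}
    for n in topological_order(p):
        ind = p[n]
        key = (ind.father_id, ind.mother_id)
        if None not in key and key in couple_cache:
            prev = couple_cache[key]
            results[n] = InbreedingResult(
                id=n, F=prev.F, contributions=prev.contributions, method=prev.method
            )
            continue
        if method == "recursive":
            res = InbreedingResult(
                id=n, F=_recursive_F(n, p, rec_memo), method="recursive"
            )
        else:
            res = engine.coefficient(n)  # type: ignore[union-attr]
            engine._F[n] = res.F  # type: ignore[union-attr]
        results[n] = res
        if None not in key:
            couple_cache[key] = res
    return {id: results[id] for id in p.ids}


def inbreeding_table(results: Dict[str, InbreedingResult], exact: bool = False) -> pd.DataFrame:
    """Tabulate results: individual_id, F, n_common_ancestors, n_pairs."""
    rows = [
        {
            "individual_id": r.id,
            "F": str(r.F) if exact else float(r.F),
            "n_common_ancestors": r.n_common_ancestors,
            "n_pairs": r.n_pairs,
        }
        for r in results.values()
    ]
    return pd.DataFrame(rows, columns=["individual_id", "F", "n_common_ancestors", "n_pairs"])
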