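"""Label types and their text grammar.

A PET label is a sequence of (sibling index, sex mark) components; the tree
parent's label is always the label minus its last component, so component
prefixes walk up the spanning tree.  Sibling indices are rendered in a
base-64 alphabet (one or more digits), sex marks are the single characters
'.' (female), ',' (male), ';' (unknown) — the mark doubles as the component
delimiter, which keeps multi-digit indices unambiguous.

A CPE label is a PET plus an ordered list of non-tree edges; each edge is a
(source PET, dest PET) pair wrapped in a case-tag delimiter:

    '$' direct      — the node's own non-tree parent edge
    '*' paternal    — inherited through the father only
    '#' maternal    — inherited through the mother only
    '&' both        — inherited through both parents
    '%' generic     — case information unavailable (reconstructed labels)

Optionally the direct edge's destination (always the node itself) is
compressed to '?'.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

from .pedigree import Sex

__all__ = [
    "EdgeCase",
    "PetLabel",
    "NonTreeEdge",
    "CpeLabel",
    "LabelParseError",
    "serialize_pet",
    "parse_pet",
    "serialize_cpe",
    "parse_cpe",
    "encode_index",
    "decode_index",
]

#: Base-64 digit alphabet for sibling indices (positional, most significant first).
_B64 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz+/"
_B64_VAL = {c: i for i, c in enumerate(_B64)}

_MARKS = {s.mark: s for s in Sex}


class LabelParseError(ValueError):
    """Malformed PET/CPE text."""


class EdgeCase(enum.IntEnum):
    """Provenance of a non-tree edge relative to the node's parents."""

    DIRECT = 0     # '$'  the node's own non-tree parent edge
    PATERNAL = 1   # '*'  in the father's set only
    MATERNAL = 2   # '#'  in the mother's set only
    BOTH = 3       # '&'  in both parents' sets
    GENERIC = 4    # '%'  unknown (parent labels reconstructed from a child)

    @property
    def tag(self) -> str:
        return "$*#&%"[self]


_TAG_TO_CASE = {c.tag: c for c in EdgeCase}


def encode_index(i: int) -> str:
    """Render a non-negative sibling index in the base-64 alphabet."""
    if i < 0:
        raise ValueError("sibling index must be non-negative")
    if i == 0:
        return "0"
    digits = []
    while i:
        digits.append(_B64[i % 64])
        i //= 64
    return "".join(reversed(digits))


def decode_index(text: str) -> int:
    val = 0
    for c in text:
        if c not in _B64_VAL:
            raise LabelParseError(f"digit {c!r} outside the base-64 alphabet")
        val = val * 64 + _B64_VAL[c]
    return val


@dataclass(frozen=True)
class PetLabel:
    """Prefix code of a node on the spanning tree; empty only for the root."""

    components: Tuple[Tuple[int, Sex], ...] = ()

    @classmethod
    def of(cls, *components: Tuple[int, Sex]) -> "PetLabel":
        return cls(tuple(components))

    @property
    def depth(self) -> int:
        return len(self.components)

    def __len__(self) -> int:
        return len(self.components)

    def __bool__(self) -> bool:
        return bool(self.components)

    def child(self, index: int, sex: Sex) -> "PetLabel":
        return PetLabel(self.components + ((index, sex),))

    def parent(self) -> "PetLabel":
        """The tree parent's label (drop the last component)."""
        if not self.components:
            raise ValueError("the root label has no parent")
        return PetLabel(self.components[:-1])

    def is_prefix_of(self, other: "PetLabel") -> bool:
        """Component-boundary prefix test (``self`` may equal ``other``)."""
        return other.components[: len(self.components)] == self.components

    def prefixes(self, proper: bool = False) -> Iterable["PetLabel"]:
        """Non-empty component prefixes, shortest first, including self unless proper."""
        stop = len(self.components) + (0 if proper else 1)
        for j in range(1, stop):
            yield PetLabel(self.components[:j])

    def __str__(self) -> str:
        return serialize_pet(self)

    def __repr__(self) -> str:
        return f"PetLabel({serialize_pet(self)!r})"

    # Lexicographic order on components gives deterministic iteration downstream.
    def __lt__(self, other: "PetLabel") -> bool:
        key = tuple((i, s.mark) for i, s in self.components)
        okey = tuple((i, s.mark) for i, s in other.components)
        return key < okey


@dataclass(frozen=True)
class NonTreeEdge:
    """A pedigree edge excluded from the spanning tree, as a PET pair + case tag."""

    source: PetLabel
    dest: PetLabel
    case: EdgeCase

    @property
    def pair(self) -> tuple[PetLabel, PetLabel]:
        """Identity of the edge, independent of the case tag."""
        return (self.source, self.dest)


@dataclass(frozen=True)
class CpeLabel:
    """A node's PET plus the ordered non-tree edges of its path-induced subgraph."""

    pet: PetLabel
    ntes: Tuple[NonTreeEdge, ...] = ()

    @property
    def direct_edge(self) -> Optional[NonTreeEdge]:
        """The edge ending at the node itself (its non-tree parent edge), if any."""
        for e in self.ntes:
            if e.dest == self.pet:
                return e
        return None

    def __str__(self) -> str:
        return serialize_cpe(self)

    def __repr__(self) -> str:
        return f"CpeLabel({serialize_cpe(self)!r})"


def serialize_pet(label: PetLabel) -> str:
    return "".join(encode_index(i) + s.mark for i, s in label.components)


def parse_pet(text: str) -> PetLabel:
    comps: list[Tuple[int, Sex]] = []
    digits = ""
    for c in text:
        if c in _MARKS:
            if not digits:
                raise LabelParseError(f"empty sibling index before {c!r} in {text!r}")
            comps.append((decode_index(digits), _MARKS[c]))
            digits = ""
        elif c in _B64_VAL:
            digits += c
        else:
            raise LabelParseError(f"unexpected character {c!r} in PET {text!r}")
    if digits:
        raise LabelParseError(f"dangling digits {digits!r} without a sex delimiter in {text!r}")
    return PetLabel(tuple(comps))


def serialize_cpe(label: CpeLabel, compress_case0: bool = False) -> str:
    parts = [serialize_pet(label.pet)]
    for e in label.ntes:
        t = e.case.tag
        dest = serialize_pet(e.dest)
        if compress_case0 and e.case is EdgeCase.DIRECT:
            dest = "?"
        parts.append(t + serialize_pet(e.source) + t + dest)
    return "".join(parts)


def parse_cpe(text: str) -> CpeLabel:
    """Invert :func:`serialize_cpe` ('?' restores to the node's own PET)."""
    tag_positions = [i for i, c in enumerate(text) if c in _TAG_TO_CASE]
    pet_end = tag_positions[0] if tag_positions else len(text)
    pet = parse_pet(text[:pet_end])
    ntes: list[NonTreeEdge] = []
    if not tag_positions:
        return CpeLabel(pet=pet)
    if len(tag_positions) % 2:
        raise LabelParseError(f"unbalanced edge delimiters in {text!r}")
    bounds = tag_positions + [len(text)]
    for k in range(0, len(tag_positions), 2):
        i, j, end = bounds[k], bounds[k + 1], bounds[k + 2]
        if text[i] != text[j]:
            raise LabelParseError(
                f"mismatched edge delimiters {text[i]!r}/{text[j]!r} in {text!r}"
            )
        case = _TAG_TO_CASE[text[i]]
        src = parse_pet(text[i + 1 : j])
        dest_text = text[j + 1 : end]
        if dest_text == "?":
            if case is not EdgeCase.DIRECT:
                raise LabelParseError("'?' shorthand is only valid on a direct ('$') edge")
            dest = pet
        else:
            dest = parse_pet(dest_text)
        ntes.append(NonTreeEdge(src, dest, case))
    return CpeLabel(pet=pet, ntes=tuple(ntes))
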