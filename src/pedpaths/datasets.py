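"""Built-in example data.

The eight-individual example pedigree exercises every interesting feature of
the encodings in a desk-checkable size: multiple founders, a single-parent
individual, a half-sib mating, an inbred ancestor, and a node (P7) whose
tree path and shortest root path differ.

Structure (parent -> child):

    P0 (F), P1 (M)            founders
    P2 (M) <- father P1, mother P0
    P3 (F) <- father P1                (single recorded parent)
    P4 (F) <- father P2, mother P3
    P5 (M) <- mother P4                (single recorded parent)
    P6 (F) <- father P1, mother P4
    P7 (M) <- father P5, mother P6
"""

from __future__ import annotations

from .pedigree import Pedigree, load_ped

__all__ = ["EXAMPLE_PED_TEXT", "example_pedigree"]

EXAMPLE_PED_TEXT = """\
# family  id  father  mother  sex
FAM1 P0 0  0  2
FAM1 P1 0  0  1
FAM1 P2 P1 P0 1
FAM1 P3 P1 0  2
FAM1 P4 P2 P3 2
FAM1 P5 0  P4 1
FAM1 P6 P1 P4 2
FAM1 P7 P5 P6 1
"""


def example_pedigree() -> Pedigree:
    """The eight-individual example pedigree (founders P0, P1)."""
    return load_ped(EXAMPLE_PED_TEXT)
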