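"""Per-position structural-element encoding of secondary structures.

Each position of a structure is classified into one of six element
types, by the standard loop taxonomy:

``f``  unpaired 5' end (before the first paired position)
``t``  unpaired 3' end (after the last paired position)
``s``  stem (paired)
``h``  hairpin loop (innermost loop closed by a single helix)
``i``  interior/bulge loop (loop bordered by exactly one enclosed helix)
``m``  multiloop (loop bordered by two or more enclosed helices,
       including the exterior loop between top-level helices)

The element string is a pure function of the pair set.  Structures with
no pairs are coded all-``f`` by convention (the taxonomy is undefined
for pairless chains).  One-hot expansion of element strings yields the
numeric matrix used for dimensionality reduction and clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure import SecondaryStructure

__all__ = ["ELEMENT_ORDER", "ElementMatrix", "to_elements", "to_matrix"]

#: Fixed order of element classes used for one-hot blocks and tie-breaks.
ELEMENT_ORDER = "ftshim"
_ELEMENT_INDEX = {c: k for k, c in enumerate(ELEMENT_ORDER)}

_EXTERIOR = -1


def to_elements(structure: SecondaryStructure) -> str:
    """Encode a structure as its length-L element string."""
    L = structure.length
    if not structure.pairs:
        return "f" * L
    db = structure.dot_bracket
    codes = [""] * L
    # child_count[p] = number of helices directly enclosed by the pair
    # opening at position p (0-based); _EXTERIOR keys the exterior loop.
    child_count: dict[int, int] = {_EXTERIOR: 0}
    enclosing = [_EXTERIOR] * L
    stack: list[int] = []
    for pos, c in enumerate(db):
        if c == "(":
            parent = stack[-1] if stack else _EXTERIOR
            child_count[parent] = child_count.get(parent, 0) + 1
            child_count.setdefault(pos, 0)
            stack.append(pos)
        elif c == ")":
            stack.pop()
        else:
            enclosing[pos] = stack[-1] if stack else _EXTERIOR
    paired = [c != "." for c in db]
    first = paired.index(True)
    last = L - 1 - paired[::-1].index(True)
    for pos in range(L):
        if paired[pos]:
            codes[pos] = "s"
        elif enclosing[pos] == _EXTERIOR:
            if pos < first:
                codes[pos] = "f"
            elif pos > last:
                codes[pos] = "t"
            else:
                codes[pos] = "m"
        else:
            n = child_count[enclosing[pos]]
            codes[pos] = "h" if n == 0 else ("i" if n == 1 else "m")
    return "".join(codes)


@dataclass(frozen=True)
class ElementMatrix:
    """Numeric matrix of element strings, one row per structure.

    With one-hot encoding the matrix has ``L * 6`` columns, the six
    columns of each position block following :data:`ELEMENT_ORDER` and
    summing to one per row.  Ordinal encoding (``L`` columns of class
    indices) is available for sensitivity checks.
    """

    values: np.ndarray
    read_ids: tuple
    length: int
    encoding: str = "onehot"

    @property
    def n_structures(self) -> int:
        return self.values.shape[0]


def to_matrix(
    element_strings: Sequence[str],
    read_ids: Sequence[str] | None = None,
    encoding: str = "onehot",
) -> ElementMatrix:
    """One-hot (default) or ordinal expansion of element strings.

    Row order follows input order.  All strings must share one length;
    a mismatch raises ``ValueError`` naming the offending read.
    """
    if encoding not in ("onehot", "ordinal"):
        raise ValueError(f"unknown encoding {encoding!r}")
    strings = list(element_strings)
    if not strings:
        raise ValueError("no element strings supplied")
    if read_ids is None:
        read_ids = [str(k) for k in range(len(strings))]
    read_ids = list(read_ids)
    if len(read_ids) != len(strings):
        raise ValueError("read_ids and element_strings differ in length")
    L = len(strings[0])
    for rid, s in zip(read_ids, strings):
        if len(s) != L:
            raise ValueError(
                f"element string of read {rid!r} has length {len(s)}, expected {L}"
            )
    idx = np.array(
        [[_ELEMENT_INDEX[c] for c in s] for s in strings], dtype=np.int64
    )
    if encoding == "ordinal":
        values = idx.astype(np.float64)
    else:
        n = len(strings)
        values = np.zeros((n, L * len(ELEMENT_ORDER)))
        cols = np.arange(L) * len(ELEMENT_ORDER) + idx
        values[np.arange(n)[:, None], cols] = 1.0
    return ElementMatrix(
        values=values, read_ids=tuple(read_ids), length=L, encoding=encoding
    )


def consensus_elements(element_strings: Sequence[str]) -> str:
    """Positionwise most common element, ties broken by ELEMENT_ORDER."""
    strings = list(element_strings)
    if not strings:
        raise ValueError("no element strings supplied")
    L = len(strings[0])
    counts = np.zeros((L, len(ELEMENT_ORDER)), dtype=np.int64)
    for s in strings:
        for p, c in enumerate(s):
            counts[p, _ELEMENT_INDEX[c]] += 1
    # argmax returns the first maximum, i.e. the earliest class in
    # ELEMENT_ORDER, which is the documented tie-break (f<t<s<h<i<m).
    return "".join(ELEMENT_ORDER[k] for k in counts.argmax(axis=1))
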