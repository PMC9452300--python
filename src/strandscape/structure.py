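"""Nested secondary-structure container and notation round trips.

A secondary structure over positions ``1..L`` is a set of base pairs in
which no position participates in more than one pair and no two pairs
cross (pseudoknot-free).  Such a structure maps one-to-one onto a
dot-bracket string over ``.``, ``(`` and ``)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = ["SecondaryStructure"]


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free pairing of one sequence.

    Parameters
    ----------
    length:
        Number of nucleotides ``L``.
    pairs:
        Base pairs ``(i, j)`` with ``1 <= i < j <= L`` (1-based, closed).
    sequence_ref:
        Identifier of the reference sequence this structure belongs to.
    """

    length: int
    pairs: frozenset = field(default_factory=frozenset)
    sequence_ref: str = ""

    def __post_init__(self) -> None:
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if self.length < 1:
            raise ValueError("length must be >= 1")
        seen: set[int] = set()
        for i, j in pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(
                    f"pair ({i},{j}) is not ordered inside 1..{self.length}"
                )
            for p in (i, j):
                if p in seen:
                    raise ValueError(f"position {p} participates in two pairs")
                seen.add(p)
        self._check_nested(pairs)

    @staticmethod
    def _check_nested(pairs: frozenset) -> None:
        # Stack sweep: a closing position must match the most recent opening.
        open_at = {i: j for i, j in pairs}
        close_at = {j: i for i, j in pairs}
        stack: list[int] = []
        positions = sorted(set(open_at) | set(close_at))
        for p in positions:
            if p in open_at:
                stack.append(open_at[p])
            else:
                if not stack or stack[-1] != p:
                    i = close_at[p]
                    raise ValueError(f"pair ({i},{p}) crosses another pair")
                stack.pop()

    # ------------------------------------------------------------------
    # views
    # ------------------------------------------------------------------
    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner(self) -> np.ndarray:
        """Partner array, 1-based; ``partner[i] == 0`` means unpaired."""
        part = np.zeros(self.length + 1, dtype=np.int64)
        for i, j in self.pairs:
            part[i] = j
            part[j] = i
        return part

    @property
    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    @classmethod
    def from_dot_bracket(cls, db: str, sequence_ref: str = "") -> "SecondaryStructure":
        pairs = []
        stack: list[int] = []
        for pos, c in enumerate(db, start=1):
            if c == "(":
                stack.append(pos)
            elif c == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {pos}")
                pairs.append((stack.pop(), pos))
            elif c != ".":
                raise ValueError(f"invalid dot-bracket character {c!r} at {pos}")
        if stack:
            raise ValueError(f"unbalanced '(' at position {stack[-1]}")
        return cls(length=len(db), pairs=frozenset(pairs), sequence_ref=sequence_ref)

    def to_ct(self, sequence: str, title: str | None = None) -> str:
        """Render the structure in connectivity-table (CT) format."""
        if len(sequence) != self.length:
            raise ValueError("sequence length does not match structure length")
        part = self.partner()
        lines = [f"{self.length} {title or self.sequence_ref or 'structure'}"]
        for i in range(1, self.length + 1):
            nxt = i + 1 if i < self.length else 0
            lines.append(
                f"{i} {sequence[i - 1]} {i - 1} {nxt} {part[i]} {i}"
            )
        return "\n".join(lines) + "\n"


def write_dot_bracket_file(
    path,
    structures: Iterable[tuple[str, SecondaryStructure]],
    sequence: str | None = None,
) -> None:
    """Write a Vienna-style multi-structure file with ``>read_id`` headers."""
    with open(path, "w") as fh:
        for read_id, s in structures:
            fh.write(f">{read_id}\n")
            if sequence is not None:
                fh.write(sequence + "\n")
            fh.write(s.dot_bracket + "\n")


def read_dot_bracket_file(path) -> list[tuple[str, SecondaryStructure]]:
    """Read a file written by :func:`write_dot_bracket_file`.

    Lines after each header that consist solely of dot-bracket characters
    are taken as the structure; an optional sequence line is skipped.
    """
    out: list[tuple[str, SecondaryStructure]] = []
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].strip()
            elif set(line) <= {".", "(", ")"}:
                out.append((name or "", SecondaryStructure.from_dot_bracket(line, sequence_ref=name or "")))
    return out
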