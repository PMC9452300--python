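"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's dynamic-programming code paths:
structures are enumerated recursively and weighted directly from the
grammar's declared semantics (unpaired emissions, stacked-scale pair
weights, one helix-initiation factor per maximal stack).
"""

from __future__ import annotations

import numpy as np


def enumerate_pair_sets(seq: str, min_hairpin: int, can_pair) -> list[frozenset]:
    """All nested pair sets (0-based) over ``seq`` honouring min_hairpin."""

    def rec(positions: tuple) -> list[frozenset]:
        if not positions:
            return [frozenset()]
        first, rest = positions[0], positions[1:]
        out = list(rec(rest))  # first unpaired
        for idx, k in enumerate(rest):
            if k - first - 1 >= min_hairpin and can_pair(first, k):
                inside = rest[:idx]
                outside = rest[idx + 1 :]
                for si in rec(inside):
                    for so in rec(outside):
                        out.append(si | so | {(first, k)})
        return out

    return rec(tuple(range(len(seq))))


def structure_weight(seq: str, pairs_0based: frozenset, grammar) -> float:
    """Weight of one structure straight from the grammar semantics."""
    lw = (len(seq) - 2 * len(pairs_0based)) * np.log(grammar.unpaired_weight)
    for i, j in pairs_0based:
        w = grammar.pair_weights.get(seq[i] + seq[j], 0.0)
        if w <= 0:
            return 0.0
        lw += np.log(w)
        if (i - 1, j + 1) not in pairs_0based:  # helix-initiating pair
            lw += np.log(grammar.helix_init)
    return float(np.exp(lw))


def exact_distribution(
    seq: str, grammar, constraints: np.ndarray | None = None
) -> dict[frozenset, float]:
    """Exact structure probabilities (keys: 1-based pair frozensets)."""
    seq = seq.upper().replace("T", "U")

    def can_pair(i: int, j: int) -> bool:
        if constraints is not None and (constraints[i] or constraints[j]):
            return False
        return grammar.pair_weights.get(seq[i] + seq[j], 0.0) > 0

    weights: dict[frozenset, float] = {}
    for ps in enumerate_pair_sets(seq, grammar.min_hairpin, can_pair):
        w = structure_weight(seq, ps, grammar)
        if w > 0 or not ps:
            key = frozenset((i + 1, j + 1) for i, j in ps)
            weights[key] = weights.get(key, 0.0) + w
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def naive_pair_counts(structures) -> dict[tuple[int, int], int]:
    """Plain pair counting, independent of the ensemble-stats module."""
    counts: dict[tuple[int, int], int] = {}
    for s in structures:
        for p in s.pairs:
            counts[p] = counts.get(p, 0) + 1
    return counts
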