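"""Base-pair probabilities and positional statistics over an ensemble.

Given any collection of structures of one sequence (the whole landscape
or one cluster), the pair probability ``P_ij`` is the fraction of
structures containing pair ``(i, j)``.  Derived per-position statistics:

* pairing probability ``P_i = sum_j P_ij`` over all partners ``j`` on
  either side of ``i``;
* likelihood of single-strandedness ``1 - P_i``;
* Shannon entropy ``E_i = sum_j -P_ij * log10(P_ij)``, summed over
  pairing partners only (terms with ``P_ij = 0`` contribute 0 by
  continuity).  High entropy marks structurally variable positions.

The literal entropy above ignores the unpaired state; an extended
variant that adds the ``1 - P_i`` term is available behind a flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure import SecondaryStructure

__all__ = ["EnsembleStats", "pair_probabilities", "per_cluster_stats"]


@dataclass(frozen=True)
class EnsembleStats:
    """Pairwise and positional statistics of a structure ensemble."""

    length: int
    n_structures: int
    pair_probs: Mapping[tuple[int, int], float]
    p_paired: np.ndarray
    single_strandedness: np.ndarray
    entropy: np.ndarray
    entropy_with_unpaired: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Per-position statistics as a DataFrame (1-based positions)."""
        return pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "p_paired": self.p_paired,
                "single_strandedness": self.single_strandedness,
                "entropy": self.entropy,
            }
        )

    def pair_table(self) -> pd.DataFrame:
        """Pair-probability table with columns i, j, p (1-based)."""
        items = sorted(self.pair_probs.items())
        return pd.DataFrame(
            {
                "i": [ij[0] for ij, _ in items],
                "j": [ij[1] for ij, _ in items],
                "p": [p for _, p in items],
            }
        )


def pair_probabilities(structures: Sequence[SecondaryStructure]) -> EnsembleStats:
    """Count pair frequencies over the ensemble and derive positional stats.

    Every pair is counted once per structure; ``P_i`` accumulates
    partners on both sides (``j < i`` and ``j > i``).
    """
    structures = list(structures)
    if not structures:
        raise ValueError("empty structure collection")
    L = structures[0].length
    if any(s.length != L for s in structures):
        raise ValueError("structures have unequal lengths")
    n = len(structures)
    counts: Counter = Counter()
    for s in structures:
        counts.update(s.pairs)
    probs = {ij: c / n for ij, c in counts.items()}
    p_paired = np.zeros(L)
    entropy = np.zeros(L)
    for (i, j), p in probs.items():
        p_paired[i - 1] += p
        p_paired[j - 1] += p
        term = -p * np.log10(p) if p > 0 else 0.0
        entropy[i - 1] += term
        entropy[j - 1] += term
    ss = 1.0 - p_paired
    with np.errstate(divide="ignore", invalid="ignore"):
        unp_term = np.where(ss > 0, -ss * np.log10(np.maximum(ss, 1e-300)), 0.0)
    return EnsembleStats(
        length=L,
        n_structures=n,
        pair_probs=probs,
        p_paired=p_paired,
        single_strandedness=ss,
        entropy=entropy,
        entropy_with_unpaired=entropy + unp_term,
    )


def per_cluster_stats(
    labels: Sequence[int],
    structures: Sequence[SecondaryStructure],
) -> dict[int, EnsembleStats]:
    """Ensemble statistics restricted to each cluster's members.

    ``labels`` must assign a cluster id to every structure.  Empty
    clusters simply do not appear in the result.
    """
    labels = np.asarray(labels)
    if len(labels) != len(structures):
        raise ValueError("labels do not cover all structures")
    out: dict[int, EnsembleStats] = {}
    for lab in np.unique(labels):
        members = [s for s, l in zip(structures, labels) if l == lab]
        out[int(lab)] = pair_probabilities(members)
    return out
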