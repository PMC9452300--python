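"""Base-pairing similarity between two secondary structures.

The positive predictive value (PPV) is the fraction of predicted base
pairs present in the reference structure; sensitivity is the fraction of
reference pairs recovered.  Pairs match exactly by default; a
slip-tolerant mode (one position of slack on either strand, as in some
published PPV variants) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

from .structure import SecondaryStructure

__all__ = ["PairSimilarity", "ppv"]


@dataclass(frozen=True)
class PairSimilarity:
    ppv: float
    sensitivity: float
    n_pred: int
    n_ref: int
    n_common: int


def _matches(pair, ref_pairs, slip: int) -> bool:
    i, j = pair
    if slip == 0:
        return pair in ref_pairs
    for di in range(-slip, slip + 1):
        for dj in range(-slip, slip + 1):
            if (i + di, j + dj) in ref_pairs:
                return True
    return False


def ppv(
    predicted: SecondaryStructure,
    reference: SecondaryStructure,
    slip: int = 0,
) -> PairSimilarity:
    """PPV and sensitivity of ``predicted`` against ``reference``.

    Requires equal lengths and at least one predicted pair (PPV is
    undefined for a pairless prediction).
    """
    if predicted.length != reference.length:
        raise ValueError("structures have different lengths")
    if not predicted.pairs:
        raise ValueError("predicted structure has no pairs; PPV undefined")
    n_common = sum(1 for p in predicted.pairs if _matches(p, reference.pairs, slip))
    n_pred = len(predicted.pairs)
    n_ref = len(reference.pairs)
    return PairSimilarity(
        ppv=n_common / n_pred,
        sensitivity=n_common / n_ref if n_ref else 0.0,
        n_pred=n_pred,
        n_ref=n_ref,
        n_common=n_common,
    )
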