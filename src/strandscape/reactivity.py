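"""Mutation rates and SHAPE reactivity profiles from bit vectors.

The mutation rate at a position is ones / (ones + zeroes) over the
informative (non-MASK) codes of all reads covering it.  Raw reactivity
combines the reagent-treated (+) and solvent-control (−) channels::

    R = (MR_plus − MR_minus) / (1 − MR_minus)

which estimates the positive likelihood ratio of chemical modification;
the true-negative rate ``1 − MR_minus`` is the specificity at that
position.  Negative raw values (control rate exceeding treatment rate)
carry no structural evidence and are clamped to zero.  Raw reactivities
are then normalised to a standard 0-to-~1 scale with the 2%/8% rule:
discard the top 2% of defined values and divide by the mean of the next
8% (a boxplot variant is available).

Undefined values (no informative coverage, or MR_minus == 1) are NaN in
memory and −999 in the export dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bitvector import MASK, BitVector, Reference

logger = logging.getLogger(__name__)

__all__ = [
    "ReactivityProfile",
    "mutation_rate",
    "mutation_rates",
    "raw_reactivity",
    "normalize",
    "replicate_correlation",
    "compute_profile",
]

UNDEF_EXPORT = -999.0


def _code_matrix(bitvectors: Sequence[BitVector]) -> np.ndarray:
    if not bitvectors:
        raise ValueError("no bit vectors supplied")
    L = len(bitvectors[0])
    if any(len(bv) != L for bv in bitvectors):
        raise ValueError("bit vectors have unequal lengths")
    return np.stack([bv.codes for bv in bitvectors])


def mutation_rates(bitvectors: Sequence[BitVector]) -> tuple[np.ndarray, np.ndarray]:
    """Per-position mutation rate and informative coverage.

    Returns ``(rates, coverage)``; positions where every code is MASK
    get rate NaN (undefined, not zero).
    """
    codes = _code_matrix(bitvectors)
    ones = (codes == 1).sum(axis=0)
    zeros = (codes == 0).sum(axis=0)
    cov = ones + zeros
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(cov > 0, ones / np.maximum(cov, 1), np.nan)
    return rates, cov


def mutation_rate(bitvectors: Sequence[BitVector], position: int) -> float:
    """Mutation rate at one 1-based position (NaN if uncovered)."""
    rates, _ = mutation_rates(bitvectors)
    if not 1 <= position <= len(rates):
        raise IndexError(f"position {position} outside 1..{len(rates)}")
    return float(rates[position - 1])


def raw_reactivity(mr_plus, mr_minus):
    """Raw reactivity R = (MR+ − MR−)/(1 − MR−), clamped at 0 from below.

    Accepts scalars or arrays; positions with ``mr_minus == 1``
    (specificity zero) are undefined and returned as NaN.
    """
    mr_plus = np.asarray(mr_plus, dtype=float)
    mr_minus = np.asarray(mr_minus, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mr_plus - mr_minus) / (1.0 - mr_minus)
        r = np.where(mr_minus >= 1.0, np.nan, r)
        r = np.where(np.isnan(r), np.nan, np.maximum(r, 0.0))
    if r.ndim == 0:
        return float(r)
    return r


def normalize(
    raw: np.ndarray, method: str = "2-8", min_defined: int = 20
) -> np.ndarray:
    """Scale raw reactivities to span 0 to around 1.

    ``"2-8"`` (default): exclude the top 2% of defined values and divide
    everything by the mean of the next 8%.  ``"boxplot"``: exclude
    values above Q3 + 1.5 IQR and divide by the mean of the top 10% of
    the remainder.  Undefined (NaN) entries pass through unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    defined = raw[np.isfinite(raw)]
    n = defined.size
    if n < min_defined:
        raise ValueError(
            f"only {n} defined reactivities (< {min_defined}); "
            "skip normalization for this profile"
        )
    desc = np.sort(defined)[::-1]
    if method == "2-8":
        n_excl = int(np.floor(0.02 * n))
        n_norm = max(int(np.floor(0.08 * n)), 1)
        divisor = desc[n_excl : n_excl + n_norm].mean()
    elif method == "boxplot":
        q1, q3 = np.percentile(defined, [25, 75])
        kept = desc[desc <= q3 + 1.5 * (q3 - q1)]
        n_norm = max(int(np.floor(0.1 * kept.size)), 1)
        divisor = kept[:n_norm].mean()
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if divisor <= 0:
        raise ValueError("normalization divisor is not positive")
    return raw / divisor


@dataclass
class ReactivityProfile:
    """Per-position rates and reactivities for one reference."""

    reference_id: str
    mr_plus: np.ndarray
    mr_minus: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray
    coverage_plus: np.ndarray
    coverage_minus: np.ndarray
    low_confidence: np.ndarray  # coverage below the floor in either channel
    sequence: str = ""

    @property
    def length(self) -> int:
        return len(self.raw)

    def defined_fraction(self) -> float:
        """Fraction of positions with a defined raw reactivity."""
        return float(np.isfinite(self.raw).mean())

    def to_frame(self) -> pd.DataFrame:
        def exp(v):
            return np.where(np.isfinite(v), v, UNDEF_EXPORT)

        return pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "base": list(self.sequence) if self.sequence else [""] * self.length,
                "mr_plus": exp(self.mr_plus),
                "mr_minus": exp(self.mr_minus),
                "raw": exp(self.raw),
                "normalized": exp(self.normalized),
                "coverage_plus": self.coverage_plus,
                "coverage_minus": self.coverage_minus,
                "low_confidence": self.low_confidence.astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        """SHAPE-map-style TSV; undefined values encoded as −999."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_shape_file(self, path) -> None:
        """Plain two-column reactivity file for standard folding tools."""
        with open(path, "w") as fh:
            for p in range(self.length):
                v = self.normalized[p]
                fh.write(f"{p + 1}\t{v if np.isfinite(v) else UNDEF_EXPORT}\n")


def compute_profile(
    plus: Sequence[BitVector],
    minus: Sequence[BitVector],
    reference: Reference | None = None,
    normalization: str = "2-8",
    min_defined: int = 20,
    coverage_floor: int = 50,
    low_defined_warning: float = 0.05,
) -> ReactivityProfile:
    """Full reactivity profile from (+) and (−) channel bit vectors.

    Positions with informative coverage below ``coverage_floor`` in
    either channel are flagged low-confidence but still reported.  If
    fewer than ``min_defined`` raw values are defined the profile is
    returned unnormalised with a warning (the defined-reactivity
    fraction tells low-modification profiles apart).
    """
    mr_p, cov_p = mutation_rates(plus)
    mr_m, cov_m = mutation_rates(minus)
    if len(mr_p) != len(mr_m):
        raise ValueError("channel bit vectors have different lengths")
    raw = raw_reactivity(mr_p, mr_m)
    try:
        norm = normalize(raw, method=normalization, min_defined=min_defined)
    except ValueError as exc:
        logger.warning("normalization skipped: %s", exc)
        norm = np.full_like(raw, np.nan)
    ref_id = reference.id if reference is not None else (
        plus[0].reference_id if plus else ""
    )
    frac = float(np.mean(np.isfinite(raw) & (raw > 0)))
    if frac < low_defined_warning:
        logger.warning(
            "profile %s has only %.1f%% positions with positive reactivity; "
            "likely unmodified or lowly modified",
            ref_id,
            100 * frac,
        )
    return ReactivityProfile(
        reference_id=ref_id,
        mr_plus=mr_p,
        mr_minus=mr_m,
        raw=raw,
        normalized=norm,
        coverage_plus=cov_p,
        coverage_minus=cov_m,
        low_confidence=(cov_p < coverage_floor) | (cov_m < coverage_floor),
        sequence=reference.sequence if reference is not None else "",
    )


def replicate_correlation(
    profile_a: ReactivityProfile, profile_b: ReactivityProfile
) -> tuple[float, int]:
    """Pearson r between two profiles over jointly defined positions.

    Returns ``(r, n)``; fewer than 3 joint positions is an error.
    Computed on raw reactivities (normalisation is a common scale factor
    and leaves r unchanged).
    """
    a, b = profile_a.raw, profile_b.raw
    if len(a) != len(b):
        raise ValueError("profiles have different lengths")
    joint = np.isfinite(a) & np.isfinite(b)
    n = int(joint.sum())
    if n < 3:
        raise ValueError(f"only {n} jointly defined positions (< 3)")
    r, _ = stats.pearsonr(a[joint], b[joint])
    return float(r), n
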