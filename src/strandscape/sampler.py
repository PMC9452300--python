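"""Stochastic sampling of nested RNA secondary structures.

The sampler draws pseudoknot-free structures from a weighted stochastic
context-free grammar, optionally under hard single-strandedness
constraints derived from one molecule's mutation bit vector (every
mutated position is forced unpaired, because chemical modification
marks flexible, unpaired nucleotides).

Grammar semantics
-----------------
A structure's derivation weight is::

    u ** n_unpaired
    * prod(pair_weight(base_i, base_j) for (i, j) in pairs)
    * helix_init ** n_helices

where a helix is a maximal run of consecutively stacked pairs, i.e. a
pair (i, j) starts a new helix exactly when (i-1, j+1) is not paired.
``pair_weights`` therefore act on the stacked scale and ``helix_init``
(< 1) penalises opening a helix, favouring stacked canonical pairs over
isolated ones, as trained structure grammars do.  Non-canonical pairs
have weight zero and hairpin loops must enclose at least ``min_hairpin``
bases.

The grammar is realised by the unambiguous leftmost decomposition

    W(i,j) = u * W(i+1,j)  +  sum_k V(i,k) * W(k+1,j)
    V(i,j) = w(i,j) * [ helix_init * (W(i+1,j-1) - V(i+1,j-1))
                        + V(i+1,j-1) ]

(``V`` is the weight with (i, j) paired), so every structure has
exactly one derivation and stochastic traceback of the inside tables
draws each structure with probability proportional to its weight.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .structure import SecondaryStructure

__all__ = [
    "Grammar",
    "DEFAULT_GRAMMAR",
    "InsideTables",
    "inside_fill",
    "sample_structures",
    "sample_per_molecule",
    "in_silico_ensemble",
    "constraints_from_codes",
    "molecule_seed",
]

_CANONICAL = ("AU", "UA", "CG", "GC", "GU", "UG")


def _normalise_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class Grammar:
    """Weight table of the structure grammar.

    ``pair_weights`` maps the six canonical pair strings (e.g. ``"GC"``)
    to non-negative stacked-pair weights; anything absent pairs with
    weight zero.  ``unpaired_weight`` is the emission weight of a single
    unpaired base, ``helix_init`` the penalty for opening a helix and
    ``min_hairpin`` the minimum hairpin-loop length (steric minimum,
    default 3).
    """

    unpaired_weight: float = 1.0
    pair_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "GC": 6.0,
            "CG": 6.0,
            "AU": 3.0,
            "UA": 3.0,
            "GU": 1.5,
            "UG": 1.5,
        }
    )
    helix_init: float = 0.02
    min_hairpin: int = 3

    def __post_init__(self) -> None:
        if self.unpaired_weight <= 0:
            raise ValueError("unpaired_weight must be positive")
        if not 0 < self.helix_init <= 1:
            raise ValueError("helix_init must be in (0, 1]")
        if self.min_hairpin < 0:
            raise ValueError("min_hairpin must be >= 0")
        for key, w in self.pair_weights.items():
            if key not in _CANONICAL:
                raise ValueError(f"non-canonical pair {key!r} in weight table")
            if w < 0:
                raise ValueError(f"negative weight for pair {key!r}")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "unpaired_weight": self.unpaired_weight,
            "pair_weights": dict(self.pair_weights),
            "helix_init": self.helix_init,
            "min_hairpin": self.min_hairpin,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Grammar":
        return cls(
            unpaired_weight=float(d.get("unpaired_weight", 1.0)),
            pair_weights={k: float(v) for k, v in d.get("pair_weights", {}).items()},
            helix_init=float(d.get("helix_init", 0.02)),
            min_hairpin=int(d.get("min_hairpin", 3)),
        )

    def pair_weight_matrix(
        self, sequence: str, force_unpaired: np.ndarray | None = None
    ) -> np.ndarray:
        """``(L, L)`` matrix of stacked-pair weights, zero where banned.

        ``force_unpaired`` is a boolean vector (0-based); a constrained
        position contributes weight only through unpaired emission, so
        its whole row and column are zeroed.
        """
        seq = _normalise_sequence(sequence)
        L = len(seq)
        idx = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.zeros((256, 256))
        for key, w in self.pair_weights.items():
            lut[ord(key[0]), ord(key[1])] = w
        P = lut[np.ix_(idx, idx)]
        band = np.add.outer(-np.arange(L), np.arange(L)) - 1  # j - i - 1
        P[band < self.min_hairpin] = 0.0
        if force_unpaired is not None:
            fu = np.asarray(force_unpaired, dtype=bool)
            if fu.shape != (L,):
                raise ValueError("constraint vector length does not match sequence")
            P[fu, :] = 0.0
            P[:, fu] = 0.0
        return P

    def log_weight(self, sequence: str, structure: SecondaryStructure) -> float:
        """Log derivation weight of one structure (useful for checks)."""
        seq = _normalise_sequence(sequence)
        pairs = structure.pairs
        lw = (seq.count("N") * 0.0) + (structure.length - 2 * len(pairs)) * np.log(
            self.unpaired_weight
        )
        for i, j in pairs:
            w = self.pair_weights.get(seq[i - 1] + seq[j - 1], 0.0)
            if w == 0.0:
                return -np.inf
            lw += np.log(w)
            if (i - 1, j + 1) not in pairs:  # helix-initiating pair
                lw += np.log(self.helix_init)
        return float(lw)


DEFAULT_GRAMMAR = Grammar()


def constraints_from_codes(codes: np.ndarray) -> np.ndarray:
    """Derive a force-unpaired vector from one bit vector's codes.

    Code 1 (mutation) forces the position unpaired; codes 0 and MASK
    are unconstrained (absence of modification is not evidence of
    pairing).
    """
    return np.asarray(codes) == 1


@dataclass
class InsideTables:
    """Inside weight tables of one (sequence, grammar, constraints).

    ``W[i, j]`` (0-based, half-open) is the total derivation weight of
    subsequence ``i..j-1``; ``V[i, k]`` the weight of ``i..k`` (closed)
    with ``(i, k)`` paired.  ``W[0, L]`` is the partition-function
    analogue; the open chain is always derivable so it is positive.
    """

    W: np.ndarray
    V: np.ndarray
    P: np.ndarray
    grammar: Grammar

    @property
    def total(self) -> float:
        return float(self.W[0, -1])


def inside_fill(
    sequence: str,
    grammar: Grammar = DEFAULT_GRAMMAR,
    constraints: np.ndarray | None = None,
) -> InsideTables:
    """Fill the inside tables for a sequence under optional constraints."""
    seq = _normalise_sequence(sequence)
    L = len(seq)
    fu = None if constraints is None else np.asarray(constraints, dtype=bool)
    P = grammar.pair_weight_matrix(seq, fu)
    u = grammar.unpaired_weight
    g = grammar.helix_init
    mh = grammar.min_hairpin
    W = np.zeros((L + 1, L + 1))
    V = np.zeros((L, L))
    diag = np.arange(L + 1)
    W[diag, diag] = 1.0
    for d in range(1, L + 1):
        # V for pair distance d: pair (i, i+d)
        if d >= mh + 1 and d < L:
            i = np.arange(0, L - d)
            w_in = W[i + 1, i + d]  # content i+1 .. i+d-1
            v_in = V[i + 1, i + d - 1] if d >= 2 else np.zeros_like(w_in)
            V[i, i + d] = P[i, i + d] * (g * (w_in - v_in) + v_in)
        # W for span d
        i = np.arange(0, L - d + 1)
        vals = u * W[i + 1, i + d]
        for m in range(mh + 1, d):
            vals = vals + V[i, i + m] * W[i + m + 1, i + d]
        W[i, i + d] = vals
    return InsideTables(W=W, V=V, P=P, grammar=grammar)


def _traceback(tables: InsideTables, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Draw one structure (1-based pair list) from the inside tables."""
    W, V = tables.W, tables.V
    g = tables.grammar.helix_init
    u = tables.grammar.unpaired_weight
    mh = tables.grammar.min_hairpin
    L = W.shape[0] - 1
    pairs: list[tuple[int, int]] = []
    # stack holds ("W", i, j, exclude_full) intervals and ("V", i, k) pairs
    stack: list[tuple] = [("W", 0, L, False)]
    while stack:
        kind, i, j, *rest = stack.pop()
        if kind == "V":
            k = j
            pairs.append((i + 1, k + 1))
            w_in = W[i + 1, k]
            v_in = V[i + 1, k - 1] if k - i >= 2 else 0.0
            w_nostack = g * (w_in - v_in)
            total = w_nostack + v_in
            if v_in > 0 and rng.random() * total >= w_nostack:
                stack.append(("V", i + 1, k - 1))
            else:
                stack.append(("W", i + 1, k, True))
            continue
        exclude_full = rest[0]
        if j <= i:
            continue
        w_unpaired = u * W[i + 1, j]
        hi = j - 1 if exclude_full else j
        ks = np.arange(i + mh + 1, hi)
        if ks.size:
            w_pair = V[i, ks] * W[ks + 1, j]
            total = w_unpaired + w_pair.sum()
        else:
            w_pair = None
            total = w_unpaired
        r = rng.random() * total
        if w_pair is None or r < w_unpaired:
            stack.append(("W", i + 1, j, False))
        else:
            cum = np.cumsum(w_pair)
            k = int(ks[np.searchsorted(cum, r - w_unpaired, side="right")])
            stack.append(("V", i, k))
            stack.append(("W", k + 1, j, False))
    return pairs


def sample_structures(
    sequence: str,
    grammar: Grammar = DEFAULT_GRAMMAR,
    constraints: np.ndarray | None = None,
    n_samples: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sequence_ref: str = "",
) -> list[SecondaryStructure]:
    """Sample ``n_samples`` structures by stochastic traceback.

    Each structure is drawn with probability proportional to its
    derivation weight under ``grammar``; positions flagged in
    ``constraints`` are guaranteed unpaired in every sample.  A fixed
    ``seed`` makes the output sequence of structures reproducible.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    seq = _normalise_sequence(sequence)
    if rng is None:
        rng = np.random.default_rng(seed)
    fu = None if constraints is None else np.asarray(constraints, dtype=bool)
    tables = inside_fill(seq, grammar, fu)
    out = []
    for _ in range(n_samples):
        pairs = _traceback(tables, rng)
        s = SecondaryStructure(
            length=len(seq), pairs=frozenset(pairs), sequence_ref=sequence_ref
        )
        if fu is not None:
            part = s.partner()[1:] > 0
            assert not np.any(part & fu), "sampled structure violates constraints"
        out.append(s)
    return out


def molecule_seed(root_seed: int, read_id: str) -> np.random.SeedSequence:
    """Per-molecule seed: root seed combined with CRC32 of the read id.

    The splitting rule depends only on the read identifier, so each
    molecule's samples are independent of the order in which molecules
    are processed.
    """
    return np.random.SeedSequence([int(root_seed), zlib.crc32(read_id.encode())])


def sample_per_molecule(
    bitvectors: Iterable,
    sequence: str,
    grammar: Grammar = DEFAULT_GRAMMAR,
    samples_per_bitvector: int = 1,
    seed: int = 0,
) -> list[tuple[str, SecondaryStructure]]:
    """Fold every molecule under its own single-strandedness constraints.

    For each bit vector the mutated positions (code 1) are forced
    unpaired and ``samples_per_bitvector`` structures are drawn, tagged
    with the molecule's ``read_id``.
    """
    out: list[tuple[str, SecondaryStructure]] = []
    for bv in bitvectors:
        if len(bv.codes) != len(sequence):
            raise ValueError(
                f"bit vector {bv.read_id} length {len(bv.codes)} does not match "
                f"sequence length {len(sequence)}"
            )
        rng = np.random.default_rng(molecule_seed(seed, bv.read_id))
        structures = sample_structures(
            sequence,
            grammar=grammar,
            constraints=constraints_from_codes(bv.codes),
            n_samples=samples_per_bitvector,
            rng=rng,
            sequence_ref=bv.reference_id,
        )
        out.extend((bv.read_id, s) for s in structures)
    return out


def in_silico_ensemble(
    sequence: str,
    grammar: Grammar = DEFAULT_GRAMMAR,
    n_samples: int = 10_000,
    seed: int | None = None,
    sequence_ref: str = "",
) -> list[SecondaryStructure]:
    """Unconstrained Boltzmann-style ensemble (default 10,000 samples).

    This named mode feeds purely in-silico ensembles into the same
    landscape stages as the probing-constrained samples.
    """
    return sample_structures(
        sequence,
        grammar=grammar,
        constraints=None,
        n_samples=n_samples,
        seed=seed,
        sequence_ref=sequence_ref,
    )
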