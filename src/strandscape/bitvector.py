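"""Per-molecule mutation bit vectors from aligned long reads.

Each high-accuracy long read aligned to a reference transcript isoform
is converted into a length-L vector of codes: 0 for a match, 1 for a
mutation (mismatch or unambiguously aligned deletion) and MASK for
uninformative positions (uncovered, soft-clipped, low-quality, read N,
or deletions whose placement is ambiguous).  MASK positions are excluded
from every rate denominator downstream.

A deletion is considered ambiguously placed when it is adjacent to or
inside a homopolymer run of length >= 2 of the deleted base, in which
case the whole run is masked; the aligner could have placed the gap
anywhere within the run.

All reported coordinates are 1-based; internal arrays are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "MASK",
    "Reference",
    "BitVector",
    "MaskPolicy",
    "load_references",
    "extract_bitvectors",
    "assign_isoform",
    "write_bitvectors",
    "read_bitvectors",
]

#: Code for an uninformative position.
MASK: int = -1

_ALPHABET = set("ACGTUN")


@dataclass(frozen=True)
class Reference:
    """One reference transcript isoform."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError("reference sequence must be non-empty")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"invalid bases in reference {self.id}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def dna(self) -> str:
        """Sequence in DNA alphabet (U -> T), as stored in SAM files."""
        return self.sequence.replace("U", "T")


@dataclass
class BitVector:
    """One read's per-reference-position mutation codes."""

    read_id: str
    reference_id: str
    codes: np.ndarray  # int8 over {0, 1, MASK}
    channel: str = "plus"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        bad = set(np.unique(self.codes)) - {0, 1, MASK}
        if bad:
            raise ValueError(f"invalid codes {sorted(bad)} in read {self.read_id}")

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class MaskPolicy:
    """Masking rules applied during extraction.

    ``min_base_quality`` is off by default because HiFi-style consensus
    reads are already high accuracy.  Reads whose aligned reference span
    covers less than ``min_coverage_fraction`` of the reference are
    dropped so every retained bit vector informs full-length structure.
    """

    mask_ambiguous_deletions: bool = True
    min_base_quality: int | None = None
    min_coverage_fraction: float = 0.9


def load_references(fasta_path) -> dict[str, Reference]:
    """Read references from FASTA, one record per transcript isoform."""
    refs = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        refs[rec.id] = Reference(id=rec.id, sequence=str(rec.seq))
    if not refs:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return refs


def _homopolymer_run(seq: str, pos: int) -> tuple[int, int]:
    """0-based closed bounds of the maximal run of ``seq[pos]`` through pos."""
    base = seq[pos]
    lo = pos
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = pos
    while hi < len(seq) - 1 and seq[hi + 1] == base:
        hi += 1
    return lo, hi


def _codes_from_alignment(
    aln: pysam.AlignedSegment,
    ref_dna: str,
    policy: MaskPolicy,
) -> tuple[np.ndarray, int]:
    """Walk the CIGAR once; return (codes, n_insertions)."""
    L = len(ref_dna)
    codes = np.full(L, MASK, dtype=np.int8)
    read = (aln.query_sequence or "").upper()
    quals = aln.query_qualities
    rpos = aln.reference_start  # 0-based
    qpos = 0
    n_ins = 0
    ambiguous: list[tuple[int, int]] = []  # masked last, so M ops cannot overwrite
    for op, ln in aln.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            for t in range(ln):
                rb = ref_dna[rpos + t]
                qb = read[qpos + t]
                if qb == "N":
                    continue  # stays MASK
                if (
                    policy.min_base_quality is not None
                    and quals is not None
                    and quals[qpos + t] < policy.min_base_quality
                ):
                    continue
                codes[rpos + t] = 0 if qb == rb else 1
            rpos += ln
            qpos += ln
        elif op == 1:  # insertion: no reference coordinate
            n_ins += 1
            qpos += ln
        elif op == 2:  # deletion of reference bases
            for t in range(ln):
                p = rpos + t
                if policy.mask_ambiguous_deletions:
                    lo, hi = _homopolymer_run(ref_dna, p)
                    if hi - lo + 1 >= 2:
                        ambiguous.append((lo, hi))
                        continue
                codes[p] = 1
            rpos += ln
        elif op == 3:  # N: skipped region stays MASK
            rpos += ln
        elif op == 4:  # soft clip
            qpos += ln
        # H (5) and P (6) consume nothing relevant
    for lo, hi in ambiguous:
        codes[lo : hi + 1] = MASK
    return codes, n_ins


def extract_bitvectors(
    alignments,
    reference: Reference,
    policy: MaskPolicy | None = None,
    channel: str = "plus",
) -> list[BitVector]:
    """Convert aligned reads into one bit vector per usable read.

    ``alignments`` may be a SAM/BAM path or an open
    :class:`pysam.AlignmentFile`.  Secondary and supplementary records
    are ignored (primary alignment only); reads aligned to a different
    reference are skipped with a warning; an empty alignment set yields
    an empty list.  Extraction is deterministic.
    """
    policy = policy or MaskPolicy()
    close = False
    if isinstance(alignments, (str, Path)):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        close = True
    ref_dna = reference.dna
    L = len(ref_dna)
    out: list[BitVector] = []
    total_ins = 0
    try:
        for aln in alignments:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.reference_name != reference.id:
                logger.warning(
                    "read %s aligned to %s, not %s; skipped",
                    aln.query_name,
                    aln.reference_name,
                    reference.id,
                )
                continue
            span = aln.reference_end - aln.reference_start
            if span < policy.min_coverage_fraction * L:
                logger.debug(
                    "read %s covers %.1f%% of reference; dropped",
                    aln.query_name,
                    100 * span / L,
                )
                continue
            codes, n_ins = _codes_from_alignment(aln, ref_dna, policy)
            total_ins += n_ins
            out.append(
                BitVector(
                    read_id=aln.query_name,
                    reference_id=reference.id,
                    codes=codes,
                    channel=channel,
                )
            )
    finally:
        if close:
            alignments.close()
    logger.info(
        "extracted %d bit vectors for %s (%d insertion events ignored)",
        len(out),
        reference.id,
        total_ins,
    )
    return out


def assign_isoform(scores: Mapping[str, float]) -> str | None:
    """Assign a read to the best-scoring reference isoform.

    Returns the reference id with the maximal alignment score, breaking
    ties lexicographically; ``None`` means unassigned (no valid score).
    """
    valid = {k: v for k, v in scores.items() if v is not None}
    if not valid:
        return None
    best = max(valid.values())
    return min(k for k, v in valid.items() if v == best)


# ----------------------------------------------------------------------
# TSV interface: read_id, reference_id, channel, code string over {0,1,?}
# ----------------------------------------------------------------------
def _code_string(codes: np.ndarray) -> str:
    return "".join("?" if c == MASK else str(int(c)) for c in codes)


def write_bitvectors(path, bitvectors: Iterable[BitVector]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treference_id\tchannel\tcodes\n")
        for bv in bitvectors:
            fh.write(
                f"{bv.read_id}\t{bv.reference_id}\t{bv.channel}\t{_code_string(bv.codes)}\n"
            )


def read_bitvectors(path) -> list[BitVector]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["read_id", "reference_id", "channel", "codes"]:
            raise ValueError(f"unexpected bit-vector table header in {path}")
        for line in fh:
            read_id, ref_id, channel, codes = line.rstrip("\n").split("\t")
            arr = np.array(
                [MASK if c == "?" else int(c) for c in codes], dtype=np.int8
            )
            out.append(
                BitVector(
                    read_id=read_id, reference_id=ref_id, codes=arr, channel=channel
                )
            )
    return out
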