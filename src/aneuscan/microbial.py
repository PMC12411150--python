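"""Ungapped mismatch-tolerant read screening against small microbial genomes.

Low-pass WGS of tissue captures microbial DNA alongside human DNA.  A
sample is screened by counting reads that place somewhere on a microbial
reference (either strand, no gaps) with at most ``max_mismatches``
Hamming mismatches; the sample is labelled positive when strictly more
than ``min_reads_exclusive`` reads match (default: more than four reads,
at most one mismatch each — the Epstein-Barr virus / H. pylori rule).

Two matchers with identical semantics are provided: a vectorized
sliding-window Hamming scan (the reference oracle) and a seed-and-extend
matcher using an exact k-mer index, which is the default for long
references.  'N' never matches anything, in read or reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "MicrobialReference",
    "ScreenParams",
    "ScreenResult",
    "read_matches",
    "read_matches_naive",
    "screen_sample",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
SEED_LENGTH = 20


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MicrobialReference:
    """A microbial reference sequence, e.g. an EBV or H. pylori genome."""

    label: str
    sequence: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError("reference alphabet must be {A,C,G,T,N}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScreenParams:
    max_mismatches: int = 1
    min_reads_exclusive: int = 4  # positive iff count strictly greater

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.min_reads_exclusive < 0:
            raise ValueError("min_reads_exclusive must be >= 0")


@dataclass
class ScreenResult:
    label: str
    matched_read_count: int
    positive: bool
    n_reads_screened: int = 0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "count": self.matched_read_count,
            "positive": self.positive,
            "n_reads_screened": self.n_reads_screened,
        }


def _encode(seq: str, is_read: bool) -> np.ndarray:
    """Bytes with N mapped to a side-specific sentinel so N never matches."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 1 if is_read else 2
    return arr


def read_matches_naive(
    read: str, reference: MicrobialReference, max_mismatches: int = 1
) -> bool:
    """Exhaustive sliding-window Hamming scan over both strands.

    Semantically definitive; quadratic in reference length x read length,
    used as the oracle for the indexed matcher.
    """
    if not read:
        raise ValueError("empty read")
    if len(read) > len(reference):
        raise ValueError("read longer than reference")
    ref_arr = _encode(reference.sequence, is_read=False)
    n, L = ref_arr.size, len(read)
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
    for candidate in (read, reverse_complement(read)):
        read_arr = _encode(candidate, is_read=True)
        mismatches = (windows != read_arr).sum(axis=1)
        if mismatches.min() <= max_mismatches:
            return True
    return False


class _KmerIndex:
    """Exact-seed index over a reference; placements verified by Hamming count.

    By pigeonhole, a placement with at most k mismatches leaves at least
    one of k+1 disjoint read chunks exact, so scanning the seeds at
    offsets 0, L_seed, 2*L_seed, ... finds every valid placement as long
    as the read holds (k+1) disjoint seeds; shorter reads fall back to
    the naive scan.
    """

    def __init__(self, reference: MicrobialReference, seed_length: int = SEED_LENGTH):
        self.reference = reference
        self.seed_length = seed_length
        self.ref_arr = _encode(reference.sequence, is_read=False)
        seq = reference.sequence.upper()
        index: dict[str, list[int]] = {}
        for pos in range(len(seq) - seed_length + 1):
            kmer = seq[pos : pos + seed_length]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append(pos)
        self.index = index

    def matches(self, read: str, max_mismatches: int) -> bool:
        L = len(read)
        if L < self.seed_length * (max_mismatches + 1):
            return read_matches_naive(read, self.reference, max_mismatches)
        n = self.ref_arr.size
        for candidate in (read, reverse_complement(read)):
            cand = candidate.upper()
            cand_arr = _encode(cand, is_read=True)
            seen: set[int] = set()
            for chunk in range(max_mismatches + 1):
                off = chunk * self.seed_length
                for pos in self.index.get(cand[off : off + self.seed_length], ()):
                    start = pos - off
                    if start < 0 or start + L > n or start in seen:
                        continue
                    seen.add(start)
                    mm = int((self.ref_arr[start : start + L] != cand_arr).sum())
                    if mm <= max_mismatches:
                        return True
        return False


def read_matches(
    read: str,
    reference: MicrobialReference,
    max_mismatches: int = 1,
    _index_cache: dict = {},
) -> bool:
    """True iff the read places ungapped on either strand of the reference
    with Hamming distance <= max_mismatches."""
    if not read:
        raise ValueError("empty read")
    if len(read) > len(reference):
        raise ValueError("read longer than reference")
    key = (id(reference), reference.label, len(reference))
    index = _index_cache.get(key)
    if index is None:
        index = _index_cache[key] = _KmerIndex(reference)
    return index.matches(read, max_mismatches)


def screen_sample(
    reads: Iterable[str],
    reference: MicrobialReference,
    params: ScreenParams | None = None,
) -> ScreenResult:
    """Count matching reads and apply the strictly-greater positivity rule."""
    params = params or ScreenParams()
    index = _KmerIndex(reference)
    count = 0
    total = 0
    for read in reads:
        total += 1
        if index.matches(read, params.max_mismatches):
            count += 1
    return ScreenResult(
        label=reference.label,
        matched_read_count=count,
        positive=count > params.min_reads_exclusive,
        n_reads_screened=total,
    )
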