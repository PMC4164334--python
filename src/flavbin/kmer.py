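"""Oligonucleotide (k-mer) frequency profiles and their correlations.

Scaffolds deriving from the same genome share compositional signatures;
normalized tri- through hexanucleotide frequency vectors are therefore the
coordinates in which scaffolds are clustered into phylogenetic bins.

K-mers are counted strand-merged (each word pooled with its reverse
complement) because scaffold orientation after assembly is arbitrary.
Windows containing an ambiguous base (N) are skipped. Each per-k block is
normalized to sum to one and the blocks are concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .util import encode_sequence

DEFAULT_K_SET = (3, 4, 5, 6)


@lru_cache(maxsize=None)
def _canonical_map(k: int) -> tuple[np.ndarray, np.ndarray]:
    """For all 4**k k-mer codes: map to canonical code; list canonical codes.

    A code is ``sum(base[i] * 4**(k-1-i))``; the canonical representative of
    a k-mer is the lexicographic minimum of itself and its reverse
    complement.
    """
    n = 4**k
    codes = np.arange(n)
    digits = np.empty((k, n), dtype=np.int64)
    tmp = codes.copy()
    for i in range(k - 1, -1, -1):
        digits[i] = tmp % 4
        tmp //= 4
    # reverse complement: complement digit (3 - d), reverse digit order
    rc = np.zeros(n, dtype=np.int64)
    for i in range(k):
        rc = rc * 4 + (3 - digits[k - 1 - i])
    canon = np.minimum(codes, rc)
    slots = np.flatnonzero(canon == codes)
    return canon, slots


def canonical_kmer_count(k: int) -> int:
    """Number of distinct canonical k-mers (4**k merged with revcomps)."""
    return len(_canonical_map(k)[1])


def count_kmers(sequence: str, k: int) -> np.ndarray:
    """Canonical k-mer counts for one sequence (vector over canonical codes)."""
    codes = encode_sequence(sequence)
    n = len(codes) - k + 1
    if n <= 0:
        raise ValueError(f"sequence shorter than k={k}")
    window = np.zeros(n, dtype=np.int64)
    for j in range(k):
        window = window * 4 + codes[j : j + n]
    # windows touching an invalid base are dropped
    bad = codes < 0
    if bad.any():
        bad_window = np.convolve(bad.astype(np.int8), np.ones(k, dtype=np.int8))[
            k - 1 : k - 1 + n
        ]
        window = window[bad_window == 0]
    canon, slots = _canonical_map(k)
    counts = np.bincount(canon[window], minlength=4**k)
    return counts[slots]


@dataclass
class KmerProfile:
    """Concatenated normalized canonical k-mer frequencies of one scaffold."""

    scaffold_id: str
    k_set: tuple[int, ...]
    blocks: dict[int, np.ndarray] = field(repr=False)

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.blocks[k] for k in self.k_set])


def compute_profile(
    sequence: str, scaffold_id: str = "", k_set: tuple[int, ...] = DEFAULT_K_SET
) -> KmerProfile:
    """Frequency profile over the given k values (default 3,4,5,6).

    Raises ``ValueError`` when the sequence is shorter than max(k_set) or
    contains no valid window for some k.
    """
    k_set = tuple(sorted(k_set))
    if len(sequence) <= max(k_set):
        raise ValueError(
            f"sequence of length {len(sequence)} too short for k={max(k_set)}"
        )
    blocks: dict[int, np.ndarray] = {}
    for k in k_set:
        counts = count_kmers(sequence, k)
        total = counts.sum()
        blocks[k] = counts / total if total > 0 else counts.astype(float)
    return KmerProfile(scaffold_id=scaffold_id, k_set=k_set, blocks=blocks)


def profile_correlation(p: KmerProfile, q: KmerProfile) -> float:
    """Pearson correlation of two concatenated profile vectors.

    Returns NaN for a zero-variance vector (correlation undefined).
    """
    x, y = p.vector, q.vector
    if x.shape != y.shape:
        raise ValueError("profiles have different k sets")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def profile_matrix(profiles: list[KmerProfile]) -> np.ndarray:
    """Stack profile vectors into an (n_scaffolds, dim) matrix."""
    return np.vstack([p.vector for p in profiles])
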