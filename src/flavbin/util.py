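"""Small shared helpers."""

from __future__ import annotations

import numpy as np

# A,C,G,T -> 0..3; everything else (incl. N) -> -1
_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to int codes (A=0, C=1, G=2, T=3, other=-1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def percent_of(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` in ``total``, rounded to ``ndigits`` decimals.

    The convention used throughout for printed community-composition
    figures, e.g. 75 flavobacterial fragments of 2,213 classified -> 3.4.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def phred_to_string(quals: np.ndarray) -> str:
    """Phred integer qualities -> Sanger (offset 33) ASCII string."""
    return (np.asarray(quals, dtype=np.uint8) + 33).tobytes().decode("latin1")


def string_to_phred(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("latin1"), dtype=np.uint8).astype(np.int32) - 33
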