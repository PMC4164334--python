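"""Pairwise dN/dS estimation by synonymous/nonsynonymous pathway counting.

Implements the classic counting estimator (Nei & Gojobori 1986): synonymous
and nonsynonymous *sites* are counted per codon as the fraction of one-step
nucleotide changes that preserve the encoded amino acid; *differences*
between two codons are counted by averaging over all mutational pathways
between them (pathways through stop codons are excluded when an alternative
exists). Proportions are corrected for multiple hits with the Jukes-Cantor
formula d = -3/4 ln(1 - 4/3 p).

Translations use the bacterial/archaeal/plastid codon table (NCBI table 11).
Codon columns containing a gap or an in-frame stop in either sequence are
removed before counting. dS > 2.0 is flagged as saturated (synonymous sites
too diverged for a reliable estimate); dS below that doubles as a relative
proxy for time since divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data import CodonTable

BACTERIAL_TABLE_ID = 11
_TABLE = CodonTable.unambiguous_dna_by_id[BACTERIAL_TABLE_ID]
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"

DS_SATURATION = 2.0


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon under table 11; '*' for stops."""
    codon = codon.upper()
    if codon in _STOPS:
        return "*"
    return _TABLE.forward_table[codon]


def synonymous_site_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3).

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    """
    codon = codon.upper()
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no site count")
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in _STOPS and translate_codon(mut) == aa:
                s += 1.0 / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) differences between two codons over pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if translate_codon(cur) == translate_codon(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            results.append((syn, nonsyn))
    if not results:
        # every pathway passes through a stop; count through them anyway
        for order in permutations(diff_pos):
            cur = c1
            syn = nonsyn = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                a1 = "*" if cur in _STOPS else translate_codon(cur)
                a2 = "*" if nxt in _STOPS else translate_codon(nxt)
                if a1 == a2:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            results.append((syn, nonsyn))
    syn = sum(r[0] for r in results) / len(results)
    nonsyn = sum(r[1] for r in results) / len(results)
    return syn, nonsyn


def _clean_codon_columns(seq_a: str, seq_b: str) -> tuple[list[str], list[str]]:
    """Drop codon columns with gaps or in-frame stops; check frame."""
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    if len(seq_a) % 3 != 0:
        raise ValueError("aligned length is not a multiple of 3")
    ca, cb = [], []
    for i in range(0, len(seq_a), 3):
        a, b = seq_a[i : i + 3], seq_b[i : i + 3]
        if "-" in a or "-" in b:
            continue
        if set(a + b) - set(_BASES):
            continue
        if a in _STOPS or b in _STOPS:
            continue
        ca.append(a)
        cb.append(b)
    return ca, cb


def jukes_cantor(p: float) -> float:
    """JC69 distance for a raw difference proportion p; inf when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return math.inf
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DnDsResult:
    """Pairwise selection estimate for one variant pair."""

    pair: tuple[str, str]
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    dn: float
    ds: float
    ratio: float | None  # None when dS == 0 (undefined)
    saturated: bool
    correction_defined: bool
    classification: str  # purifying | neutral | positive | undefined

    def __post_init__(self) -> None:
        assert self.saturated == (self.ds > DS_SATURATION)


def compute_dnds(
    seq_a: str, seq_b: str, pair: tuple[str, str] = ("a", "b")
) -> DnDsResult:
    """NG86-style dN/dS for two aligned coding sequences.

    Gapped codon columns and columns with an in-frame stop are removed
    before counting. ``ratio`` is None when dS = 0; ``saturated`` is set
    when dS exceeds 2.0; when pN or pS >= 3/4 the JC correction is
    undefined and ``correction_defined`` is False (distances are inf).
    """
    ca, cb = _clean_codon_columns(seq_a, seq_b)
    if not ca:
        raise ValueError("no comparable codon columns after trimming")
    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    for a, b in zip(ca, cb):
        s_sites += (synonymous_site_fraction(a) + synonymous_site_fraction(b)) / 2.0
        sd, nd = _pathway_counts(a, b)
        s_diff += sd
        n_diff += nd
    n_sites = 3.0 * len(ca) - s_sites

    ps = s_diff / s_sites if s_sites > 0 else 0.0
    pn = n_diff / n_sites if n_sites > 0 else 0.0
    correction_defined = ps < 0.75 and pn < 0.75
    ds = jukes_cantor(ps) if ps < 0.75 else math.inf
    dn = jukes_cantor(pn) if pn < 0.75 else math.inf

    if ds == 0.0 or (math.isinf(ds) and math.isinf(dn)):
        ratio = None
        classification = "undefined"
    else:
        # dn/ds is still meaningful when exactly one of the distances
        # saturates: dn finite with ds = inf -> 0, dn = inf -> positive
        ratio = 0.0 if math.isinf(ds) else dn / ds
        if ratio < 1.0:
            classification = "purifying"
        elif ratio == 1.0:
            classification = "neutral"
        else:
            classification = "positive"

    return DnDsResult(
        pair=pair,
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=s_diff,
        nonsyn_diffs=n_diff,
        dn=dn,
        ds=ds,
        ratio=ratio,
        saturated=ds > DS_SATURATION,
        correction_defined=correction_defined,
        classification=classification,
    )
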