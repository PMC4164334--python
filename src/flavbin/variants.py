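"""Read-level SNP calling and gene-variant (haplotype) reconstruction.

Individual Sanger reads mapped to a scaffold are treated as coming from
individual cells, so SNP patterns across the reads covering a CDS reveal
co-existing gene variants in the population. The workflow over one CDS:

1. quality correction — a base below Q30 that no other read supports at
   its column is replaced with the column consensus;
2. SNP calling — a site is a SNP when read coverage is at least 4 and some
   non-consensus allele is carried by at least 2 reads;
3. CDS selection — only CDSs with mean depth strictly above 7x are
   analyzed (one below the 8x draft-genome convention, to admit more CDSs);
4. track reconstruction — reads are grouped by single-link compatibility:
   two reads join when they overlap at least one SNP site and agree at
   every SNP site they share; each connected group is a variant track;
5. seasonal classification of each track, and pairwise dN/dS of every
   track against a reference track (most reads, ties broken by similarity
   to the consensus).
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dnds import DnDsResult, compute_dnds
from .util import string_to_phred

Q_MIN = 30
SNP_MIN_COV = 4
SNP_MIN_ALT = 2
CDS_MIN_COV = 7.0

_BASE_ORDER = "ACGT-"


@dataclass
class BaseCall:
    read_id: str
    base: str
    quality: int


#: a pileup is position -> list of BaseCall (0-based scaffold coordinates)
Pileup = dict[int, list[BaseCall]]


@dataclass
class SnpCall:
    position: int
    consensus_base: str
    alt_bases: dict[str, int]  # allele -> supporting read count
    coverage: int


@dataclass
class VariantTrack:
    track_id: str
    cds_id: str
    read_ids: list[str]
    alleles: dict[int, str]  # SNP position -> allele carried
    consensus: str
    span: tuple[int, int]  # half-open, scaffold coordinates
    season: str | None = None  # summer_only | winter_only | both

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


def build_pileup(
    reads: pd.DataFrame, scaffold_id: str, start: int, end: int
) -> Pileup:
    """Pileup over [start, end) from an alignment table.

    The table carries read sequences already in scaffold orientation (no
    indels: a read covers exactly its [start, end) span), with per-base
    Phred qualities.
    """
    pileup: Pileup = {}
    sub = reads[reads["scaffold_id"] == scaffold_id]
    sub = sub[(sub["end"] > start) & (sub["start"] < end)]
    for row in sub.itertuples(index=False):
        quals = string_to_phred(row.quality)
        lo, hi = max(start, row.start), min(end, row.end)
        for pos in range(lo, hi):
            off = pos - row.start
            pileup.setdefault(pos, []).append(
                BaseCall(row.read_id, row.sequence[off], int(quals[off]))
            )
    return pileup


def column_consensus(calls: list[BaseCall]) -> str:
    """Majority base; ties broken by summed quality, then alphabetically."""
    counts: dict[str, int] = {}
    quals: dict[str, int] = {}
    for c in calls:
        counts[c.base] = counts.get(c.base, 0) + 1
        quals[c.base] = quals.get(c.base, 0) + c.quality
    return min(counts, key=lambda b: (-counts[b], -quals[b], b))


def correct_low_quality(pileup: Pileup, q_min: int = Q_MIN) -> Pileup:
    """Replace unsupported sub-Q30 calls with the column consensus.

    A call below ``q_min`` whose base appears in no *other* read at the
    column is treated as a sequencing error and set to the consensus;
    calls at or above ``q_min``, and low-quality calls that support each
    other, are left untouched.
    """
    out: Pileup = {}
    for pos, calls in pileup.items():
        cons = column_consensus(calls)
        counts: dict[str, int] = {}
        for c in calls:
            counts[c.base] = counts.get(c.base, 0) + 1
        new_calls = []
        for c in calls:
            if c.quality < q_min and counts[c.base] == 1 and c.base != cons:
                new_calls.append(BaseCall(c.read_id, cons, c.quality))
            else:
                new_calls.append(c)
        out[pos] = new_calls
    return out


def call_snps(
    pileup: Pileup, min_cov: int = SNP_MIN_COV, min_alt: int = SNP_MIN_ALT
) -> list[SnpCall]:
    """Sites with coverage >= min_cov where >= min_alt reads share a mutation."""
    snps: list[SnpCall] = []
    for pos in sorted(pileup):
        calls = pileup[pos]
        if len(calls) < min_cov:
            continue
        cons = column_consensus(calls)
        counts: dict[str, int] = {}
        for c in calls:
            counts[c.base] = counts.get(c.base, 0) + 1
        alts = {b: n for b, n in counts.items() if b != cons and n >= min_alt}
        if alts:
            snps.append(
                SnpCall(
                    position=pos,
                    consensus_base=cons,
                    alt_bases=alts,
                    coverage=len(calls),
                )
            )
    return snps


def mean_depth(pileup: Pileup, start: int, end: int) -> float:
    """Mean read depth over the [start, end) span (zero-covered included)."""
    if end <= start:
        raise ValueError("empty span")
    total = sum(len(pileup.get(p, [])) for p in range(start, end))
    return total / (end - start)


def select_cds(
    cds_table: pd.DataFrame,
    reads: pd.DataFrame,
    min_cov: float = CDS_MIN_COV,
) -> pd.DataFrame:
    """Keep CDSs whose mean read depth over their span is strictly > min_cov."""
    depths = []
    for row in cds_table.itertuples(index=False):
        sub = reads[reads["scaffold_id"] == row.scaffold_id]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        overlap = np.clip(
            np.minimum(ends, row.end) - np.maximum(starts, row.start), 0, None
        )
        depths.append(overlap.sum() / (row.end - row.start))
    out = cds_table.copy()
    out["mean_depth"] = depths
    return out[out["mean_depth"] > min_cov].reset_index(drop=True)


def reconstruct_tracks(
    cds_id: str,
    pileup: Pileup,
    snps: list[SnpCall],
    cds_span: tuple[int, int],
) -> tuple[list[VariantTrack], str]:
    """Group the reads over a CDS into haplotype-consistent variant tracks.

    Returns (tracks, classification) with classification one of
    ``no_snps`` (zero SNPs: a single variant), ``undetermined`` (SNPs
    present but reads cannot be consistently partitioned — e.g. a
    single-link group with an internal conflict), or ``multi_variant``.

    Reads that carry no alternate allele at any SNP site they cover are
    assigned to the consensus (reference) track by parsimony; only
    variant-bearing reads are clustered by single-link agreement. Without
    this rule a mutation-free read covering a single SNP site would link
    the reference group to a variant group through a shared consensus
    base and transitively merge incompatible haplotypes.
    """
    # per-read allele vector over SNP sites, and read spans within the CDS
    read_alleles: dict[str, dict[int, str]] = {}
    read_span: dict[str, tuple[int, int]] = {}
    for pos, calls in pileup.items():
        for c in calls:
            lo, hi = read_span.get(c.read_id, (pos, pos + 1))
            read_span[c.read_id] = (min(lo, pos), max(hi, pos + 1))
    snp_positions = [s.position for s in snps]
    for pos in snp_positions:
        for c in pileup.get(pos, []):
            read_alleles.setdefault(c.read_id, {})[pos] = c.base

    consensus = _consensus_sequence(pileup, cds_span)

    if not snps:
        members = sorted(read_span)
        if not members:
            return [], "no_snps"
        span = (
            min(read_span[r][0] for r in members),
            max(read_span[r][1] for r in members),
        )
        track = VariantTrack(
            track_id=f"{cds_id}.v1",
            cds_id=cds_id,
            read_ids=members,
            alleles={},
            consensus=consensus[span[0] - cds_span[0] : span[1] - cds_span[0]],
            span=span,
        )
        return [track], "no_snps"

    snp_consensus = {s.position: s.consensus_base for s in snps}
    informative = sorted(read_alleles)
    variant_bearing = [
        r
        for r in informative
        if any(b != snp_consensus[p] for p, b in read_alleles[r].items())
    ]
    consensus_reads = [r for r in informative if r not in set(variant_bearing)]

    # single-link among variant-bearing reads: union reads that overlap
    # >=1 SNP site and agree at every shared site
    parent = {r: r for r in variant_bearing}

    def find(r: str) -> str:
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    for i, r1 in enumerate(variant_bearing):
        a1 = read_alleles[r1]
        for r2 in variant_bearing[i + 1 :]:
            a2 = read_alleles[r2]
            shared = a1.keys() & a2.keys()
            if shared and all(a1[p] == a2[p] for p in shared):
                parent[find(r1)] = find(r2)

    groups: dict[str, list[str]] = {}
    for r in variant_bearing:
        groups.setdefault(find(r), []).append(r)
    if consensus_reads:
        groups["__consensus__"] = consensus_reads

    # internal conflict check: single-link closure may chain incompatible reads
    for members in groups.values():
        for i, r1 in enumerate(members):
            a1 = read_alleles[r1]
            for r2 in members[i + 1 :]:
                a2 = read_alleles[r2]
                shared = a1.keys() & a2.keys()
                if any(a1[p] != a2[p] for p in shared):
                    return [], "undetermined"

    tracks: list[VariantTrack] = []
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), ms[0]))
    for idx, members in enumerate(ordered, start=1):
        members = sorted(members)
        alleles: dict[int, str] = {}
        for r in members:
            alleles.update(read_alleles[r])
        span = (
            min(read_span[r][0] for r in members),
            max(read_span[r][1] for r in members),
        )
        seq = list(consensus[span[0] - cds_span[0] : span[1] - cds_span[0]])
        for pos, base in alleles.items():
            if span[0] <= pos < span[1]:
                seq[pos - span[0]] = base
        tracks.append(
            VariantTrack(
                track_id=f"{cds_id}.v{idx}",
                cds_id=cds_id,
                read_ids=members,
                alleles=alleles,
                consensus="".join(seq),
                span=span,
            )
        )
    classification = "multi_variant" if len(tracks) > 1 else "undetermined"
    return tracks, classification


def _consensus_sequence(pileup: Pileup, span: tuple[int, int]) -> str:
    out = []
    for pos in range(span[0], span[1]):
        calls = pileup.get(pos, [])
        out.append(column_consensus(calls) if calls else "N")
    return "".join(out)


def pick_reference(tracks: list[VariantTrack], cds_consensus: str, cds_start: int) -> VariantTrack:
    """Reference track: most supporting reads; ties by similarity to consensus.

    Residual ties break lexicographically on track id so the choice is
    deterministic.
    """
    if not tracks:
        raise ValueError("no tracks")

    def identity(t: VariantTrack) -> float:
        seq = t.consensus
        ref = cds_consensus[t.span[0] - cds_start : t.span[1] - cds_start]
        matches = sum(1 for a, b in zip(seq, ref) if a == b)
        return matches / max(len(seq), 1)

    return min(tracks, key=lambda t: (-t.n_reads, -identity(t), t.track_id))


def classify_season(track: VariantTrack, read_seasons: dict[str, str]) -> str:
    """summer_only / winter_only / both, from the member reads' labels."""
    seasons = set()
    for r in track.read_ids:
        if r not in read_seasons:
            raise ValueError(f"read {r} has no season label")
        seasons.add(read_seasons[r])
    if seasons == {"summer"}:
        return "summer_only"
    if seasons == {"winter"}:
        return "winter_only"
    return "both"


def track_pair_dnds(
    reference: VariantTrack, other: VariantTrack, cds_span: tuple[int, int]
) -> DnDsResult:
    """NG86 dN/dS between a track and the reference over their codon-aligned overlap.

    The overlap of the two spans is trimmed to codon boundaries in the CDS
    reading frame before counting.
    """
    lo = max(reference.span[0], other.span[0])
    hi = min(reference.span[1], other.span[1])
    # snap to the CDS frame
    lo += (3 - (lo - cds_span[0]) % 3) % 3
    hi -= (hi - cds_span[0]) % 3
    if hi - lo < 3:
        raise ValueError("tracks share no complete codon")
    a = reference.consensus[lo - reference.span[0] : hi - reference.span[0]]
    b = other.consensus[lo - other.span[0] : hi - other.span[0]]
    return compute_dnds(a, b, pair=(reference.track_id, other.track_id))


def summarize_variant_table(table: pd.DataFrame) -> pd.Series:
    """Column totals of a per-bin variant census table.

    Expects the seasonal columns ``winter_only``, ``summer_only`` and
    ``both_seasons`` (plus any per-bin metadata columns, which are
    ignored); returns the summed seasonal counts and their grand total.
    """
    totals = table[["winter_only", "summer_only", "both_seasons"]].sum()
    totals["total_variants"] = int(totals.sum())
    return totals.astype(int)
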