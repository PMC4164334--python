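"""Composition-based scaffold clustering into phylogenetic bins.

Scaffolds above a length cutoff are embedded by their oligonucleotide
frequency profiles, placed in a dendrogram by average-linkage agglomeration
on the distance 1 - Pearson r, and flat clusters are extracted wherever the
merge height corresponds to a within-cluster correlation of at least
``r_min`` (default 0.90). Only clusters seeded by a scaffold carrying a
single-copy phylogenetic marker become bin candidates. Candidates then pass
size/read-count filters, and candidates whose duplicated single-copy gene
estimate indicates a mixture are recursively subdivided at their internal
dendrogram root until clean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .kmer import KmerProfile, profile_matrix
from .quality import BinCandidate

logger = logging.getLogger(__name__)

MIN_SCAFFOLD_BP_PASS1 = 3_000
MIN_SCAFFOLD_BP_PASS2 = 5_000
MIN_BIN_BP = 1_900_000
MIN_BIN_READS = 10_000
R_MIN = 0.90
DUP_MAX_PCT = 10.0


@dataclass
class ScaffoldRecord:
    """One assembled scaffold: the unit of binning."""

    id: str
    sequence: str = ""
    length_bp: int = 0
    read_ids: tuple[str, ...] = ()
    has_marker: bool = False

    def __post_init__(self) -> None:
        if self.sequence and self.length_bp == 0:
            self.length_bp = len(self.sequence)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


@dataclass
class Dendrogram:
    """Average-linkage tree over scaffold profiles (scipy linkage matrix)."""

    scaffold_ids: list[str]
    Z: np.ndarray | None  # None for a single-leaf tree
    excluded: list[str] = field(default_factory=list)

    def flat_clusters(self, max_distance: float) -> dict[int, list[str]]:
        """Cut at a merge-height threshold; returns cluster -> scaffold ids."""
        if len(self.scaffold_ids) == 1:
            return {1: list(self.scaffold_ids)}
        labels = fcluster(self.Z, t=max_distance, criterion="distance")
        out: dict[int, list[str]] = {}
        for sid, lab in zip(self.scaffold_ids, labels):
            out.setdefault(int(lab), []).append(sid)
        return out

    def split_in_two(self) -> tuple[list[str], list[str]]:
        """Cut at the root merge into exactly two groups."""
        if len(self.scaffold_ids) < 2:
            raise ValueError("cannot split a single-leaf tree")
        labels = fcluster(self.Z, t=2, criterion="maxclust")
        a = [s for s, l in zip(self.scaffold_ids, labels) if l == labels[0]]
        b = [s for s, l in zip(self.scaffold_ids, labels) if l != labels[0]]
        return a, b


def correlation_distance_matrix(profiles: Sequence[KmerProfile]) -> np.ndarray:
    """Pairwise 1 - Pearson r over profile vectors (square, zero diagonal)."""
    mat = profile_matrix(list(profiles))
    r = np.corrcoef(mat)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def cluster_scaffolds(
    profiles: Sequence[KmerProfile],
    lengths: dict[str, int] | None = None,
    min_scaffold_bp: int = MIN_SCAFFOLD_BP_PASS1,
) -> Dendrogram:
    """Average-linkage dendrogram over scaffolds passing the length filter.

    Scaffolds of length <= ``min_scaffold_bp`` are excluded (strict >, as
    the binning protocol applies it); pass ``lengths=None`` to skip the
    filter.
    """
    kept, excluded = [], []
    for p in profiles:
        if lengths is not None and lengths.get(p.scaffold_id, 0) <= min_scaffold_bp:
            excluded.append(p.scaffold_id)
        else:
            kept.append(p)
    if not kept:
        raise ValueError("no scaffolds pass the length filter")
    ids = [p.scaffold_id for p in kept]
    if len(kept) == 1:
        return Dendrogram(scaffold_ids=ids, Z=None, excluded=excluded)
    d = correlation_distance_matrix(kept)
    Z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(scaffold_ids=ids, Z=Z, excluded=excluded)


def extract_seed_clusters(
    dendrogram: Dendrogram,
    scaffolds: dict[str, ScaffoldRecord],
    r_min: float = R_MIN,
    prefix: str = "bin",
) -> list[BinCandidate]:
    """Flat clusters at distance <= 1 - r_min that contain a marker scaffold.

    Marker-free clusters are dropped: only clusters anchored by a
    single-copy phylogenetic marker can be assigned a taxon.
    """
    clusters = dendrogram.flat_clusters(max_distance=1.0 - r_min)
    out: list[BinCandidate] = []
    for lab in sorted(clusters):
        members = clusters[lab]
        markers = [s for s in members if scaffolds[s].has_marker]
        if not markers:
            continue
        out.append(_make_candidate(f"{prefix}{len(out) + 1:02d}", members, scaffolds, markers))
    if not out:
        logger.warning("no marker-seeded clusters at r_min=%.3f", r_min)
    return out


def _make_candidate(
    bin_id: str,
    members: list[str],
    scaffolds: dict[str, ScaffoldRecord],
    markers: list[str] | None = None,
) -> BinCandidate:
    return BinCandidate(
        bin_id=bin_id,
        scaffold_ids=list(members),
        cumulative_bp=sum(scaffolds[s].length_bp for s in members),
        total_reads=sum(scaffolds[s].n_reads for s in members),
        seed_markers=list(markers or []),
    )


def filter_candidates(
    bins: Sequence[BinCandidate],
    scaffolds: dict[str, ScaffoldRecord],
    stage: str,
    min_bp: int = MIN_BIN_BP,
    min_reads: int = MIN_BIN_READS,
    min_scaffold_bp: int = MIN_SCAFFOLD_BP_PASS2,
) -> list[BinCandidate]:
    """Apply the per-pass bin filters (strict > comparisons, as printed).

    stage "size": keep bins with cumulative length > min_bp (first pass).
    stage "reads": restrict members to scaffolds > min_scaffold_bp, then
    keep bins with > min_reads total reads (second pass).
    """
    out: list[BinCandidate] = []
    if stage == "size":
        for b in bins:
            if b.cumulative_bp > min_bp:
                out.append(b)
    elif stage == "reads":
        for b in bins:
            members = [
                s for s in b.scaffold_ids if scaffolds[s].length_bp > min_scaffold_bp
            ]
            if not members:
                continue
            cand = _make_candidate(b.bin_id, members, scaffolds, b.seed_markers)
            if cand.total_reads > min_reads:
                out.append(cand)
    else:
        raise ValueError(f"unknown filter stage {stage!r}")
    return out


def subdivide_until_clean(
    candidate: BinCandidate,
    profiles: dict[str, KmerProfile],
    scaffolds: dict[str, ScaffoldRecord],
    quality_fn: Callable[[BinCandidate], float],
    dup_max: float = DUP_MAX_PCT,
    max_iter: int = 32,
) -> list[BinCandidate]:
    """Recursively split a bin at its dendrogram root until duplication < dup_max.

    ``quality_fn`` returns the percent-duplication estimate for a candidate.
    Singleton bins cannot be split and are returned as-is; when the
    iteration budget runs out, the current partition is returned with its
    bins flagged unconverged.
    """
    result: list[BinCandidate] = []
    stack = [candidate]
    iters = 0
    while stack:
        b = stack.pop()
        dup = quality_fn(b)
        b.duplication_estimate = dup
        if dup < dup_max or len(b.scaffold_ids) < 2:
            result.append(b)
            continue
        if iters >= max_iter:
            b.unconverged = True
            result.append(b)
            continue
        iters += 1
        sub = cluster_scaffolds(
            [profiles[s] for s in b.scaffold_ids], lengths=None
        )
        left, right = sub.split_in_two()
        stack.append(_make_candidate(b.bin_id + ".1", left, scaffolds))
        stack.append(_make_candidate(b.bin_id + ".2", right, scaffolds))
    result.sort(key=lambda b: b.bin_id)
    return result
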