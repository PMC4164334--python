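"""Bin refinement and quality estimation.

A reference pangenome (gene-family occurrence counts across several related
genomes) yields a *core genome*: every family present in all reference
genomes, with an expected multiplicity equal to the minimum count observed.
Families at exactly one copy in every reference genome are conserved
single-copy genes (CSCGs). A bin's completeness is the fraction of expected
core occurrences recovered; its duplication is the fraction of CSCGs seen
more than once, which signals that the bin mixes closely related organisms.

Refinement applies two screens before quality estimation: a taxonomy vote
(scaffolds whose annotated CDS plurality does not support the target phylum
are removed) and duplicate-scaffold removal (a shorter scaffold whose gene
content is almost entirely shared with a longer one is redundant).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

#: printed-report rounding for percentages
_PCT_DECIMALS = 2


@dataclass
class BinCandidate:
    """A cluster of scaffolds under assessment as a phylogenetic bin."""

    bin_id: str
    scaffold_ids: list[str]
    cumulative_bp: int = 0
    total_reads: int = 0
    seed_markers: list[str] = field(default_factory=list)
    duplication_estimate: float | None = None
    unconverged: bool = False

    def __len__(self) -> int:
        return len(self.scaffold_ids)


@dataclass
class CoreGenome:
    """Expected core gene-family content derived from a pangenome."""

    core_counts: dict[str, int]
    cscg_set: frozenset[str]

    @property
    def expected_total(self) -> int:
        return sum(self.core_counts.values())

    @property
    def n_families(self) -> int:
        return len(self.core_counts)


@dataclass
class BinQualityReport:
    bin_id: str
    identified_core: int
    pct_complete: float
    duplicate_cscgs: int
    pct_duplication: float
    total_bp: int
    approx_genome_bp: int | None


def taxonomy_filter(
    bin_scaffolds: list[str],
    annotations: pd.DataFrame,
    target_phylum: str = "Bacteroidetes",
    min_frac: float = 0.60,
) -> tuple[list[str], list[str], list[str]]:
    """Remove scaffolds whose CDS top-hit vote for the target phylum is < min_frac.

    ``annotations`` needs columns scaffold_id and top_hit_phylum (NaN = no
    hit). The vote is computed over CDS *with* a hit; the comparison is
    strict (<), so exactly 60% is retained. Scaffolds with no annotated CDS
    (or none with hits) are retained and flagged separately — there is no
    evidence on which to remove them.

    Returns (kept, removed, no_evidence).
    """
    ann = annotations[annotations["scaffold_id"].isin(bin_scaffolds)]
    with_hit = ann.dropna(subset=["top_hit_phylum"])
    hits_total = with_hit.groupby("scaffold_id").size()
    hits_target = (
        with_hit[with_hit["top_hit_phylum"] == target_phylum]
        .groupby("scaffold_id")
        .size()
    )
    kept, removed, no_evidence = [], [], []
    for sid in bin_scaffolds:
        total = int(hits_total.get(sid, 0))
        if total == 0:
            kept.append(sid)
            no_evidence.append(sid)
            continue
        frac = int(hits_target.get(sid, 0)) / total
        if frac < min_frac:
            removed.append(sid)
        else:
            kept.append(sid)
    return kept, removed, no_evidence


def dedup_scaffolds(
    bin_scaffolds: list[str],
    scaffold_lengths: dict[str, int],
    scaffold_genes: dict[str, set[str]],
    gene_similarity_pairs: set[frozenset[str]],
    min_shared: float = 0.85,
) -> tuple[list[str], list[str]]:
    """Drop shorter scaffolds whose genes are >= min_shared homologous to a keeper.

    ``gene_similarity_pairs`` is an injected homology relation over CDS ids
    (each element a frozenset of two cds ids). Scaffolds are processed
    longest-first (ties broken by id) so the longer member of a redundant
    pair is always the keeper. Returns (kept, removed).
    """
    homologs: dict[str, set[str]] = {}
    for pair in gene_similarity_pairs:
        a, b = tuple(pair) if len(pair) == 2 else (next(iter(pair)),) * 2
        homologs.setdefault(a, set()).add(b)
        homologs.setdefault(b, set()).add(a)

    order = sorted(bin_scaffolds, key=lambda s: (-scaffold_lengths[s], s))
    kept: list[str] = []
    removed: list[str] = []
    for sid in order:
        genes = scaffold_genes.get(sid, set())
        redundant = False
        for keeper in kept:
            keeper_genes = scaffold_genes.get(keeper, set())
            if not genes:
                break
            shared = sum(
                1 for g in genes if homologs.get(g, set()) & keeper_genes
            )
            if shared / len(genes) >= min_shared:
                redundant = True
                break
        (removed if redundant else kept).append(sid)
    # restore input order for kept scaffolds
    kept_set = set(kept)
    return [s for s in bin_scaffolds if s in kept_set], removed


def build_core_genome(counts: pd.DataFrame) -> CoreGenome:
    """Derive the core genome from a pangenome count table.

    ``counts`` is genomes x families (integer occurrence counts). A family
    enters the core when present (count >= 1) in every genome, with
    expected count = the minimum across genomes; CSCGs are families at
    exactly one copy everywhere.
    """
    if counts.empty:
        raise ValueError("empty pangenome count table")
    if counts.shape[0] < 2:
        raise ValueError("pangenome needs at least 2 genomes")
    if (counts.to_numpy() < 0).any():
        raise ValueError("occurrence counts must be nonnegative")
    mins = counts.min(axis=0)
    core = mins[mins >= 1]
    cscg = counts.columns[(counts == 1).all(axis=0)]
    return CoreGenome(
        core_counts={str(f): int(c) for f, c in core.items()},
        cscg_set=frozenset(str(f) for f in cscg),
    )


def count_core_in_bin(
    bin_family_counts: Counter | dict[str, int], core: CoreGenome, cap: bool = True
) -> tuple[int, int]:
    """Count identified core occurrences and duplicated CSCGs in a bin.

    Identified occurrences of each core family are capped at the expected
    multiplicity (a family cannot contribute more completeness than the
    core expects; the cap is configurable). A CSCG counts as duplicated
    when it appears more than once in the bin.
    """
    identified = 0
    for fam, expected in core.core_counts.items():
        n = int(bin_family_counts.get(fam, 0))
        identified += min(n, expected) if cap else n
    duplicates = sum(
        1 for fam in core.cscg_set if int(bin_family_counts.get(fam, 0)) > 1
    )
    return identified, duplicates


def estimate_completeness(identified_core: int, core: CoreGenome) -> float:
    """Percent completeness = identified / expected core occurrences x 100."""
    if identified_core < 0:
        raise ValueError("identified_core must be nonnegative")
    if core.expected_total == 0:
        raise ValueError("core genome has no expected occurrences")
    return round(100.0 * identified_core / core.expected_total, _PCT_DECIMALS)


def estimate_duplication(duplicate_cscgs: int, core: CoreGenome) -> float:
    """Percent duplication = duplicated CSCGs / total CSCGs x 100."""
    if duplicate_cscgs < 0:
        raise ValueError("duplicate_cscgs must be nonnegative")
    if not core.cscg_set:
        raise ValueError("core genome has no CSCGs")
    return round(100.0 * duplicate_cscgs / len(core.cscg_set), _PCT_DECIMALS)


def extrapolate_genome_size(
    total_bp: int, pct_complete: float, pct_duplication: float
) -> int:
    """Approximate full genome size from bin size, completeness and duplication.

    total / (complete fraction) scaled by the non-duplicated fraction,
    rounded to the nearest integer.
    """
    if pct_complete <= 0 or pct_complete > 100:
        raise ValueError("pct_complete must be in (0, 100]")
    if not 0 <= pct_duplication < 100:
        raise ValueError("pct_duplication must be in [0, 100)")
    return round(total_bp / (pct_complete / 100.0) * (1.0 - pct_duplication / 100.0))


def bin_quality_report(
    bin_id: str,
    bin_family_counts: Counter | dict[str, int],
    core: CoreGenome,
    total_bp: int,
) -> BinQualityReport:
    """Assemble the per-bin quality summary (the per-row report table)."""
    identified, duplicates = count_core_in_bin(bin_family_counts, core)
    pct_c = estimate_completeness(identified, core)
    pct_d = estimate_duplication(duplicates, core)
    approx = extrapolate_genome_size(total_bp, pct_c, pct_d) if pct_c > 0 else None
    return BinQualityReport(
        bin_id=bin_id,
        identified_core=identified,
        pct_complete=pct_c,
        duplicate_cscgs=duplicates,
        pct_duplication=pct_d,
        total_bp=total_bp,
        approx_genome_bp=approx,
    )
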