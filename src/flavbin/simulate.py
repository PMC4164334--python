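"""Synthetic metagenomic communities with known ground truth.

Every downstream stage (binning, quality estimation, variant tracking,
biogeography) is exercised against communities built here, where genome
membership, core-gene placement, gene haplotypes and abundance profiles
are all known exactly.

What is emulated
----------------
* several genomes with distinguishable oligonucleotide composition — each
  genome's sequence is drawn from its own order-2 Markov chain with an
  independently sampled transition matrix, which gives scaffolds of the
  same genome highly correlated k-mer profiles without modelling any real
  organism;
* Sanger-like reads (default mean 1,008 bp) drawn from samples spanning
  two seasons and six sites, with genome-specific expected read fractions
  per sample; substitution errors only (default 1e-3), no indels or
  chimeras; Phred-like qualities with a small fraction below 30;
* planted single-copy core genes shared by all genomes (driving the
  completeness/duplication estimators) plus one marker gene per genome;
* planted CDS haplotypes with exact synonymous/nonsynonymous divergence
  under the bacterial codon table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dnds import translate_codon, _STOPS
from .util import phred_to_string

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

SUMMER, WINTER = "summer", "winter"


# ---------------------------------------------------------------------------
# specs


@dataclass
class VariantPlan:
    """A planted set of haplotypes for one CDS."""

    cds_id: str | None = None  # None: the generator picks a CDS
    num_haplotypes: int = 2
    syn_snps: int = 2
    nonsyn_snps: int = 1
    reads_per_haplotype: int = 6
    season_bias: float | tuple[float, ...] = 0.5  # P(read labelled summer)
    read_length_bp: int = 500

    def bias_for(self, hap_index: int) -> float:
        if isinstance(self.season_bias, (tuple, list)):
            return float(self.season_bias[hap_index])
        return float(self.season_bias)

    def validate(self) -> None:
        if self.num_haplotypes < 1:
            raise ValueError("num_haplotypes must be >= 1")
        if self.syn_snps < 0 or self.nonsyn_snps < 0:
            raise ValueError("SNP counts must be nonnegative")
        if self.reads_per_haplotype < 0:
            raise ValueError("reads_per_haplotype must be nonnegative")


@dataclass
class CommunitySpec:
    """Parameters of a synthetic community; the defaults are the study conditions."""

    num_genomes: int = 4
    genome_length_bp: int = 2_200_000
    markov_order: int = 2
    scaffold_length_range: tuple[int, int] = (5_000, 20_000)
    read_length_mean: int = 1_008
    read_length_sd: int = 150
    #: genome x sample expected read fractions (rows: genomes, cols: samples)
    abundance: np.ndarray | None = None
    #: list of (site_id, season)
    samples: list[tuple[str, str]] = field(default_factory=list)
    reads_per_sample: int = 13_000
    planted_cscg_count: int = 60
    planted_multicopy_core: int = 3  # core families at 2 copies everywhere
    planted_variants: list[VariantPlan] = field(default_factory=list)
    error_rate: float = 1e-3
    q30_fraction: float = 0.97
    cds_length_bp: int = 900
    pangenome_size: int = 7  # reference genomes in the synthetic pangenome
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = default_samples()
        if self.abundance is None:
            self.abundance = default_abundance(self.num_genomes, len(self.samples))
        self.abundance = np.asarray(self.abundance, dtype=float)

    def validate(self) -> None:
        if self.num_genomes < 1:
            raise ValueError("need at least one genome")
        if self.read_length_mean <= 0:
            raise ValueError("read_length_mean must be positive")
        lo, hi = self.scaffold_length_range
        if lo > hi or lo < 1:
            raise ValueError("bad scaffold_length_range")
        if lo > self.genome_length_bp:
            raise ValueError(
                "infeasible spec: minimum scaffold length "
                f"{lo} exceeds genome length {self.genome_length_bp}"
            )
        if self.abundance.shape != (self.num_genomes, len(self.samples)):
            raise ValueError(
                "abundance matrix must be num_genomes x num_samples, got "
                f"{self.abundance.shape}"
            )
        if (self.abundance < 0).any():
            raise ValueError("abundance fractions must be nonnegative")
        sums = self.abundance.sum(axis=0)
        if (sums > 1.0 + 1e-9).any():
            raise ValueError("per-sample genome fractions must sum to <= 1")
        for season in {s for _, s in self.samples}:
            if season not in (SUMMER, WINTER):
                raise ValueError(f"unknown season {season!r}")
        for plan in self.planted_variants:
            plan.validate()


def default_samples() -> list[tuple[str, str]]:
    """Six sites: three sampled in winter, three in summer."""
    return [
        ("GoMA03", WINTER),
        ("GoMA04", WINTER),
        ("GoMA06", WINTER),
        ("GoMA12", SUMMER),
        ("GoMA13", SUMMER),
        ("GoMA14", SUMMER),
    ]


def default_abundance(num_genomes: int, num_samples: int) -> np.ndarray:
    """Seasonally structured expected read fractions.

    For the default 4-genome/6-sample community: one summer bloomer, one
    winter-dominant genome and two intermediates (qualitatively the
    seasonal pattern of the four flavobacterial bins); the per-sample
    remainder is background community. Other shapes get a flat profile.
    """
    if num_genomes == 4 and num_samples == 6:
        winter = np.array([0.04, 0.10, 0.20, 0.35])
        summer = np.array([0.35, 0.20, 0.15, 0.05])
        return np.column_stack([winter] * 3 + [summer] * 3)
    flat = min(0.8 / num_genomes, 0.3)
    return np.full((num_genomes, num_samples), flat)


# ---------------------------------------------------------------------------
# ground truth and the community container


@dataclass
class GroundTruth:
    scaffold_to_genome: dict[str, str]
    read_to_genome: dict[str, str]
    cds_haplotype: dict[str, tuple[str, int]]  # read_id -> (cds_id, hap index)
    core_placements: pd.DataFrame  # genome_id, family_id, cds_id
    variant_haplotypes: dict[str, list[str]]  # cds_id -> haplotype sequences


@dataclass
class Community:
    spec: CommunitySpec
    scaffolds: dict[str, str]  # scaffold_id -> sequence
    reads: pd.DataFrame
    annotations: pd.DataFrame
    pangenome: pd.DataFrame  # wide: genome x family occurrence counts
    truth: GroundTruth

    def scaffold_records(self):
        """Scaffolds as binning units (with read sets and marker flags)."""
        from .binning import ScaffoldRecord

        read_ids: dict[str, list[str]] = {s: [] for s in self.scaffolds}
        for rid, sid in zip(self.reads["read_id"], self.reads["scaffold_id"]):
            read_ids[sid].append(rid)
        markers = set(
            self.annotations.loc[self.annotations["is_marker"], "scaffold_id"]
        )
        return {
            sid: ScaffoldRecord(
                id=sid,
                sequence=seq,
                read_ids=tuple(read_ids[sid]),
                has_marker=sid in markers,
            )
            for sid, seq in self.scaffolds.items()
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA + TSV artifacts; returns the output paths."""
        from . import io as fio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scaffolds": outdir / "scaffolds.fasta",
            "reads": outdir / "reads.tsv",
            "annotations": outdir / "annotations.tsv",
            "pangenome": outdir / "pangenome_counts.tsv",
            "truth": outdir / "ground_truth.tsv",
        }
        fio.write_fasta(self.scaffolds, paths["scaffolds"])
        self.reads.to_csv(paths["reads"], sep="\t", index=False)
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        self.pangenome.to_csv(paths["pangenome"], sep="\t")
        truth = pd.DataFrame(
            {
                "scaffold_id": list(self.truth.scaffold_to_genome),
                "genome_id": list(self.truth.scaffold_to_genome.values()),
            }
        )
        truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


READ_COLUMNS = [
    "read_id",
    "scaffold_id",
    "start",
    "end",
    "strand",
    "sample_id",
    "season",
    "quality",
    "sequence",
]

ANNOTATION_COLUMNS = [
    "cds_id",
    "scaffold_id",
    "start",
    "end",
    "strand",
    "product",
    "top_hit_phylum",
    "family_ids",
    "is_marker",
]


# ---------------------------------------------------------------------------
# sequence generation


def _markov_transitions(order: int, rng: np.random.Generator) -> list[list[float]]:
    """Cumulative transition thresholds, one row per 4**order state."""
    probs = rng.dirichlet(np.ones(4), size=4**order)
    cum = np.cumsum(probs, axis=1)
    return cum[:, :3].tolist()


def _markov_sequence(
    length: int, trans_cum: list[list[float]], order: int, rng: np.random.Generator
) -> str:
    """Sample a base string from an order-``order`` Markov chain."""
    u = rng.random(length).tolist()
    out = bytearray(length)
    n_states = 4**order
    state = int(rng.integers(n_states))
    acgt = b"ACGT"
    for i in range(length):
        row = trans_cum[state]
        x = u[i]
        if x <= row[0]:
            b = 0
        elif x <= row[1]:
            b = 1
        elif x <= row[2]:
            b = 2
        else:
            b = 3
        out[i] = acgt[b]
        state = (state * 4 + b) % n_states
    return out.decode("ascii")


def _tile_scaffolds(
    genome_id: str, sequence: str, length_range: tuple[int, int], rng
) -> dict[str, str]:
    """Chop a genome into non-overlapping scaffolds of random lengths."""
    lo, hi = length_range
    scaffolds: dict[str, str] = {}
    pos, idx = 0, 0
    n = len(sequence)
    while pos < n:
        ln = int(rng.integers(lo, hi + 1))
        chunk = sequence[pos : pos + ln]
        if len(chunk) < lo:
            break  # drop a short terminal fragment
        scaffolds[f"{genome_id}_s{idx:04d}"] = chunk
        pos += ln
        idx += 1
    if not scaffolds:  # genome shorter than one scaffold range: single piece
        scaffolds[f"{genome_id}_s0000"] = sequence
    return scaffolds


def _sample_read(
    scaffold_seq: str, spec: CommunitySpec, rng: np.random.Generator
) -> tuple[int, int, str, str]:
    """One read from a scaffold: (start, end, sequence, quality string)."""
    n = len(scaffold_seq)
    ln = int(round(rng.normal(spec.read_length_mean, spec.read_length_sd)))
    ln = max(100, min(ln, n))
    start = int(rng.integers(0, n - ln + 1))
    seq = np.frombuffer(scaffold_seq[start : start + ln].encode("ascii"), np.uint8).copy()
    # substitution errors
    err = np.flatnonzero(rng.random(ln) < spec.error_rate)
    if len(err) > 0:
        cur = seq[err]
        shift = rng.integers(1, 4, size=len(err))
        idx = np.searchsorted(_BASE_BYTES, cur)
        seq[err] = _BASE_BYTES[(idx + shift) % 4]
    quals = np.where(
        rng.random(ln) < spec.q30_fraction,
        rng.integers(30, 61, size=ln),
        rng.integers(5, 30, size=ln),
    )
    return start, start + ln, seq.tobytes().decode("ascii"), phred_to_string(quals)


# ---------------------------------------------------------------------------
# variant planting


def _single_nt_changes(codon: str) -> list[tuple[int, str, str]]:
    """(position, new base, new codon) for all 9 one-step changes."""
    out = []
    for pos in range(3):
        for b in _BASES:
            if b != codon[pos]:
                out.append((pos, b, codon[:pos] + b + codon[pos + 1 :]))
    return out


def _mutate_cds(
    sequence: str,
    syn: int,
    nonsyn: int,
    rng: np.random.Generator,
    codon_window: tuple[int, int] | None = None,
) -> tuple[str, list[int]]:
    """Apply exactly ``syn`` synonymous + ``nonsyn`` nonsynonymous point changes.

    At most one change per codon, so an independent per-codon translation
    check classifies every change unambiguously. ``codon_window`` limits
    eligible codons to the half-open index range. Raises when the sequence
    does not offer enough codons with a legal (non-stop) change of the
    requested kind.
    """
    codons = [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
    lo, hi = codon_window if codon_window else (0, len(codons))
    eligible = [i for i in range(len(codons)) if lo <= i < hi]
    order = [eligible[i] for i in rng.permutation(len(eligible))]
    changed: dict[int, str] = {}
    positions: list[int] = []

    def place(count: int, want_syn: bool) -> None:
        need = count
        for ci in order:
            if need == 0:
                return
            if ci in changed:
                continue
            codon = codons[ci]
            aa = translate_codon(codon)
            options = [
                (pos, new)
                for pos, b, new in _single_nt_changes(codon)
                if new not in _STOPS
                and (translate_codon(new) == aa) == want_syn
            ]
            if not options:
                continue
            pos, new = options[int(rng.integers(len(options)))]
            changed[ci] = new
            positions.append(ci * 3 + pos)
            need -= 1
        if need:
            kind = "synonymous" if want_syn else "nonsynonymous"
            raise ValueError(
                f"cannot place {count} {kind} SNPs without creating a stop "
                "or reusing a codon"
            )

    place(syn, True)
    place(nonsyn, False)
    mutated = [changed.get(i, c) for i, c in enumerate(codons)]
    return "".join(mutated), sorted(positions)


def plant_variants(
    cds_sequence: str, plan: VariantPlan, rng: np.random.Generator
) -> tuple[list[str], pd.DataFrame]:
    """Build haplotypes of a CDS and the labelled reads that sample them.

    Haplotype 1 is the input sequence; each further haplotype differs from
    it by exactly ``plan.syn_snps`` synonymous and ``plan.nonsyn_snps``
    nonsynonymous point changes (bacterial codon table), confined to the
    stretch of the CDS that every tiled read covers, so each read spans
    all of its haplotype's SNP sites. Reads are clean (no errors, quality
    >= Q30) and labelled summer with the per-haplotype season bias
    (realized as exact counts). Coordinates in the returned table are
    CDS-relative. Raises when the reads are too short relative to the CDS
    to share a window that can host the requested changes.
    """
    plan.validate()
    if len(cds_sequence) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    codons = [cds_sequence[i : i + 3] for i in range(0, len(cds_sequence), 3)]
    if any(c in _STOPS for c in codons[:-1]):
        raise ValueError("CDS contains an internal stop codon")

    n = len(cds_sequence)
    rl = min(plan.read_length_bp, n)
    # codons fully inside [n - rl, rl), the span common to all tiled reads
    window = (-(-(n - rl) // 3), rl // 3)
    if window[1] - window[0] < plan.syn_snps + plan.nonsyn_snps:
        raise ValueError(
            "reads too short for this CDS: the window covered by every "
            "read cannot host the requested SNPs"
        )

    haplotypes = [cds_sequence]
    for _ in range(plan.num_haplotypes - 1):
        hap, _pos = _mutate_cds(
            cds_sequence, plan.syn_snps, plan.nonsyn_snps, rng, codon_window=window
        )
        haplotypes.append(hap)

    rows = []
    for h, hap in enumerate(haplotypes):
        m = plan.reads_per_haplotype
        n_summer = int(round(plan.bias_for(h) * m))
        starts = (
            [int(round(i * (n - rl) / (m - 1))) for i in range(m)]
            if m > 1
            else [0] * m
        )
        for i, start in enumerate(starts):
            seq = hap[start : start + rl]
            quals = rng.integers(35, 61, size=len(seq))
            rows.append(
                {
                    "read_id": f"hap{h + 1}_r{i:03d}",
                    "haplotype": h + 1,
                    "start": start,
                    "end": start + len(seq),
                    "season": SUMMER if i < n_summer else WINTER,
                    "sequence": seq,
                    "quality": phred_to_string(quals),
                }
            )
    reads = pd.DataFrame(
        rows,
        columns=["read_id", "haplotype", "start", "end", "season", "sequence", "quality"],
    )
    return haplotypes, reads


# ---------------------------------------------------------------------------
# codon-process simulator (for validating the dN/dS estimator)


def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """Random stop-free coding sequence of ``n_codons`` codons."""
    codons = []
    while len(codons) < n_codons:
        c = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def evolve_coding_pair(
    n_codons: int,
    omega: float,
    n_events: int,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Evolve a copy of a random CDS under a simple codon process.

    ``n_events`` uniform single-nucleotide mutation proposals are applied
    to one copy: synonymous changes always fix, nonsynonymous changes fix
    with probability ``omega``, changes creating a stop never fix. The
    returned pair (ancestor, descendant) therefore diverges with a true
    nonsynonymous/synonymous rate ratio of ``omega``.
    """
    anc = random_coding_sequence(n_codons, rng)
    cur = list(anc)
    n = len(cur)
    for _ in range(n_events):
        pos = int(rng.integers(n))
        ci = pos // 3
        codon = "".join(cur[ci * 3 : ci * 3 + 3])
        b = _BASES[int(rng.integers(4))]
        if b == cur[pos]:
            continue
        new = codon[: pos % 3] + b + codon[pos % 3 + 1 :]
        if new in _STOPS:
            continue
        if translate_codon(new) != translate_codon(codon) and rng.random() >= omega:
            continue
        cur[pos] = b
    return anc, "".join(cur)


def events_for_target_ds(n_codons: int, target_ds: float) -> int:
    """Proposal count giving roughly the requested synonymous divergence.

    Uses the average synonymous-site fraction of the uniform codon
    distribution (~1/4) and inverts the Jukes-Cantor correction.
    """
    p = 0.75 * (1.0 - np.exp(-4.0 * target_ds / 3.0))
    # a fraction of proposals is rejected (self, stop); ~ (3/4 of 9) usable
    return int(round(p * 3 * n_codons * (4.0 / 3.0)))


# ---------------------------------------------------------------------------
# community generation


def generate_community(spec: CommunitySpec) -> Community:
    """Build a full synthetic community from a spec (deterministic per seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)

    genome_ids = [f"G{i + 1}" for i in range(spec.num_genomes)]
    background_needed = bool((spec.abundance.sum(axis=0) < 1.0 - 1e-9).any())
    all_genomes = genome_ids + (["background"] if background_needed else [])

    # genomes and scaffolds
    scaffolds: dict[str, str] = {}
    scaffold_to_genome: dict[str, str] = {}
    genome_scaffolds: dict[str, list[str]] = {}
    for gid in all_genomes:
        trans = _markov_transitions(spec.markov_order, rng)
        seq = _markov_sequence(spec.genome_length_bp, trans, spec.markov_order, rng)
        tiles = _tile_scaffolds(gid, seq, spec.scaffold_length_range, rng)
        scaffolds.update(tiles)
        genome_scaffolds[gid] = list(tiles)
        for sid in tiles:
            scaffold_to_genome[sid] = gid

    # annotations: tile CDSs along every scaffold
    annotations = _annotate(spec, scaffolds, scaffold_to_genome, rng)

    # plant core families + markers on target-genome CDSs
    annotations, core_placements, families = _plant_core_genes(
        spec, annotations, scaffold_to_genome, genome_ids, rng
    )

    pangenome = _synthetic_pangenome(spec, families)

    # resolve planted-variant CDSs and make their regions stop-free BEFORE
    # sampling reads, so regular reads agree with haplotype 1
    variant_sites = _resolve_variant_cds(spec, annotations, scaffolds, scaffold_to_genome)

    # reads
    read_rows: list[dict] = []
    read_to_genome: dict[str, str] = {}
    lengths = np.array([len(scaffolds[s]) for s in scaffolds], dtype=float)
    scaffold_ids = list(scaffolds)
    by_genome_idx = {
        gid: np.array([i for i, s in enumerate(scaffold_ids) if scaffold_to_genome[s] == gid])
        for gid in all_genomes
    }
    counter = 0
    for j, (site, season) in enumerate(spec.samples):
        fracs = spec.abundance[:, j]
        probs = list(fracs) + (
            [1.0 - fracs.sum()] if background_needed else []
        )
        probs = np.clip(np.asarray(probs, dtype=float), 0, None)
        probs = probs / probs.sum() if probs.sum() > 0 else probs
        counts = (
            rng.multinomial(spec.reads_per_sample, probs)
            if spec.reads_per_sample > 0
            else np.zeros(len(probs), dtype=int)
        )
        for gid, n_reads in zip(all_genomes, counts):
            idx = by_genome_idx[gid]
            if len(idx) == 0 or n_reads == 0:
                continue
            w = lengths[idx] / lengths[idx].sum()
            chosen = rng.choice(idx, size=n_reads, p=w)
            for si in chosen:
                sid = scaffold_ids[si]
                start, end, seq, qual = _sample_read(scaffolds[sid], spec, rng)
                rid = f"r{counter:07d}"
                counter += 1
                read_rows.append(
                    {
                        "read_id": rid,
                        "scaffold_id": sid,
                        "start": start,
                        "end": end,
                        "strand": "+" if rng.random() < 0.5 else "-",
                        "sample_id": site,
                        "season": season,
                        "quality": qual,
                        "sequence": seq,
                    }
                )
                read_to_genome[rid] = gid
    reads = pd.DataFrame(read_rows, columns=READ_COLUMNS)

    # planted haplotype reads
    cds_haplotype: dict[str, tuple[str, int]] = {}
    variant_haplotypes: dict[str, list[str]] = {}
    if spec.planted_variants:
        reads, cds_haplotype, variant_haplotypes = _plant_variant_reads(
            spec, variant_sites, scaffolds, scaffold_to_genome, reads, read_to_genome, rng
        )

    truth = GroundTruth(
        scaffold_to_genome=scaffold_to_genome,
        read_to_genome=read_to_genome,
        cds_haplotype=cds_haplotype,
        core_placements=core_placements,
        variant_haplotypes=variant_haplotypes,
    )
    return Community(
        spec=spec,
        scaffolds=scaffolds,
        reads=reads,
        annotations=annotations,
        pangenome=pangenome,
        truth=truth,
    )


def _annotate(spec, scaffolds, scaffold_to_genome, rng) -> pd.DataFrame:
    rows = []
    cds_len = spec.cds_length_bp
    gap = 100
    for sid, seq in scaffolds.items():
        target = scaffold_to_genome[sid] != "background"
        pos = gap // 2
        idx = 0
        while pos + cds_len <= len(seq):
            u = rng.random()
            if target:
                phylum = (
                    "Bacteroidetes" if u < 0.85
                    else ("Proteobacteria" if u < 0.90 else None)
                )
            else:
                phylum = (
                    "Proteobacteria" if u < 0.80
                    else ("Bacteroidetes" if u < 0.90 else None)
                )
            rows.append(
                {
                    "cds_id": f"{sid}_c{idx:03d}",
                    "scaffold_id": sid,
                    "start": pos,
                    "end": pos + cds_len,
                    "strand": "+",
                    "product": "hypothetical protein",
                    "top_hit_phylum": phylum,
                    "family_ids": "",
                    "is_marker": False,
                }
            )
            pos += cds_len + gap
            idx += 1
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def _plant_core_genes(spec, annotations, scaffold_to_genome, genome_ids, rng):
    """Assign core families (and one marker) to CDSs of each target genome."""
    single = [f"FAM{i + 1:04d}" for i in range(spec.planted_cscg_count)]
    multi = [f"MFAM{i + 1:02d}" for i in range(spec.planted_multicopy_core)]
    families = {f: 1 for f in single}
    families.update({f: 2 for f in multi})
    families["MARKER_DNAG"] = 1

    ann = annotations.copy()
    genome_of = ann["scaffold_id"].map(scaffold_to_genome)
    placements = []
    fam_col = ann["family_ids"].to_list()
    marker_col = ann["is_marker"].to_list()
    for gid in genome_ids:
        cds_idx = list(ann.index[genome_of == gid])
        slots = [f for f in single] + [f for f in multi for _ in range(2)] + ["MARKER_DNAG"]
        if len(slots) > len(cds_idx):
            raise ValueError(
                f"genome {gid}: {len(cds_idx)} CDSs cannot host "
                f"{len(slots)} planted core-gene occurrences"
            )
        chosen = rng.choice(len(cds_idx), size=len(slots), replace=False)
        for fam, k in zip(slots, chosen):
            i = cds_idx[int(k)]
            fam_col[i] = fam
            if fam == "MARKER_DNAG":
                marker_col[i] = True
            placements.append(
                {"genome_id": gid, "family_id": fam, "cds_id": ann.at[i, "cds_id"]}
            )
    ann["family_ids"] = fam_col
    ann["is_marker"] = marker_col
    return ann, pd.DataFrame(placements), families


def _synthetic_pangenome(spec, families: dict[str, int]) -> pd.DataFrame:
    """Reference pangenome counts: every planted family in every reference."""
    refs = [f"ref{i + 1}" for i in range(spec.pangenome_size)]
    data = {fam: [count] * len(refs) for fam, count in families.items()}
    return pd.DataFrame(data, index=refs)


def _strip_stops(seq: str) -> str:
    """Rewrite internal stop codons (third base -> C) so the frame is coding."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    return "".join(c[:2] + "C" if c in _STOPS else c for c in codons)


def _resolve_variant_cds(spec, annotations, scaffolds, scaffold_to_genome):
    """Pick the CDS hosting each VariantPlan; sanitize its scaffold region.

    Returns [(plan, cds_row)] with the scaffold sequences updated so every
    chosen CDS is a stop-free open reading frame.
    """
    if not spec.planted_variants:
        return []
    target_ann = annotations[
        annotations["scaffold_id"].map(scaffold_to_genome) != "background"
    ]
    auto_iter = iter(target_ann.itertuples(index=False))
    out = []
    used = set()
    for plan in spec.planted_variants:
        if plan.cds_id is None:
            row = next(auto_iter)
            while row.cds_id in used:
                row = next(auto_iter)
        else:
            match = target_ann[target_ann["cds_id"] == plan.cds_id]
            if match.empty:
                raise ValueError(f"unknown cds_id {plan.cds_id!r}")
            row = next(match.itertuples(index=False))
        used.add(row.cds_id)
        seq = scaffolds[row.scaffold_id]
        clean = _strip_stops(seq[row.start : row.end])
        scaffolds[row.scaffold_id] = seq[: row.start] + clean + seq[row.end :]
        out.append((plan, row))
    return out


def _plant_variant_reads(
    spec, variant_sites, scaffolds, scaffold_to_genome, reads, read_to_genome, rng
):
    """Emit haplotype reads for each VariantPlan, in scaffold coordinates."""
    summer_sites = [s for s, season in spec.samples if season == SUMMER]
    winter_sites = [s for s, season in spec.samples if season == WINTER]
    if not summer_sites or not winter_sites:
        raise ValueError("variant planting needs both seasons among samples")

    cds_haplotype: dict[str, tuple[str, int]] = {}
    variant_haplotypes: dict[str, list[str]] = {}
    extra = []
    for p_idx, (plan, row) in enumerate(variant_sites):
        cds_seq = scaffolds[row.scaffold_id][row.start : row.end]
        haps, hap_reads = plant_variants(cds_seq, plan, rng)
        variant_haplotypes[row.cds_id] = haps
        for r in hap_reads.itertuples(index=False):
            rid = f"pv{p_idx}_{r.read_id}"
            site_pool = summer_sites if r.season == SUMMER else winter_sites
            extra.append(
                {
                    "read_id": rid,
                    "scaffold_id": row.scaffold_id,
                    "start": row.start + r.start,
                    "end": row.start + r.end,
                    "strand": "+",
                    "sample_id": site_pool[int(rng.integers(len(site_pool)))],
                    "season": r.season,
                    "quality": r.quality,
                    "sequence": r.sequence,
                }
            )
            cds_haplotype[rid] = (row.cds_id, r.haplotype)
            read_to_genome[rid] = scaffold_to_genome[row.scaffold_id]
    reads = pd.concat(
        [reads, pd.DataFrame(extra, columns=READ_COLUMNS)], ignore_index=True
    )
    return reads, cds_haplotype, variant_haplotypes


def default_community_spec(seed: int = 42, **overrides) -> CommunitySpec:
    """The default study-condition community (4 genomes, ~2 Mbp, 6 samples)."""
    return CommunitySpec(rng_seed=seed, **overrides)
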