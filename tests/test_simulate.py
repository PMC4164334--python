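"""Ground-truth fidelity of the synthetic community generator."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flavbin.dnds import translate_codon
from flavbin.kmer import compute_profile, profile_correlation
from flavbin.simulate import (
    CommunitySpec,
    VariantPlan,
    generate_community,
    plant_variants,
    random_coding_sequence,
)
from flavbin.util import string_to_phred


def _tiny_spec(**overrides):
    defaults = dict(
        num_genomes=2,
        genome_length_bp=100_000,
        scaffold_length_range=(5_000, 10_000),
        reads_per_sample=200,
        planted_cscg_count=10,
        rng_seed=3,
    )
    defaults.update(overrides)
    return CommunitySpec(**defaults)


class TestCommunityGeneration:
    def test_deterministic_under_fixed_seed(self):
        a = generate_community(_tiny_spec())
        b = generate_community(_tiny_spec())
        assert a.scaffolds == b.scaffolds
        pd.testing.assert_frame_equal(a.reads, b.reads)
        pd.testing.assert_frame_equal(a.annotations, b.annotations)

    def test_different_seeds_differ(self):
        a = generate_community(_tiny_spec(rng_seed=3))
        b = generate_community(_tiny_spec(rng_seed=4))
        assert a.scaffolds != b.scaffolds

    def test_exact_read_counts_per_sample(self):
        com = generate_community(_tiny_spec())
        counts = com.reads.groupby("sample_id").size()
        assert set(counts.index) == {s for s, _ in com.spec.samples}
        assert (counts == com.spec.reads_per_sample).all()

    def test_reads_lie_within_their_scaffold(self):
        com = generate_community(_tiny_spec())
        lengths = com.reads["scaffold_id"].map(
            {sid: len(seq) for sid, seq in com.scaffolds.items()}
        )
        assert (com.reads["start"] >= 0).all()
        assert (com.reads["end"] <= lengths).all()
        assert (com.reads["sequence"].str.len() == com.reads["end"] - com.reads["start"]).all()

    def test_read_labels_match_scaffold_of_origin(self):
        com = generate_community(_tiny_spec())
        truth = com.truth
        for row in com.reads.itertuples(index=False):
            assert truth.read_to_genome[row.read_id] == truth.scaffold_to_genome[row.scaffold_id]

    def test_substitution_error_rate_near_nominal(self):
        com = generate_community(_tiny_spec(reads_per_sample=500))
        mismatches = bases = 0
        for row in com.reads.itertuples(index=False):
            ref = com.scaffolds[row.scaffold_id][row.start : row.end]
            mismatches += sum(1 for a, b in zip(ref, row.sequence) if a != b)
            bases += len(ref)
        rate = mismatches / bases
        assert 0.3e-3 < rate < 3e-3  # nominal 1e-3 with sampling slack

    def test_q30_fraction_near_nominal(self):
        com = generate_community(_tiny_spec())
        quals = np.concatenate([string_to_phred(q) for q in com.reads["quality"]])
        frac = float((quals >= 30).mean())
        assert abs(frac - com.spec.q30_fraction) < 0.02

    def test_scaffolds_cover_each_genome_minus_dropped_tail(self):
        # tiling may drop one terminal fragment shorter than the minimum
        # scaffold length, so coverage is genome length minus < min length
        com = generate_community(_tiny_spec())
        by_genome: dict[str, int] = {}
        for sid, seq in com.scaffolds.items():
            gid = com.truth.scaffold_to_genome[sid]
            by_genome[gid] = by_genome.get(gid, 0) + len(seq)
        min_len = com.spec.scaffold_length_range[0]
        for gid, total in by_genome.items():
            if gid != "background":
                assert com.spec.genome_length_bp - min_len < total
                assert total <= com.spec.genome_length_bp

    def test_within_genome_profiles_more_similar_than_between(self, small_community):
        com = small_community
        truth = com.truth.scaffold_to_genome
        profiles, genome = [], []
        for sid, seq in com.scaffolds.items():
            if truth[sid] == "background" or len(seq) <= 5_000:
                continue
            profiles.append(compute_profile(seq, sid))
            genome.append(truth[sid])
        within, between = [], []
        for i in range(len(profiles)):
            for j in range(i + 1, len(profiles)):
                r = profile_correlation(profiles[i], profiles[j])
                (within if genome[i] == genome[j] else between).append(r)
        assert min(within) > max(between)

    def test_marker_planted_once_per_genome(self, small_community):
        ann = small_community.annotations
        markers = ann[ann["is_marker"]]
        genomes = markers["scaffold_id"].map(small_community.truth.scaffold_to_genome)
        assert sorted(genomes) == ["G1", "G2"]

    def test_infeasible_specs_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            _tiny_spec(scaffold_length_range=(200_000, 300_000)).validate()
        with pytest.raises(ValueError, match="sum"):
            _tiny_spec(abundance=np.full((2, 6), 0.6)).validate()
        with pytest.raises(ValueError, match="num_genomes x num_samples"):
            _tiny_spec(abundance=np.full((3, 6), 0.1)).validate()


class TestPlantVariants:
    def _diff_census(self, a: str, b: str):
        """Independent per-codon translate-and-compare of two CDSs."""
        syn = nonsyn = sites = 0
        for i in range(0, len(a), 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            ndiff = sum(x != y for x, y in zip(ca, cb))
            sites += ndiff
            if ndiff == 0:
                continue
            assert ndiff == 1  # one change per codon
            if translate_codon(ca) == translate_codon(cb):
                syn += 1
            else:
                nonsyn += 1
        return syn, nonsyn, sites

    def test_exact_syn_nonsyn_counts(self, rng):
        cds = random_coding_sequence(405, rng)  # 1,215 bp
        plan = VariantPlan(
            num_haplotypes=2, syn_snps=47, nonsyn_snps=13, read_length_bp=1_215
        )
        haps, reads = plant_variants(cds, plan, rng)
        assert haps[0] == cds
        syn, nonsyn, sites = self._diff_census(haps[0], haps[1])
        assert (syn, nonsyn, sites) == (47, 13, 60)

    def test_every_read_spans_every_snp_site(self, rng):
        cds = random_coding_sequence(300, rng)
        plan = VariantPlan(num_haplotypes=3, syn_snps=2, nonsyn_snps=1,
                           reads_per_haplotype=5, read_length_bp=500)
        haps, reads = plant_variants(cds, plan, rng)
        snp_sites = [
            i for i in range(len(cds))
            if any(h[i] != cds[i] for h in haps[1:])
        ]
        for row in reads.itertuples(index=False):
            assert all(row.start <= p < row.end for p in snp_sites)

    def test_season_bias_realized_exactly(self, rng):
        cds = random_coding_sequence(300, rng)
        plan = VariantPlan(
            num_haplotypes=3,
            syn_snps=1,
            nonsyn_snps=0,
            reads_per_haplotype=6,
            season_bias=(0.5, 1.0, 0.0),
            read_length_bp=900,
        )
        _, reads = plant_variants(cds, plan, rng)
        per_hap = reads.groupby("haplotype")["season"].apply(
            lambda s: (s == "summer").sum()
        )
        assert per_hap[1] == 3 and per_hap[2] == 6 and per_hap[3] == 0

    def test_impossible_placement_errors(self, rng):
        # ATG (Met) admits no synonymous one-step change
        with pytest.raises(ValueError, match="cannot place"):
            plant_variants(
                "ATG" * 50,
                VariantPlan(num_haplotypes=2, syn_snps=1, nonsyn_snps=0,
                            read_length_bp=150),
                rng,
            )

    def test_reads_too_short_for_common_window_errors(self, rng):
        cds = random_coding_sequence(300, rng)  # 900 bp; 300-bp reads share no window
        with pytest.raises(ValueError, match="too short"):
            plant_variants(
                cds,
                VariantPlan(num_haplotypes=2, reads_per_haplotype=4, read_length_bp=300),
                rng,
            )

    def test_internal_stop_rejected(self, rng):
        with pytest.raises(ValueError, match="stop"):
            plant_variants("ATGTAAATGGGG", VariantPlan(read_length_bp=12), rng)


def test_small_spec_haplotype_reads_carry_their_haplotype(small_community):
    com = small_community
    (cds_id,) = com.truth.variant_haplotypes
    haps = com.truth.variant_haplotypes[cds_id]
    row = com.annotations[com.annotations["cds_id"] == cds_id].iloc[0]
    reads = com.reads.set_index("read_id")
    for rid, (cid, hap) in com.truth.cds_haplotype.items():
        r = reads.loc[rid]
        lo, hi = r["start"] - row["start"], r["end"] - row["start"]
        assert r["sequence"] == haps[hap - 1][lo:hi]
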