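"""SNP calling, quality correction, track reconstruction and the census summary."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

from flavbin.variants import (
    BaseCall,
    VariantTrack,
    build_pileup,
    call_snps,
    classify_season,
    column_consensus,
    correct_low_quality,
    mean_depth,
    pick_reference,
    reconstruct_tracks,
    select_cds,
    summarize_variant_table,
    track_pair_dnds,
)

DATA = Path(__file__).parent / "data"


def _pileup(columns):
    """columns: {pos: [(read_id, base, quality), ...]}."""
    return {
        pos: [BaseCall(r, b, q) for r, b, q in calls]
        for pos, calls in columns.items()
    }


class TestConsensusAndCorrection:
    def test_majority_wins(self):
        calls = [BaseCall("r1", "A", 40), BaseCall("r2", "A", 40), BaseCall("r3", "G", 60)]
        assert column_consensus(calls) == "A"

    def test_tie_broken_by_summed_quality_then_alphabet(self):
        calls = [BaseCall("r1", "G", 50), BaseCall("r2", "A", 40)]
        assert column_consensus(calls) == "G"
        calls = [BaseCall("r1", "G", 40), BaseCall("r2", "A", 40)]
        assert column_consensus(calls) == "A"

    def test_unsupported_subq30_call_replaced(self):
        p = _pileup({5: [("r1", "A", 40), ("r2", "A", 40), ("r3", "G", 20)]})
        out = correct_low_quality(p)
        assert [c.base for c in out[5]] == ["A", "A", "A"]

    def test_subq30_call_supported_by_another_read_kept(self):
        p = _pileup({5: [("r1", "A", 40), ("r2", "G", 20), ("r3", "G", 20)]})
        out = correct_low_quality(p)
        assert sorted(c.base for c in out[5]) == ["A", "G", "G"]

    def test_high_quality_mismatch_kept(self):
        p = _pileup({5: [("r1", "A", 40), ("r2", "A", 40), ("r3", "G", 30)]})
        out = correct_low_quality(p)
        assert sorted(c.base for c in out[5]) == ["A", "A", "G"]


class TestSnpCalling:
    def test_two_supporting_reads_is_a_snp(self):
        p = _pileup({0: [("r1", "A", 40), ("r2", "A", 40), ("r3", "G", 40), ("r4", "G", 40)]})
        snps = call_snps(p)
        assert len(snps) == 1
        assert snps[0].alt_bases == {"G": 2}
        assert snps[0].coverage == 4

    def test_singleton_mutation_not_a_snp(self):
        p = _pileup({0: [("r1", "A", 40), ("r2", "A", 40), ("r3", "A", 40), ("r4", "G", 40)]})
        assert call_snps(p) == []

    def test_coverage_below_four_not_a_snp(self):
        p = _pileup({0: [("r1", "A", 40), ("r2", "G", 40), ("r3", "G", 40)]})
        assert call_snps(p) == []

    def test_matches_bruteforce_scan_on_random_pileups(self, rng):
        for _ in range(200):
            n_cols = int(rng.integers(1, 6))
            p = {}
            for pos in range(n_cols):
                cov = int(rng.integers(1, 9))
                p[pos] = [
                    BaseCall(f"r{i}", "ACGT"[rng.integers(4)], int(rng.integers(10, 60)))
                    for i in range(cov)
                ]
            got = {s.position: s.alt_bases for s in call_snps(p)}
            expected = {}
            for pos, calls in p.items():
                if len(calls) < 4:
                    continue
                cons = column_consensus(calls)
                tally: dict[str, int] = {}
                for c in calls:
                    tally[c.base] = tally.get(c.base, 0) + 1
                alts = {b: n for b, n in tally.items() if b != cons and n >= 2}
                if alts:
                    expected[pos] = alts
            assert got == expected


class TestDepthAndSelection:
    def _reads(self, rows):
        return pd.DataFrame(
            rows, columns=["read_id", "scaffold_id", "start", "end"]
        )

    def test_mean_depth_counts_uncovered_positions(self):
        p = _pileup({0: [("r1", "A", 40)], 1: [("r1", "C", 40)]})
        assert mean_depth(p, 0, 4) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            mean_depth(p, 4, 4)

    def test_selection_strict_above_seven(self):
        cds = pd.DataFrame(
            [("c7", "s1", 0, 100), ("c75", "s2", 0, 100)],
            columns=["cds_id", "scaffold_id", "start", "end"],
        )
        reads = self._reads(
            [(f"a{i}", "s1", 0, 100) for i in range(7)]
            + [(f"b{i}", "s2", 0, 100) for i in range(7)]
            + [("b7", "s2", 0, 50)]
        )
        kept = select_cds(cds, reads)
        assert list(kept["cds_id"]) == ["c75"]
        assert kept["mean_depth"].iloc[0] == pytest.approx(7.5)


class TestTrackReconstruction:
    def test_no_snps_single_track(self):
        p = _pileup(
            {i: [("r1", "A", 40), ("r2", "A", 40)] for i in range(6)}
        )
        tracks, cls = reconstruct_tracks("c1", p, [], (0, 6))
        assert cls == "no_snps"
        assert len(tracks) == 1 and sorted(tracks[0].read_ids) == ["r1", "r2"]

    def test_two_clean_haplotypes(self):
        # SNP at 2: r1/r2 carry A (consensus), r3/r4 carry G
        cols = {}
        for i in range(6):
            base_by_read = {"r1": "A", "r2": "A", "r3": "A", "r4": "A"}
            if i == 2:
                base_by_read["r3"] = base_by_read["r4"] = "G"
            cols[i] = [(r, base_by_read[r], 40) for r in base_by_read]
        p = _pileup(cols)
        snps = call_snps(p)
        tracks, cls = reconstruct_tracks("c1", p, snps, (0, 6))
        assert cls == "multi_variant" and len(tracks) == 2
        memberships = {frozenset(t.read_ids) for t in tracks}
        assert memberships == {frozenset({"r1", "r2"}), frozenset({"r3", "r4"})}

    def test_conflicting_chain_is_undetermined(self):
        # group a (sites 0,1: G,C) links to group b (sites 1,2: C,T) at
        # site 1, group b links to group c (sites 0,2: T,T) at site 2, yet
        # groups a and c conflict at site 0 -> transitive closure merges
        # an inconsistent set -> undetermined
        cols: dict[int, list] = {0: [], 1: [], 2: []}
        for i in range(5):  # consensus background
            for pos in cols:
                cols[pos].append((f"bg{i}", "A", 40))
        for i in range(2):
            cols[0].append((f"a{i}", "G", 40))
            cols[1].append((f"a{i}", "C", 40))
            cols[1].append((f"b{i}", "C", 40))
            cols[2].append((f"b{i}", "T", 40))
            cols[0].append((f"c{i}", "T", 40))
            cols[2].append((f"c{i}", "T", 40))
        p = _pileup(cols)
        snps = call_snps(p)
        assert len(snps) == 3  # sanity: the conflict sits on real SNP sites
        tracks, cls = reconstruct_tracks("c1", p, snps, (0, 3))
        assert cls == "undetermined" and tracks == []

    def test_planted_three_haplotype_cds_recovered(self, small_community):
        com = small_community
        (cds_id,) = com.truth.variant_haplotypes
        row = com.annotations[com.annotations["cds_id"] == cds_id].iloc[0]
        pileup = build_pileup(com.reads, row["scaffold_id"], row["start"], row["end"])
        pileup = correct_low_quality(pileup)
        snps = call_snps(pileup)
        tracks, cls = reconstruct_tracks(cds_id, pileup, snps, (row["start"], row["end"]))
        assert cls == "multi_variant"
        assert len(tracks) == 3

        # every planted read lands in a track with only its own haplotype
        hap_of = {
            rid: hap
            for rid, (cid, hap) in com.truth.cds_haplotype.items()
            if cid == cds_id
        }
        track_of_hap = {}
        for t in tracks:
            haps = {hap_of[r] for r in t.read_ids if r in hap_of}
            assert len(haps) <= 1
            if haps:
                track_of_hap[haps.pop()] = t
        assert set(track_of_hap) == {1, 2, 3}

        # seasonal labels follow the planted per-haplotype bias (0.5, 1.0, 0.0)
        seasons = dict(zip(com.reads["read_id"], com.reads["season"]))
        assert classify_season(track_of_hap[2], seasons) == "summer_only"
        assert classify_season(track_of_hap[3], seasons) == "winter_only"

        # tracks partition the SNP-informative reads (no read in two tracks)
        all_members = [r for t in tracks for r in t.read_ids]
        assert len(all_members) == len(set(all_members))

        # dN/dS vs the reference: planted 2 syn + 1 nonsyn per haplotype
        ref = pick_reference(tracks, "".join("N" for _ in range(row["end"] - row["start"])), row["start"])
        for t in tracks:
            if t is ref:
                continue
            r = track_pair_dnds(ref, t, (row["start"], row["end"]))
            assert r.classification == "purifying"
            assert r.ratio is not None and r.ratio < 1.0


class TestReferenceAndSeasons:
    def _track(self, tid, reads, consensus, span=(0, 6)):
        return VariantTrack(tid, "c", reads, {}, consensus, span)

    def test_most_reads_wins(self):
        t1 = self._track("c.v1", ["a", "b", "c", "d"], "AAAAAA")
        t2 = self._track("c.v2", ["e", "f"], "AAAAAA")
        assert pick_reference([t2, t1], "AAAAAA", 0) is t1

    def test_tie_broken_by_consensus_identity(self):
        t1 = self._track("c.v1", ["a", "b", "c"], "AAAATA")
        t2 = self._track("c.v2", ["d", "e", "f"], "AAAAAA")
        assert pick_reference([t1, t2], "AAAAAA", 0) is t2

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pick_reference([], "", 0)

    def test_classify_season(self):
        t = self._track("c.v1", ["a", "b"], "AA")
        assert classify_season(t, {"a": "summer", "b": "summer"}) == "summer_only"
        assert classify_season(t, {"a": "winter", "b": "winter"}) == "winter_only"
        assert classify_season(t, {"a": "winter", "b": "summer"}) == "both"
        with pytest.raises(ValueError):
            classify_season(t, {"a": "winter"})


class TestCensusSummary:
    def test_reference_census_totals(self):
        table = pd.read_csv(DATA / "variant_census.tsv", sep="\t")
        totals = summarize_variant_table(table)
        assert totals["winter_only"] == 23
        assert totals["summer_only"] == 36
        assert totals["both_seasons"] == 42
        assert totals["total_variants"] == 101

    def test_empty_table_sums_to_zero(self):
        table = pd.DataFrame(columns=["bin_id", "winter_only", "summer_only", "both_seasons"])
        totals = summarize_variant_table(table)
        assert totals["total_variants"] == 0
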