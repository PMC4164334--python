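"""End-to-end driver: bin -> refine -> quality -> variants -> biogeography."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import binning, biogeography, io as fio, quality, variants
from .config import PipelineConfig
from .kmer import compute_profile

logger = logging.getLogger(__name__)

STAGES = ("bin", "refine", "quality", "variants", "biogeo")


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        """Atomic write: stage to a temp file, then rename into place."""
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "inputs": self.inputs,
                    "timings": self.timings,
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        tmp.replace(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def family_counts_for_bin(
    scaffold_ids: list[str], annotations: pd.DataFrame
) -> Counter:
    """Gene-family occurrence counts over a set of scaffolds."""
    sub = annotations[
        annotations["scaffold_id"].isin(scaffold_ids)
        & (annotations["family_ids"] != "")
    ]
    counts: Counter = Counter()
    for fams in sub["family_ids"]:
        for fam in str(fams).split(","):
            counts[fam] += 1
    return counts


def homology_from_families(annotations: pd.DataFrame) -> set[frozenset[str]]:
    """Injected CDS homology relation: two CDS are homologs iff they share a family."""
    pairs: set[frozenset[str]] = set()
    sub = annotations[annotations["family_ids"] != ""]
    by_family: dict[str, list[str]] = {}
    for cds, fams in zip(sub["cds_id"], sub["family_ids"]):
        for fam in str(fams).split(","):
            by_family.setdefault(fam, []).append(cds)
    for members in by_family.values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                pairs.add(frozenset((a, b)))
    return pairs


def run_pipeline(
    config: PipelineConfig,
    scaffolds_fasta: str | Path,
    reads_tsv: str | Path,
    annotations_tsv: str | Path,
    pangenome_tsv: str | Path,
    outdir: str | Path,
) -> RunManifest:
    """Run every stage on file inputs, writing per-stage TSVs and a manifest.

    A missing or unreadable input halts at the stage that needs it, with
    earlier outputs left intact on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {}
    for p in (scaffolds_fasta, reads_tsv, annotations_tsv, pangenome_tsv):
        p = Path(p)
        if p.exists():
            inputs[str(p)] = _sha256(p)
    manifest = RunManifest(config=config.to_dict(), inputs=inputs)

    def _require(path, stage):
        if not Path(path).exists():
            manifest.write(outdir / "manifest.json")
            raise FileNotFoundError(
                f"stage {stage!r} needs input {path}; run halted "
                "(previous outputs kept)"
            )

    # ---- stage: bin ------------------------------------------------------
    t0 = time.monotonic()
    _require(scaffolds_fasta, "bin")
    _require(reads_tsv, "bin")
    scaffolds = fio.read_fasta(scaffolds_fasta)
    reads = fio.read_alignment_table(reads_tsv, scaffolds)
    _require(annotations_tsv, "bin")
    annotations = fio.read_annotation_table(annotations_tsv)
    marker_scaffolds = set(
        annotations.loc[annotations.get("is_marker", False), "scaffold_id"]
    )
    records = {
        sid: binning.ScaffoldRecord(
            id=sid,
            sequence=seq,
            read_ids=tuple(reads.loc[reads["scaffold_id"] == sid, "read_id"]),
            has_marker=sid in marker_scaffolds,
        )
        for sid, seq in scaffolds.items()
    }
    profiles = {
        sid: compute_profile(seq, sid)
        for sid, seq in scaffolds.items()
        if len(seq) > config.min_scaffold_bp_pass1
    }
    lengths = {sid: len(seq) for sid, seq in scaffolds.items()}
    dendro = binning.cluster_scaffolds(
        list(profiles.values()), lengths, config.min_scaffold_bp_pass1
    )
    candidates = binning.extract_seed_clusters(dendro, records, config.r_min)
    candidates = binning.filter_candidates(
        candidates, records, "size", min_bp=config.min_bin_bp
    )
    candidates = binning.filter_candidates(
        candidates,
        records,
        "reads",
        min_reads=config.min_bin_reads,
        min_scaffold_bp=config.min_scaffold_bp_pass2,
    )

    _require(pangenome_tsv, "quality")
    core = quality.build_core_genome(fio.read_pangenome_counts(pangenome_tsv))

    def dup_estimate(cand: binning.BinCandidate) -> float:
        counts = family_counts_for_bin(cand.scaffold_ids, annotations)
        _, dups = quality.count_core_in_bin(counts, core)
        return quality.estimate_duplication(dups, core)

    final_bins: list[binning.BinCandidate] = []
    for cand in candidates:
        final_bins.extend(
            binning.subdivide_until_clean(
                cand, profiles, records, dup_estimate, dup_max=config.dup_max_pct
            )
        )
    bins = {b.bin_id: list(b.scaffold_ids) for b in final_bins}
    fio.write_bin_table(bins, outdir / "bins.tsv")
    manifest.outputs["bins"] = str(outdir / "bins.tsv")
    manifest.timings["bin"] = time.monotonic() - t0

    # ---- stage: refine ---------------------------------------------------
    t0 = time.monotonic()
    homology = homology_from_families(annotations)
    scaffold_genes = {
        sid: set(annotations.loc[annotations["scaffold_id"] == sid, "cds_id"])
        for sid in scaffolds
    }
    refined: dict[str, list[str]] = {}
    removed_rows = []
    for bid, members in bins.items():
        kept, removed, no_evidence = quality.taxonomy_filter(
            members, annotations, config.target_phylum, config.taxon_vote_min
        )
        for s in removed:
            removed_rows.append({"bin_id": bid, "scaffold_id": s, "reason": "taxonomy"})
        kept, dedup_removed = quality.dedup_scaffolds(
            kept, lengths, scaffold_genes, homology, config.dedup_min_shared
        )
        for s in dedup_removed:
            removed_rows.append({"bin_id": bid, "scaffold_id": s, "reason": "duplicate"})
        refined[bid] = kept
    fio.write_bin_table(refined, outdir / "bins_refined.tsv")
    pd.DataFrame(removed_rows, columns=["bin_id", "scaffold_id", "reason"]).to_csv(
        outdir / "removed_scaffolds.tsv", sep="\t", index=False
    )
    manifest.outputs["bins_refined"] = str(outdir / "bins_refined.tsv")
    manifest.timings["refine"] = time.monotonic() - t0

    # ---- stage: quality --------------------------------------------------
    t0 = time.monotonic()
    reports = []
    for bid, members in refined.items():
        counts = family_counts_for_bin(members, annotations)
        total_bp = sum(lengths[s] for s in members)
        rep = quality.bin_quality_report(bid, counts, core, total_bp)
        reports.append(
            {
                "bin_id": bid,
                "total_bp": rep.total_bp,
                "n_scaffolds": len(members),
                "pct_complete": rep.pct_complete,
                "pct_duplication": rep.pct_duplication,
                "approx_genome_bp": rep.approx_genome_bp,
            }
        )
    pd.DataFrame(reports).to_csv(outdir / "bin_quality.tsv", sep="\t", index=False)
    manifest.outputs["bin_quality"] = str(outdir / "bin_quality.tsv")
    manifest.timings["quality"] = time.monotonic() - t0

    # ---- stage: variants -------------------------------------------------
    t0 = time.monotonic()
    dnds_rows = []
    binned_scaffolds = {s: b for b, ms in refined.items() for s in ms}
    cds_in_bins = annotations[annotations["scaffold_id"].isin(binned_scaffolds)]
    selected = variants.select_cds(cds_in_bins, reads, config.cds_min_cov)
    read_seasons = dict(zip(reads["read_id"], reads["season"]))
    per_bin = {
        b: {"cds_over_7x": 0, "no_snps": 0, "multi_variant": 0,
            "winter_only": 0, "summer_only": 0, "both_seasons": 0}
        for b in refined
    }
    for row in selected.itertuples(index=False):
        bid = binned_scaffolds[row.scaffold_id]
        per_bin[bid]["cds_over_7x"] += 1
        pileup = variants.build_pileup(reads, row.scaffold_id, row.start, row.end)
        pileup = variants.correct_low_quality(pileup, config.q_min)
        snps = variants.call_snps(pileup, config.snp_min_cov, config.snp_min_alt)
        tracks, cls = variants.reconstruct_tracks(
            row.cds_id, pileup, snps, (row.start, row.end)
        )
        if cls == "no_snps":
            per_bin[bid]["no_snps"] += 1
        elif cls == "multi_variant":
            per_bin[bid]["multi_variant"] += 1
            for t in tracks:
                t.season = variants.classify_season(t, read_seasons)
                key = {"summer_only": "summer_only", "winter_only": "winter_only",
                       "both": "both_seasons"}[t.season]
                per_bin[bid][key] += 1
            cons = variants._consensus_sequence(pileup, (row.start, row.end))
            ref = variants.pick_reference(tracks, cons, row.start)
            for t in tracks:
                if t is ref:
                    continue
                try:
                    res = variants.track_pair_dnds(ref, t, (row.start, row.end))
                except ValueError:
                    continue
                dnds_rows.append(
                    {
                        "cds_id": row.cds_id,
                        "reference": res.pair[0],
                        "variant": res.pair[1],
                        "dN": res.dn,
                        "dS": res.ds,
                        "ratio": res.ratio,
                        "saturated": res.saturated,
                        "classification": res.classification,
                    }
                )
    census = pd.DataFrame(
        [{"bin_id": b, **vals} for b, vals in sorted(per_bin.items())]
    )
    census.to_csv(outdir / "variant_census.tsv", sep="\t", index=False)
    pd.DataFrame(
        dnds_rows,
        columns=["cds_id", "reference", "variant", "dN", "dS", "ratio",
                 "saturated", "classification"],
    ).to_csv(outdir / "dnds.tsv", sep="\t", index=False)
    manifest.outputs["variant_census"] = str(outdir / "variant_census.tsv")
    manifest.outputs["dnds"] = str(outdir / "dnds.tsv")
    manifest.timings["variants"] = time.monotonic() - t0

    # ---- stage: biogeo ---------------------------------------------------
    t0 = time.monotonic()
    flagged: set[str] = set()
    for bid, members in refined.items():
        with_reads = [s for s in members if (reads["scaffold_id"] == s).any()]
        if not with_reads:
            continue
        rep = biogeography.seasonal_outliers(bid, with_reads, reads)
        flagged.update(rep.flagged)
    table = biogeography.abundance(refined, reads, exclude_scaffolds=flagged)
    table.round(2).to_csv(outdir / "abundance.tsv", sep="\t")
    manifest.outputs["abundance"] = str(outdir / "abundance.tsv")
    manifest.timings["biogeo"] = time.monotonic() - t0

    manifest.write(outdir / "manifest.json")
    manifest.outputs["manifest"] = str(outdir / "manifest.json")
    return manifest
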