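"""Spatio-temporal abundance of bins and permutation significance tests.

Each Sanger read is treated as one sampled cell, so a bin's abundance in a
sample is simply the percent of that sample's reads that map to the bin's
scaffolds. Abundances are tabulated per site and pooled per season;
scaffolds whose seasonal read composition is an outlier within their bin
(Tukey IQR fences) are flagged and excluded from the biogeographic table,
though they remain available for gene-content analyses. Group differences
are assessed with a two-sided permutation t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PERMUTATIONS = 10_000
IQR_K = 1.5


@dataclass
class PermutationResult:
    group_sizes: tuple[int, int]
    t_observed: float
    permutations: int
    p_value: float


@dataclass
class OutlierReport:
    bin_id: str
    table: pd.DataFrame  # scaffold_id, summer_fraction, flag
    insufficient: bool  # bin too small for outlier calling

    @property
    def flagged(self) -> list[str]:
        return list(self.table.loc[self.table["flag"], "scaffold_id"])


def abundance(
    bin_members: dict[str, list[str]],
    reads: pd.DataFrame,
    exclude_scaffolds: set[str] | None = None,
) -> pd.DataFrame:
    """Bin x sample percent-of-reads table with seasonal pools and TOTAL row.

    ``bin_members`` maps bin_id -> scaffold ids; ``reads`` needs columns
    read_id, scaffold_id, sample_id, season. Percentages are relative to
    the *total* reads of each sample (binned or not), so the per-sample
    binned percentages plus the unbinned remainder add to 100.
    """
    if exclude_scaffolds:
        reads = reads[~reads["scaffold_id"].isin(exclude_scaffolds)]
    sample_totals = reads.groupby("sample_id").size()
    if (sample_totals == 0).any() or sample_totals.empty:
        raise ValueError("every sample must have at least one read")
    sample_season = (
        reads.drop_duplicates("sample_id").set_index("sample_id")["season"]
    )
    seasons = ["winter", "summer"]
    season_totals = {
        s: sample_totals[sample_season[sample_totals.index] == s].sum()
        for s in seasons
    }

    scaffold_to_bin = {
        s: b for b, members in bin_members.items() for s in members
    }
    reads = reads.assign(bin_id=reads["scaffold_id"].map(scaffold_to_bin))
    binned = reads.dropna(subset=["bin_id"])
    per_bin_sample = binned.groupby(["bin_id", "sample_id"]).size()

    rows = {}
    for b in sorted(bin_members):
        row = {}
        for s in seasons:
            n = sum(
                per_bin_sample.get((b, smp), 0)
                for smp in sample_totals.index
                if sample_season[smp] == s
            )
            row[s] = 100.0 * n / season_totals[s] if season_totals[s] else 0.0
        for smp in sample_totals.index:
            row[smp] = 100.0 * per_bin_sample.get((b, smp), 0) / sample_totals[smp]
        rows[b] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["TOTAL"] = table.sum(axis=0)
    table.index.name = "bin"
    return table


def seasonal_fractions(
    scaffold_ids: list[str], reads: pd.DataFrame
) -> pd.Series:
    """Per-scaffold fraction of reads labelled summer."""
    sub = reads[reads["scaffold_id"].isin(scaffold_ids)]
    frac = (
        sub.assign(is_summer=sub["season"] == "summer")
        .groupby("scaffold_id")["is_summer"]
        .mean()
    )
    return frac.reindex(scaffold_ids)


def seasonal_outliers(
    bin_id: str,
    scaffold_ids: list[str],
    reads: pd.DataFrame,
    k: float = IQR_K,
    min_scaffolds: int = 4,
) -> OutlierReport:
    """Flag scaffolds whose summer-read fraction falls outside Tukey fences.

    Fences are [Q1 - k*IQR, Q3 + k*IQR] over the bin's per-scaffold summer
    fractions. Bins with fewer than ``min_scaffolds`` scaffolds yield no
    calls (too few replicates to define a distribution).
    """
    frac = seasonal_fractions(scaffold_ids, reads)
    if frac.isna().any():
        missing = list(frac.index[frac.isna()])
        raise ValueError(f"scaffolds without reads: {missing}")
    table = pd.DataFrame(
        {"scaffold_id": scaffold_ids, "summer_fraction": frac.to_numpy()}
    )
    if len(scaffold_ids) < min_scaffolds:
        table["flag"] = False
        return OutlierReport(bin_id=bin_id, table=table, insufficient=True)
    q1, q3 = np.percentile(table["summer_fraction"], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    table["flag"] = (table["summer_fraction"] < lo) | (table["summer_fraction"] > hi)
    return OutlierReport(bin_id=bin_id, table=table, insufficient=False)


def _t_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-variance two-sample t statistic (0 when both groups constant)."""
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def permutation_ttest(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    B: int = PERMUTATIONS,
    rng_seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Two-sided permutation t-test.

    p = (1 + #{|t*| >= |t_obs|}) / (B + 1) — the add-one convention, so p
    is never zero and is bounded below by 1/(B+1).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    t_obs = _t_statistic(a, b)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    # vectorized label shuffles: argsort of uniform noise = random permutation
    order = np.argsort(rng.random((B, n)), axis=1)
    perm = pooled[order]
    pa, pb = perm[:, :na], perm[:, na:]
    ma, mb = pa.mean(axis=1), pb.mean(axis=1)
    va = pa.var(axis=1, ddof=1) if na > 1 else np.zeros(B)
    vb = pb.var(axis=1, ddof=1) if n - na > 1 else np.zeros(B)
    sp2 = ((na - 1) * va + (n - na - 1) * vb) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / (n - na)))
    t_star = np.where(sp2 == 0, np.where(ma == mb, 0.0, np.inf), t_star)
    exceed = int(np.sum(np.abs(t_star) >= abs(t_obs)))
    p = (1 + exceed) / (B + 1)
    return PermutationResult(
        group_sizes=(len(a), len(b)),
        t_observed=t_obs,
        permutations=B,
        p_value=p,
    )
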