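"""Shared fixtures: small synthetic communities and a reference core genome."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flavbin.quality import build_core_genome
from flavbin.simulate import CommunitySpec, VariantPlan, generate_community


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def small_spec(seed: int = 7, **overrides) -> CommunitySpec:
    defaults = dict(
        num_genomes=2,
        genome_length_bp=150_000,
        scaffold_length_range=(5_000, 10_000),
        reads_per_sample=800,
        planted_cscg_count=20,
        planted_variants=[
            VariantPlan(
                num_haplotypes=3,
                syn_snps=2,
                nonsyn_snps=1,
                reads_per_haplotype=8,
                season_bias=(0.5, 1.0, 0.0),
            )
        ],
        rng_seed=seed,
    )
    defaults.update(overrides)
    return CommunitySpec(**defaults)


@pytest.fixture(scope="session")
def small_community():
    """Two 150-kb genomes, 6 samples, planted core genes and a 3-haplotype CDS."""
    return generate_community(small_spec())


@pytest.fixture(scope="session")
def reference_core():
    """A synthetic pangenome shaped like the study's reference core genome.

    Seven reference genomes; 665 core families and 799 expected
    occurrences, of which 199 families are single-copy in every genome
    (the CSCG set): 199 strict singletons, 332 families that one genome
    carries twice (min count 1, not single-copy), and 134 two-copy
    families.
    """
    n_refs = 7
    data: dict[str, list[int]] = {}
    for i in range(199):
        data[f"SC{i:03d}"] = [1] * n_refs
    for i in range(332):
        data[f"UN{i:03d}"] = [2] + [1] * (n_refs - 1)
    for i in range(134):
        data[f"DU{i:03d}"] = [2] * n_refs
    counts = pd.DataFrame(data, index=[f"ref{j}" for j in range(n_refs)])
    core = build_core_genome(counts)
    assert core.n_families == 665
    assert core.expected_total == 799
    assert len(core.cscg_set) == 199
    return core
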