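"""Shared fixtures: small hand-built records and simulated harmonized datasets."""

from __future__ import annotations

import numpy as np
import pytest

from summr import (
    HarmonizedDataset,
    Pleiotropy,
    SimulationConfig,
    VariantAssociation,
    harmonize_dataset,
    simulate_gwas_pair,
)


def make_variant(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pvalue=1e-10,
    chrom="1",
    pos=1_000_000,
    eaf=0.3,
    n=100_000,
    **kwargs,
) -> VariantAssociation:
    return VariantAssociation(
        variant_id=variant_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pvalue=pvalue,
        chrom=chrom,
        pos=pos,
        eaf=eaf,
        n=n,
        **kwargs,
    )


@pytest.fixture
def sim_dataset():
    """Factory: clean simulated harmonized dataset with known causal effect."""

    def _make(seed: int, theta: float = 0.0, k: int = 50,
              pleiotropy: Pleiotropy | None = None, **cfg_kwargs) -> HarmonizedDataset:
        config = SimulationConfig(
            n_variants=k,
            theta=theta,
            pleiotropy=pleiotropy or Pleiotropy.none(),
            palindrome_fraction=0.0,
            seed=seed,
            **cfg_kwargs,
        )
        exposure, outcome, _ = simulate_gwas_pair(config)
        return harmonize_dataset(exposure, outcome)

    return _make


@pytest.fixture
def random_arrays_dataset():
    """Factory: harmonized dataset built from random effect arrays."""

    def _make(seed: int, k: int = 10) -> HarmonizedDataset:
        rng = np.random.default_rng(seed)
        bx = rng.normal(0.05, 0.02, k)
        bx[np.abs(bx) < 1e-3] = 0.02
        by = rng.normal(0.01, 0.02, k)
        sx = rng.uniform(0.002, 0.01, k)
        sy = rng.uniform(0.005, 0.03, k)
        return HarmonizedDataset.from_arrays(bx, sx, by, sy)

    return _make
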