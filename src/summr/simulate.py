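"""Synthetic GWAS summary statistics with known causal truth.

The generator emulates the data regime of a modern 2-sample MR analysis:
a large continuous-trait exposure GWAS (hundreds of thousands of samples)
and a binary outcome GWAS with extreme case/control imbalance, reported as
per-variant effect estimates with sampling noise scaled by allele frequency
and sample size.

For each variant j with effect-allele frequency f_j the true standardized
exposure effect γ_j is sized to explain a configured fraction of trait
variance, r²_j = 2 f_j (1 − f_j) γ_j².  Observed effects are

    β_Xj ~ N(γ_j, se_Xj²),        se_Xj = 1 / sqrt(2 n_X f_j (1 − f_j))
    β_Yj ~ N(θ γ_j + α_j, se_Yj²), se_Yj = 1 / sqrt(2 n_eff f_j (1 − f_j))

with n_eff = 4 / (1/n_case + 1/n_control) the effective outcome sample size
and α_j a horizontal-pleiotropy term (zero, balanced, or directional;
directional means are applied relative to the exposure-increasing allele, so
they survive arbitrary allele-label orientation).
Outcome effects are drawn directly on the log-odds scale — no
individual-level genotypes are simulated — and exposure and outcome noise
use independent random streams (the two-sample design).  Instruments are
mutually unlinked and placed > 1 Mb apart, i.e. post-clumping by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .io import SummaryStats, TraitMeta, VariantAssociation

__all__ = [
    "Pleiotropy",
    "SimulationConfig",
    "MultiSimulationConfig",
    "SimulationTruth",
    "simulate_gwas_pair",
    "simulate_multi_exposure",
]

_P_FLOOR = float(np.nextafter(0, 1))


@dataclass(frozen=True)
class Pleiotropy:
    """Horizontal-pleiotropy regime for the variant–outcome direct effects α_j."""

    kind: str = "none"  # none | balanced | directional
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.kind == "balanced" and self.mean != 0:
            raise ValueError("balanced pleiotropy has mean 0")
        if self.sd < 0:
            raise ValueError("pleiotropy sd must be >= 0")

    @classmethod
    def none(cls) -> "Pleiotropy":
        return cls("none")

    @classmethod
    def balanced(cls, sd: float) -> "Pleiotropy":
        return cls("balanced", 0.0, sd)

    @classmethod
    def directional(cls, mean: float, sd: float) -> "Pleiotropy":
        return cls("directional", mean, sd)

    def draw(self, rng: np.random.Generator, k: int) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(k)
        return rng.normal(self.mean, self.sd, size=k)


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one exposure/outcome summary-statistic pair.

    Defaults mirror a large continuous exposure GWAS (n = 300,000) read
    against a severely imbalanced binary outcome (6,406 cases / 902,088
    controls), with per-variant variance explained drawn uniformly from
    [0.02%, 0.1%] so a 50-variant instrument set explains a few percent of
    the exposure — the regime typical of complex-trait instruments.
    """

    n_variants: int = 50
    n_exposure: int = 300_000
    n_case: int = 6_406
    n_control: int = 902_088
    theta: float = 0.0
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    r2_per_variant: tuple[float, float] = (0.0002, 0.001)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    palindrome_fraction: float = 0.1
    seed: int = 0
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"

    def __post_init__(self):
        if min(self.n_variants, self.n_exposure, self.n_case, self.n_control) <= 0:
            raise ValueError("all sizes must be positive")
        lo, hi = self.r2_per_variant
        if not 0 < lo <= hi < 1:
            raise ValueError("per-variant variance explained must lie in (0, 1)")
        if not 0 <= self.palindrome_fraction <= 1:
            raise ValueError("palindrome_fraction must be in [0, 1]")
        lo, hi = self.eaf_range
        if not 0 < lo <= hi < 1:
            raise ValueError("eaf_range must lie strictly inside (0, 1)")


@dataclass
class SimulationTruth:
    """The generating parameters attached to every synthetic dataset."""

    theta: float | np.ndarray
    gamma: np.ndarray  # true variant–exposure effects (total, per exposure column)
    alpha: np.ndarray  # horizontal-pleiotropy effects on the outcome
    seed: int
    gamma_direct: np.ndarray | None = None
    cross_effects: np.ndarray | None = None


def _assign_alleles(rng: np.random.Generator, k: int, palindrome_fraction: float):
    """Effect/other allele pairs; a configured fraction are strand-ambiguous."""
    n_pal = int(round(palindrome_fraction * k))
    is_pal = np.zeros(k, dtype=bool)
    if n_pal:
        is_pal[rng.choice(k, size=n_pal, replace=False)] = True
    pal_pairs = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
    plain_pairs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T")]
    ea, oa = [], []
    for j in range(k):
        pair = pal_pairs[rng.integers(len(pal_pairs))] if is_pal[j] else (
            plain_pairs[rng.integers(len(plain_pairs))]
        )
        ea.append(pair[0])
        oa.append(pair[1])
    return ea, oa


def _positions(k: int) -> tuple[list[str], list[int]]:
    # mutually unlinked by design: cycle chromosomes, 5 Mb apart on each
    chroms = [str(j % 22 + 1) for j in range(k)]
    pos = [10_000_000 + (j // 22) * 5_000_000 for j in range(k)]
    return chroms, pos


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, _P_FLOOR, 1.0)


def _records(
    ids, chroms, pos, ea, oa, eaf, beta, se, trait_id, n=None, n_case=None, n_control=None
) -> list[VariantAssociation]:
    pvals = _pvalues(beta, se)
    return [
        VariantAssociation(
            variant_id=ids[j],
            effect_allele=ea[j],
            other_allele=oa[j],
            beta=float(beta[j]),
            se=float(se[j]),
            pvalue=float(pvals[j]),
            chrom=chroms[j],
            pos=pos[j],
            eaf=float(eaf[j]),
            n=n,
            n_case=n_case,
            n_control=n_control,
            trait_id=trait_id,
        )
        for j in range(len(ids))
    ]


def effective_sample_size(n_case: int, n_control: int) -> float:
    """n_eff = 4 / (1/n_case + 1/n_control); equals 4 n φ(1−φ) at case fraction φ."""
    return 4.0 / (1.0 / n_case + 1.0 / n_control)


def simulate_gwas_pair(
    config: SimulationConfig,
) -> tuple[SummaryStats, SummaryStats, SimulationTruth]:
    """Draw one exposure table, one outcome table, and the generating truth."""
    cfg = config
    k = cfg.n_variants
    ss = np.random.SeedSequence(cfg.seed)
    rng_struct, rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(3))

    eaf = rng_struct.uniform(*cfg.eaf_range, size=k)
    r2 = rng_struct.uniform(*cfg.r2_per_variant, size=k)
    het = 2 * eaf * (1 - eaf)
    gamma = np.sqrt(r2 / het) * rng_struct.choice([-1.0, 1.0], size=k)
    # pleiotropy is defined relative to the exposure-increasing allele, so a
    # directional mean survives re-orientation of arbitrary allele labels
    alpha = np.where(gamma >= 0, 1.0, -1.0) * cfg.pleiotropy.draw(rng_struct, k)
    ea, oa = _assign_alleles(rng_struct, k, cfg.palindrome_fraction)
    chroms, pos = _positions(k)
    ids = [f"rs{j+1}" for j in range(k)]

    se_x = 1.0 / np.sqrt(2 * cfg.n_exposure * eaf * (1 - eaf))
    beta_x = rng_x.normal(gamma, se_x)

    n_eff = effective_sample_size(cfg.n_case, cfg.n_control)
    se_y = 1.0 / np.sqrt(2 * n_eff * eaf * (1 - eaf))
    b = cfg.theta * gamma + alpha
    beta_y = rng_y.normal(b, se_y)

    exposure = SummaryStats(
        records=_records(ids, chroms, pos, ea, oa, eaf, beta_x, se_x,
                         cfg.exposure_id, n=cfg.n_exposure),
        meta=TraitMeta(trait_id=cfg.exposure_id, trait_type="continuous",
                       unit_label="SD", n=cfg.n_exposure),
    )
    outcome = SummaryStats(
        records=_records(ids, chroms, pos, ea, oa, eaf, beta_y, se_y, cfg.outcome_id,
                         n=cfg.n_case + cfg.n_control, n_case=cfg.n_case,
                         n_control=cfg.n_control),
        meta=TraitMeta(trait_id=cfg.outcome_id, trait_type="binary", unit_label="log-odds",
                       n=cfg.n_case + cfg.n_control, n_case=cfg.n_case,
                       n_control=cfg.n_control),
    )
    truth = SimulationTruth(theta=cfg.theta, gamma=gamma, alpha=alpha, seed=cfg.seed)
    return exposure, outcome, truth


@dataclass(frozen=True)
class MultiSimulationConfig:
    """Generating parameters for an m-exposure system with cross-exposure paths.

    Each exposure has its own block of primary variants (``n_variants[i]``
    variants whose direct effects act on exposure i).  ``cross_effects`` is a
    strictly lower-triangular m×m matrix: entry (l, i) is the causal path
    coefficient from exposure i to exposure l, so a variant's total effect on
    a downstream exposure includes mediated paths.  ``theta`` holds each
    exposure's direct effect on the outcome; an exposure whose only route to
    the outcome is through a mediator gets theta 0 and a nonzero cross path.
    """

    n_variants: tuple[int, ...] = (30, 30)
    n_exposure: tuple[int, ...] = (300_000, 300_000)
    cross_effects: tuple[tuple[float, ...], ...] | None = None
    theta: tuple = (0.0, 0.0)
    n_case: int = 6_406
    n_control: int = 902_088
    n_outcomes: int = 1
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    r2_per_variant: tuple[float, float] = (0.0002, 0.001)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    palindrome_fraction: float = 0.1
    seed: int = 0
    exposure_ids: tuple[str, ...] | None = None
    outcome_id: str = "outcome"

    @property
    def m(self) -> int:
        return len(self.n_variants)

    def theta_matrix(self) -> np.ndarray:
        """(m, n_outcomes) direct effects; a flat theta is shared across outcomes."""
        arr = np.asarray(self.theta, dtype=float)
        if arr.ndim == 1:
            arr = np.tile(arr[:, None], (1, self.n_outcomes))
        if arr.shape != (self.m, self.n_outcomes):
            raise ValueError(f"theta must be ({self.m},) or ({self.m}, {self.n_outcomes})")
        return arr

    def cross_matrix(self) -> np.ndarray:
        m = self.m
        if self.cross_effects is None:
            return np.zeros((m, m))
        mat = np.asarray(self.cross_effects, dtype=float)
        if mat.shape != (m, m):
            raise ValueError(f"cross_effects must be {m}x{m}")
        if np.any(np.triu(mat) != 0):
            raise ValueError("cross_effects must be strictly lower-triangular (acyclic)")
        return mat

    def __post_init__(self):
        if len(self.n_exposure) != self.m:
            raise ValueError("n_exposure must have one entry per exposure")
        if self.n_outcomes <= 0:
            raise ValueError("n_outcomes must be positive")
        self.cross_matrix()
        self.theta_matrix()


def simulate_multi_exposure(
    config: MultiSimulationConfig,
) -> tuple[list[SummaryStats], SummaryStats, SimulationTruth]:
    """Draw m exposure tables sharing one variant panel, plus the outcome table.

    The outcome is generated from the exposures' *total* variant effects:
    b_j = Σ_l theta_l Γ_jl + α_j with Γ = Γ_direct propagated through the
    cross-exposure paths.  Every exposure table reports effects for the full
    variant panel (multivariable MR needs each variant's effect on every
    exposure).  With ``n_outcomes > 1`` a list of outcome tables is returned,
    each with its own noise stream and its own theta column — a joint panel
    for exposure × outcome screens.
    """
    cfg = config
    m = cfg.m
    lam = cfg.cross_matrix()
    theta = cfg.theta_matrix()
    k = int(np.sum(cfg.n_variants))
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(1 + cfg.n_outcomes + m)
    rng_struct = np.random.default_rng(streams[0])
    rng_y = [np.random.default_rng(s) for s in streams[1:1 + cfg.n_outcomes]]
    rng_x = [np.random.default_rng(s) for s in streams[1 + cfg.n_outcomes:]]

    eaf = rng_struct.uniform(*cfg.eaf_range, size=k)
    r2 = rng_struct.uniform(*cfg.r2_per_variant, size=k)
    het = 2 * eaf * (1 - eaf)
    gamma_direct = np.zeros((k, m))
    start = 0
    for i, ki in enumerate(cfg.n_variants):
        block = slice(start, start + ki)
        gamma_direct[block, i] = np.sqrt(r2[block] / het[block]) * rng_struct.choice(
            [-1.0, 1.0], size=ki
        )
        start += ki

    gamma_total = gamma_direct.copy()
    for l in range(m):  # acyclic propagation in index order
        for i in range(l):
            gamma_total[:, l] += lam[l, i] * gamma_total[:, i]

    # orient directional pleiotropy to each variant's own-block increasing allele
    block_sign = np.where(gamma_direct.sum(axis=1) >= 0, 1.0, -1.0)
    alpha = block_sign * cfg.pleiotropy.draw(rng_struct, k)
    ea, oa = _assign_alleles(rng_struct, k, cfg.palindrome_fraction)
    chroms, pos = _positions(k)
    ids = [f"rs{j+1}" for j in range(k)]
    names = cfg.exposure_ids or tuple(f"exposure_{i+1}" for i in range(m))

    exposures = []
    for i in range(m):
        se_x = 1.0 / np.sqrt(2 * cfg.n_exposure[i] * eaf * (1 - eaf))
        beta_x = rng_x[i].normal(gamma_total[:, i], se_x)
        exposures.append(
            SummaryStats(
                records=_records(ids, chroms, pos, ea, oa, eaf, beta_x, se_x, names[i],
                                 n=cfg.n_exposure[i]),
                meta=TraitMeta(trait_id=names[i], trait_type="continuous", unit_label="SD",
                               n=cfg.n_exposure[i]),
            )
        )

    n_eff = effective_sample_size(cfg.n_case, cfg.n_control)
    se_y = 1.0 / np.sqrt(2 * n_eff * eaf * (1 - eaf))
    outcomes = []
    for o in range(cfg.n_outcomes):
        name = cfg.outcome_id if cfg.n_outcomes == 1 else f"{cfg.outcome_id}_{o+1}"
        b = gamma_total @ theta[:, o] + alpha
        beta_y = rng_y[o].normal(b, se_y)
        outcomes.append(
            SummaryStats(
                records=_records(ids, chroms, pos, ea, oa, eaf, beta_y, se_y, name,
                                 n=cfg.n_case + cfg.n_control, n_case=cfg.n_case,
                                 n_control=cfg.n_control),
                meta=TraitMeta(trait_id=name, trait_type="binary", unit_label="log-odds",
                               n=cfg.n_case + cfg.n_control, n_case=cfg.n_case,
                               n_control=cfg.n_control),
            )
        )
    truth = SimulationTruth(
        theta=theta[:, 0] if cfg.n_outcomes == 1 else theta,
        gamma=gamma_total,
        alpha=alpha,
        seed=cfg.seed,
        gamma_direct=gamma_direct,
        cross_effects=lam,
    )
    return exposures, outcomes[0] if cfg.n_outcomes == 1 else outcomes, truth
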