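"""Genetic-instrument selection and strength diagnostics.

Instrument selection for a 2-sample MR analysis proceeds in two steps:
keep variants below a genome-wide significance threshold, then prune the
survivors so the retained set is approximately independent — greedy LD
clumping with an additional same-chromosome distance rule.  Per-variant
instrument strength is summarized by the F-statistic (beta/se)² and by the
fraction of trait variance (or liability) each variant explains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import TraitMeta, VariantAssociation
from .ld import LDSource

__all__ = [
    "InstrumentSet",
    "select_candidates",
    "ld_clump",
    "f_statistic",
    "variance_explained_continuous",
    "variance_explained_binary",
    "WEAK_INSTRUMENT_F",
]

logger = logging.getLogger(__name__)

#: conventional weak-instrument flag threshold
WEAK_INSTRUMENT_F = 10.0

#: genome-wide significance default
DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_THRESHOLD = 0.01
DEFAULT_WINDOW_BP = 1_000_000


@dataclass
class InstrumentSet:
    """Variants retained as instruments for one exposure, with diagnostics.

    ``f_stats[i]`` and ``r2_explained[i]`` refer to ``variants[i]``;
    ``r2_explained`` entries are NaN when the inputs needed to estimate
    variance explained (sample sizes, allele frequency) are missing.
    """

    trait_id: str
    variants: list[VariantAssociation]
    f_stats: np.ndarray
    r2_explained: np.ndarray
    selection_config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def n_weak(self) -> int:
        """Number of instruments with F below the conventional threshold of 10."""
        return int(np.sum(self.f_stats < WEAK_INSTRUMENT_F))

    @property
    def total_r2_explained(self) -> float:
        """Sum of per-variant variance explained, ignoring missing entries."""
        return float(np.nansum(self.r2_explained))


def select_candidates(
    stats: Iterable[VariantAssociation], p_threshold: float = DEFAULT_P_THRESHOLD
) -> list[VariantAssociation]:
    """Keep variants with ``pvalue < p_threshold``, preserving input order."""
    if not 0 < p_threshold <= 1:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    return [v for v in stats if v.pvalue < p_threshold]


def _clump_sort_key(v: VariantAssociation):
    # ties on p broken by (chrom, pos, variant_id) for reproducibility
    return (v.pvalue, str(v.chrom), v.pos if v.pos is not None else -1, v.variant_id)


def ld_clump(
    candidates: Sequence[VariantAssociation],
    ld: LDSource | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
    *,
    trait_meta: TraitMeta | None = None,
    prevalence: float | None = None,
    p_threshold: float | None = None,
) -> InstrumentSet:
    """Greedy LD + distance clumping of candidate instruments.

    Candidates are visited in ascending p-value order.  Each visited variant
    is retained unless it has r² above ``r2_threshold`` with an already
    retained variant, or sits on the same chromosome within ``window_bp``
    (center-to-center, half-open) of one.  With an empty/absent LD source
    every pair is treated as unlinked and only the distance rule prunes.

    Returns an :class:`InstrumentSet` carrying per-variant F-statistics and
    variance explained (continuous traits via p-value/sample-size inversion,
    binary traits via the liability-scale log-odds approximation).
    """
    ld = ld or LDSource.independent()
    candidates = list(candidates)
    for v in candidates:
        if v.chrom is None or v.pos is None:
            raise ValueError(f"variant {v.variant_id} is missing chrom/pos needed for clumping")

    missing_before = ld.missing_queries
    accepted: list[VariantAssociation] = []
    for v in sorted(candidates, key=_clump_sort_key):
        conflict = False
        for a in accepted:
            if ld.r2(v.variant_id, a.variant_id) > r2_threshold:
                conflict = True
                break
            if v.chrom == a.chrom and abs(v.pos - a.pos) < window_bp:
                conflict = True
                break
        if not conflict:
            accepted.append(v)
    missing = ld.missing_queries - missing_before
    if missing and len(ld):  # an empty source means "all unlinked" by declaration
        logger.warning(
            "%d variant pairs absent from the LD source were treated as independent (r2 = 0)",
            missing,
        )

    f_stats = np.array([f_statistic(v) for v in accepted])
    r2_explained = np.array([_variant_r2(v, trait_meta, prevalence) for v in accepted])
    config = {
        "p_threshold": p_threshold,
        "r2_threshold": r2_threshold,
        "window_bp": window_bp,
    }
    trait_id = trait_meta.trait_id if trait_meta else (accepted[0].trait_id if accepted else "")
    return InstrumentSet(
        trait_id=trait_id,
        variants=accepted,
        f_stats=f_stats,
        r2_explained=r2_explained,
        selection_config=config,
    )


def _variant_r2(
    v: VariantAssociation, meta: TraitMeta | None, prevalence: float | None
) -> float:
    binary = meta is not None and meta.trait_type == "binary"
    if binary:
        n_case = v.n_case if v.n_case is not None else (meta.n_case if meta else None)
        n_control = v.n_control if v.n_control is not None else (meta.n_control if meta else None)
        if v.eaf is None or n_case is None or n_control is None or not 0 < v.eaf < 1:
            return math.nan
        return variance_explained_binary(v.beta, v.eaf, n_case, n_control, prevalence)
    n = v.n if v.n is not None else (meta.n if meta else None)
    if n is None or n <= 2:
        return math.nan
    return variance_explained_continuous(v.pvalue, n)


def f_statistic(v: VariantAssociation) -> float:
    """Per-variant instrument strength, (beta/se)²."""
    if v.se <= 0:
        raise ValueError(f"{v.variant_id}: se must be > 0")
    return (v.beta / v.se) ** 2


def variance_explained_continuous(pvalue: float, n: int) -> float:
    """Trait variance explained by one variant, from its p-value and sample size.

    Inverts the reported p-value to the equivalent F statistic on
    (1, n − 2) degrees of freedom and converts via r² = F / (F + n − 2).
    Monotone decreasing in p at fixed n; p = 1 maps to 0.
    """
    if not 0 < pvalue <= 1:
        raise ValueError(f"pvalue must be in (0, 1], got {pvalue}")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    if pvalue == 1:
        return 0.0
    f_val = stats.f.isf(pvalue, 1, n - 2)
    if not math.isfinite(f_val):
        # the F quantile overflows for extreme p; the normal-quantile square
        # is its large-n limit and stays finite far further into the tail
        f_val = float(stats.norm.isf(pvalue / 2)) ** 2
    return float(f_val / (f_val + n - 2))


def variance_explained_binary(
    log_or: float,
    eaf: float,
    n_case: int,
    n_control: int,
    prevalence: float | None = None,
) -> float:
    """Liability-scale variance explained by one variant of a binary trait.

    The per-allele log odds ratio is mapped to a liability-scale effect with
    the threshold-model linearization b_liab ≈ b · K(1−K)/φ(Φ⁻¹(K)), where K
    is the population prevalence (defaulting to the sample case fraction),
    and the explained liability variance is 2·eaf·(1−eaf)·b_liab² on the
    unit-variance liability.  Symmetric under allele relabeling
    (log_or, eaf) ↔ (−log_or, 1−eaf); zero at log_or = 0.
    """
    if not 0 < eaf < 1:
        raise ValueError(f"eaf must be strictly inside (0, 1), got {eaf}")
    if n_case <= 0 or n_control <= 0:
        raise ValueError("n_case and n_control must be positive")
    if prevalence is None:
        prevalence = n_case / (n_case + n_control)
    if not 0 < prevalence < 1:
        raise ValueError(f"prevalence must be strictly inside (0, 1), got {prevalence}")
    if log_or == 0:
        return 0.0
    z = stats.norm.pdf(stats.norm.ppf(prevalence))
    b_liab = log_or * prevalence * (1 - prevalence) / z
    r2 = 2 * eaf * (1 - eaf) * b_liab**2
    return float(min(r2, 1 - np.finfo(float).eps))
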