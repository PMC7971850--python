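"""Multivariable MR: conditional (direct) effects and weak-instrument diagnostics.

With several exposures instrumented jointly, regressing the variant–outcome
effects on all exposures' variant effects at once (no intercept, weights
1/se_Y²) estimates each exposure's direct effect conditional on the others —
the summary-statistic analogue of multivariable instrumental-variable
regression.  The pairwise screen (one focal exposure conditioned on one
potential mediator at a time) is the orchestration used to decompose a total
effect into direct and mediated components.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .estimators import Z_95, _P_FLOOR, _two_sided_p
from .harmonize import HarmonizedDataset, HarmonizedVariant, harmonize_pair
from .instruments import DEFAULT_P_THRESHOLD, DEFAULT_R2_THRESHOLD, DEFAULT_WINDOW_BP, ld_clump
from .io import SummaryStats, VariantAssociation
from .ld import LDSource

__all__ = [
    "MVMRResult",
    "MultivariableIVW",
    "build_mvmr_dataset",
    "mvmr_fit",
    "instrument_strength_q",
]

_CONDITION_NUMBER_MAX = 1e10


@dataclass
class MVMRResult:
    """Conditional causal estimates, one per exposure, plus diagnostics."""

    exposures: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalue: np.ndarray
    n_variants: int
    strength_q: dict[str, tuple[float, float]] = field(default_factory=dict)
    overdispersion: float = 1.0

    def __post_init__(self):
        m = len(self.exposures)
        for name in ("beta", "se", "ci_low", "ci_high", "pvalue"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} must have one entry per exposure")
        if self.n_variants < m + 1:
            raise ValueError("need more variants than exposures")

    def estimate_for(self, trait_id: str) -> dict:
        i = self.exposures.index(trait_id)
        return {
            "beta": float(self.beta[i]),
            "se": float(self.se[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "pvalue": float(self.pvalue[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, trait in enumerate(self.exposures):
            sq = self.strength_q.get(trait)
            rows.append(
                {
                    "exposure": trait,
                    "beta": self.beta[i],
                    "se": self.se[i],
                    "ci_low": self.ci_low[i],
                    "ci_high": self.ci_high[i],
                    "odds_ratio": np.exp(self.beta[i]),
                    "pvalue": self.pvalue[i],
                    "n_variants": self.n_variants,
                    "strength_q": None if sq is None else sq[0],
                    "strength_q_pvalue": None if sq is None else sq[1],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "exposures": list(self.exposures),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "pvalue": self.pvalue.tolist(),
            "n_variants": self.n_variants,
            "strength_q": {k: list(v) for k, v in self.strength_q.items()},
            "overdispersion": self.overdispersion,
        }


def _design(data: HarmonizedDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bx = np.atleast_2d(data.beta_x)
    if bx.shape[0] == 1 and data.n_retained != 1:
        bx = bx.T
    by = data.beta_y
    w = 1.0 / data.se_y**2
    return bx, by, w


def _check_conditioning(xtwx: np.ndarray) -> None:
    cond = np.linalg.cond(xtwx)
    if not np.isfinite(cond) or cond > _CONDITION_NUMBER_MAX:
        raise ValueError(
            f"exposure effect columns are collinear (condition number {cond:.3g})"
        )


class MultivariableIVW(BaseEstimator):
    """Weighted multiple regression of β_Y on all exposures' β_X, no intercept.

    Standard errors use the multiplicative overdispersion factor
    max(1, sqrt(Q/(k−m))), mirroring random-effects univariable IVW.  When
    ``compute_strength`` is set, each exposure's conditional
    instrument-strength Q (Sanderson-style) is attached to the result.
    """

    def __init__(self, compute_strength: bool = True):
        self.compute_strength = compute_strength

    def fit(self, data: HarmonizedDataset) -> "MultivariableIVW":
        bx, by, w = _design(data)
        k, m = bx.shape
        if k <= m:
            raise ValueError(f"need more variants ({k}) than exposures ({m})")
        # an identically-zero effect column carries no information about its
        # exposure: solve on the informative columns, report beta 0 / se inf
        active = np.sqrt(np.sum(bx**2, axis=0)) > 0
        if not np.any(active):
            raise ValueError("all exposure effect columns are zero")
        bxa = bx[:, active]
        ma = int(np.sum(active))
        xtwx = bxa.T @ (bxa * w[:, None])
        _check_conditioning(xtwx)
        cov_unscaled = np.linalg.inv(xtwx)
        beta_a = cov_unscaled @ (bxa.T @ (w * by))
        resid = by - bxa @ beta_a
        q = float(np.sum(w * resid**2))
        phi = max(1.0, np.sqrt(q / (k - ma)))
        se_a = np.sqrt(np.diag(cov_unscaled)) * phi
        beta = np.zeros(m)
        se = np.full(m, np.inf)
        beta[active] = beta_a
        se[active] = se_a
        pvals = np.array(
            [_two_sided_p(b / s) if np.isfinite(s) else 1.0 for b, s in zip(beta, se)]
        )

        strength: dict[str, tuple[float, float]] = {}
        if self.compute_strength and m >= 2 and np.all(active):
            for trait in data.exposure_ids:
                strength[trait] = instrument_strength_q(data, trait)

        self.result_ = MVMRResult(
            exposures=tuple(data.exposure_ids),
            beta=beta,
            se=se,
            ci_low=beta - Z_95 * se,
            ci_high=beta + Z_95 * se,
            pvalue=pvals,
            n_variants=k,
            strength_q=strength,
            overdispersion=float(phi),
        )
        self.beta_ = beta
        self.se_ = se
        return self


def mvmr_fit(data: HarmonizedDataset, compute_strength: bool = True) -> MVMRResult:
    """Conditional causal estimates for every exposure; see :class:`MultivariableIVW`."""
    return MultivariableIVW(compute_strength=compute_strength).fit(data).result_


def instrument_strength_q(data: HarmonizedDataset, target_exposure: str) -> tuple[float, float]:
    """Conditional instrument-strength Q for one exposure given the others.

    The target exposure's variant effects are regressed (weights
    1/se_X,target², no intercept) on the other exposures' effects; the
    precision-weighted residual sum of squares is the strength statistic.
    Large Q relative to chi-square with k − (m − 1) degrees of freedom means
    the instruments predict the target beyond what they predict of the other
    exposures — i.e., conditionally strong instruments.  The returned
    p-value is the upper-tail chi-square probability (small p = strong).
    """
    if data.n_exposures < 2:
        raise ValueError("conditional strength needs >= 2 exposures")
    if target_exposure not in data.exposure_ids:
        raise ValueError(f"unknown exposure {target_exposure!r}")
    t = data.exposure_ids.index(target_exposure)
    bx = np.atleast_2d(data.beta_x)
    sx = np.atleast_2d(data.se_x)
    k, m = bx.shape
    y = bx[:, t]
    x = np.delete(bx, t, axis=1)
    w = 1.0 / sx[:, t] ** 2
    xtwx = x.T @ (x * w[:, None])
    _check_conditioning(xtwx)
    coef = np.linalg.solve(xtwx, x.T @ (w * y))
    resid = y - x @ coef
    q = float(np.sum(w * resid**2))
    df = k - (m - 1)
    p = max(float(stats.chi2.sf(q, df)), _P_FLOOR)
    return q, p


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def _records(stats) -> list[VariantAssociation]:
    return stats.records if isinstance(stats, SummaryStats) else list(stats)


def _trait_of(stats, default: str) -> str:
    if isinstance(stats, SummaryStats):
        return stats.meta.trait_id
    recs = _records(stats)
    return recs[0].trait_id or default if recs else default


def build_mvmr_dataset(
    exposure_stats: Mapping[str, object] | Sequence[object],
    outcome_stats,
    ld: LDSource | None = None,
    af_window: tuple[float, float] = (0.4, 0.6),
    *,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
    palindrome_filter: bool = True,
) -> HarmonizedDataset:
    """Assemble a multi-exposure harmonized dataset for multivariable MR.

    Takes the union of variants reaching ``p_threshold`` in at least one
    exposure, keeps those present in every exposure table and the outcome
    (absences are logged), clumps the union greedily ranking by the best
    p-value across exposures, aligns all tables to the first exposure's
    effect allele, and applies the palindromic-frequency exclusion.
    """
    if isinstance(exposure_stats, Mapping):
        tables = list(exposure_stats.values())
        names = list(exposure_stats.keys())
    else:
        tables = list(exposure_stats)
        names = [_trait_of(t, f"exposure_{i+1}") for i, t in enumerate(tables)]
    if len(tables) < 2:
        raise ValueError("multivariable MR needs >= 2 exposures")

    maps = []
    for t in tables:
        m: dict[str, VariantAssociation] = {}
        for rec in _records(t):
            m.setdefault(rec.variant_id, rec)
        maps.append(m)
    y_map: dict[str, VariantAssociation] = {}
    for rec in _records(outcome_stats):
        y_map.setdefault(rec.variant_id, rec)
    outcome_id = _trait_of(outcome_stats, "outcome")

    log: Counter = Counter()
    union_ids: list[str] = []
    seen: set[str] = set()
    for m in maps:  # union in first-seen order, deduplicated
        for vid, rec in m.items():
            if vid in seen:
                continue
            seen.add(vid)
            if rec.pvalue < p_threshold or any(
                vid in mm and mm[vid].pvalue < p_threshold for mm in maps
            ):
                union_ids.append(vid)

    candidates: list[VariantAssociation] = []
    for vid in union_ids:
        if any(vid not in mm for mm in maps):
            log["absent_from_exposure"] += 1
            continue
        if vid not in y_map:
            log["absent_from_outcome"] += 1
            continue
        ref = maps[0][vid]
        best_p = min(mm[vid].pvalue for mm in maps)
        # rank the greedy pass by the best association across exposures
        candidates.append(
            VariantAssociation(
                variant_id=vid,
                effect_allele=ref.effect_allele,
                other_allele=ref.other_allele,
                beta=ref.beta,
                se=ref.se,
                pvalue=best_p,
                chrom=ref.chrom,
                pos=ref.pos,
                eaf=ref.eaf,
                trait_id=ref.trait_id,
            )
        )

    clumped = ld_clump(candidates, ld, r2_threshold, window_bp)

    variants: list[HarmonizedVariant] = []
    for v in clumped.variants:
        ref = maps[0][v.variant_id]
        y = y_map[v.variant_id]
        hy = harmonize_pair(ref, y, af_window, palindrome_filter=palindrome_filter)
        if not hy.retained:
            log[hy.status] += 1
            variants.append(hy)
            continue
        betas = [ref.beta]
        ses = [ref.se]
        dropped = False
        for mm in maps[1:]:
            he = harmonize_pair(ref, mm[v.variant_id], af_window,
                                palindrome_filter=palindrome_filter)
            if not he.retained:
                log[he.status] += 1
                variants.append(HarmonizedVariant(variant_id=v.variant_id, status=he.status))
                dropped = True
                break
            betas.append(he.beta_y)  # the "outcome" slot holds the aligned exposure beta
            ses.append(he.se_y)
        if dropped:
            continue
        variants.append(
            HarmonizedVariant(
                variant_id=v.variant_id,
                status=hy.status,
                beta_x=tuple(betas),
                se_x=tuple(ses),
                beta_y=hy.beta_y,
                se_y=hy.se_y,
                eaf=ref.eaf,
            )
        )

    if not any(v.retained for v in variants):
        raise ValueError("no variants survived multivariable harmonization")
    return HarmonizedDataset(
        exposure_ids=tuple(names),
        outcome_id=outcome_id,
        variants=variants,
        exclusion_log=log,
    )
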