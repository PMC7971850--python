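"""Orchestration of a many-exposure × several-outcome MR screen.

For every (exposure, outcome) pair the screen runs the full chain —
significance filtering, LD + distance clumping, allele harmonization,
random-effects IVW as the primary estimator, then the requested sensitivity
battery (MR-Egger, weighted median, mode-based, leave-one-out, optionally
MR-PRESSO).  Significance is declared only on the primary IVW p-value
against a Bonferroni threshold of alpha / (exposures × outcomes);
sensitivity methods contribute a direction-concordance indicator, never the
significance flag.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, cochran_q, egger, ivw, leave_one_out, mode_based, weighted_median
from .harmonize import harmonize_dataset
from .instruments import (
    DEFAULT_P_THRESHOLD,
    DEFAULT_R2_THRESHOLD,
    DEFAULT_WINDOW_BP,
    ld_clump,
    select_candidates,
)
from .io import SummaryStats
from .ld import LDSource
from .presso import run_presso
from .simulate import effective_sample_size

__all__ = [
    "BonferroniThreshold",
    "ScreenResult",
    "bonferroni_threshold",
    "run_screen",
    "detectable_or",
]


@dataclass(frozen=True)
class BonferroniThreshold:
    """A multiple-testing threshold, exact and as conventionally displayed."""

    exact: float
    display: str
    n_tests: int

    def __float__(self) -> float:
        return self.exact


def _display_round(value: float) -> str:
    """Shortest 1–2 significant-digit decimal within 5% relative error.

    Printed thresholds in the MR literature are quoted with the fewest
    digits that still identify the value (0.05/34 → "0.0015", 0.05/8 →
    "0.006"); this reproduces that convention deterministically.
    """
    for digits in (1, 2):
        rounded = float(f"%.{digits}g" % value)
        if value != 0 and abs(rounded - value) / abs(value) <= 0.05:
            return f"%.{digits}g" % value
    return "%.2g" % value


def bonferroni_threshold(
    n_exposures: int, n_outcomes: int, alpha: float = 0.05
) -> BonferroniThreshold:
    """alpha / (n_exposures × n_outcomes), with its conventional display string."""
    if n_exposures <= 0 or n_outcomes <= 0:
        raise ValueError("exposure and outcome counts must be positive")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    n_tests = n_exposures * n_outcomes
    exact = alpha / n_tests
    return BonferroniThreshold(exact=exact, display=_display_round(exact), n_tests=n_tests)


@dataclass
class ScreenResult:
    """Long-format per-method rows plus the declaration rule and run metadata."""

    rows: pd.DataFrame
    bonferroni: BonferroniThreshold
    failures: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def primary(self) -> pd.DataFrame:
        """One row per (exposure, outcome): the random-effects IVW estimate."""
        return self.rows[self.rows["method"] == "ivw_random"].reset_index(drop=True)

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        prim = self.primary
        hits = prim[prim["significant"]]
        return list(zip(hits["exposure"], hits["outcome"]))

    def to_frame(self) -> pd.DataFrame:
        return self.rows


def _pair_seed(seed: int, exposure: str, outcome: str) -> int:
    """Stable per-pair seed below 2^31, independent of pair iteration order."""
    digest = hashlib.sha256(f"{seed}:{exposure}:{outcome}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_screen(
    exposures: Mapping[str, SummaryStats] | Sequence[SummaryStats],
    outcomes: Mapping[str, SummaryStats] | Sequence[SummaryStats],
    *,
    methods: Iterable[str] = ("ivw_random", "egger", "weighted_median", "mode_based"),
    ld: LDSource | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
    af_window: tuple[float, float] = (0.4, 0.6),
    alpha: float = 0.05,
    seed: int = 0,
    n_boot: int = 1000,
    include_presso: bool = False,
    presso_n_sim: int = 1000,
    loo_flag_se_multiple: float = 1.0,
) -> ScreenResult:
    """Run the full screen over every exposure × outcome pair.

    Pairs that cannot be analysed (no instruments, no shared variants) are
    recorded in ``failures`` and the screen continues.  All stochastic steps
    derive per-pair seeds from ``seed`` so the result is reproducible and
    independent of iteration order.
    """

    def as_map(tables) -> dict[str, SummaryStats]:
        if isinstance(tables, Mapping):
            return dict(tables)
        return {t.meta.trait_id: t for t in tables}

    exp_map = as_map(exposures)
    out_map = as_map(outcomes)
    methods = list(methods)
    bonf = bonferroni_threshold(len(exp_map), len(out_map), alpha)

    rows: list[dict] = []
    failures: list[dict] = []
    for exp_id, exp_stats in exp_map.items():
        candidates = select_candidates(exp_stats.records, p_threshold)
        for out_id, out_stats in out_map.items():
            pair_seed = _pair_seed(seed, exp_id, out_id)
            try:
                instruments = ld_clump(
                    candidates, ld, r2_threshold, window_bp,
                    trait_meta=exp_stats.meta, p_threshold=p_threshold,
                )
                if len(instruments) == 0:
                    raise ValueError("no instruments passed selection")
                data = harmonize_dataset(instruments.variants, out_stats, af_window)
                if data.n_retained == 0:
                    raise ValueError("no variants survived harmonization")
                estimates: dict[str, MREstimate] = {}
                estimates["ivw_random"] = ivw(data, "random")
                for method in methods:
                    if method in ("ivw_random", "ivw"):
                        continue
                    elif method == "ivw_fixed":
                        estimates[method] = ivw(data, "fixed")
                    elif method == "egger" and data.n_retained >= 3:
                        estimates[method] = egger(data)
                    elif method == "weighted_median" and data.n_retained >= 3:
                        estimates[method] = weighted_median(data, n_boot, pair_seed)
                    elif method == "mode_based" and data.n_retained >= 3:
                        estimates[method] = mode_based(data, 1.0, n_boot, pair_seed + 1)
                loo_flags = 0
                if data.n_retained >= 3:
                    loo = leave_one_out(data, "random", loo_flag_se_multiple)
                    loo_flags = sum(e.flagged for e in loo)
                presso_global_p = None
                presso_outliers = None
                if include_presso and data.n_retained >= 4:
                    pres = run_presso(data, presso_n_sim, seed=pair_seed + 2)
                    presso_global_p = pres.global_pvalue
                    presso_outliers = len(pres.outlier_ids)
            except ValueError as exc:
                failures.append({"exposure": exp_id, "outcome": out_id, "reason": str(exc)})
                continue

            betas = [est.beta for est in estimates.values()]
            concordant = bool(np.all(np.sign(betas) == np.sign(betas[0])))
            for method, est in estimates.items():
                rows.append(
                    {
                        "exposure": exp_id,
                        "outcome": out_id,
                        "method": method,
                        "beta": est.beta,
                        "se": est.se,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "odds_ratio": est.odds_ratio,
                        "pvalue": est.pvalue,
                        "n_variants": est.n_variants,
                        "q": est.q,
                        "q_pvalue": est.q_pvalue,
                        "egger_intercept": est.intercept,
                        "egger_intercept_pvalue": est.intercept_pvalue,
                        "significant": bool(
                            method == "ivw_random" and est.pvalue < bonf.exact
                        ),
                        "direction_concordant": concordant,
                        "loo_flagged": loo_flags,
                        "presso_global_pvalue": presso_global_p,
                        "presso_n_outliers": presso_outliers,
                        "unit_label": exp_stats.meta.unit_label,
                        "pair_seed": pair_seed,
                    }
                )

    rows_df = pd.DataFrame(rows)
    config = {
        "p_threshold": p_threshold,
        "r2_threshold": r2_threshold,
        "window_bp": window_bp,
        "af_window": af_window,
        "alpha": alpha,
        "seed": seed,
        "methods": methods,
        "n_boot": n_boot,
        "include_presso": include_presso,
    }
    return ScreenResult(rows=rows_df, bonferroni=bonf, failures=failures, config=config)


def detectable_or(
    r2_explained: float,
    n_case: int,
    n_control: int,
    alpha: float = 0.05,
    power: float = 0.8,
) -> float:
    """Smallest detectable causal odds ratio per SD of the exposure.

    Normal-approximation power for binary-outcome 2-sample MR: the IVW
    estimate of the log odds ratio per exposure SD has sampling variance
    ≈ 1 / (n_eff · R²), where R² is the variance of the exposure explained
    by the instruments and n_eff = 4/(1/n_case + 1/n_control).  The smallest
    log OR detectable at two-sided level ``alpha`` with the given power is
    (z_{1−α/2} + z_power) / sqrt(n_eff · R²).  Monotone decreasing in R²
    and in both sample sizes; approaches OR = 1 as information grows.
    """
    if not 0 < r2_explained < 1:
        raise ValueError(f"r2_explained must be in (0, 1), got {r2_explained}")
    if n_case <= 0 or n_control <= 0:
        raise ValueError("n_case and n_control must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not alpha < power < 1:
        raise ValueError("power must lie strictly between alpha and 1")
    n_eff = effective_sample_size(n_case, n_control)
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    log_or = z / np.sqrt(n_eff * r2_explained)
    return float(np.exp(log_or))
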