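"""Univariable two-sample MR estimators and heterogeneity diagnostics.

Given per-variant aligned effect pairs (β_Xj, se_Xj, β_Yj, se_Yj), the causal
effect θ of the exposure on the outcome is estimated by combining the
per-variant Wald ratios θ_j = β_Yj/β_Xj:

* IVW — weighted regression of β_Y on β_X through the origin with weights
  1/se_Y²; the primary estimator.  The random-effects variant inflates the
  standard error by the multiplicative overdispersion factor
  max(1, sqrt(Q/(k−1))).
* MR-Egger — same regression with a free intercept; the intercept is a test
  for directional pleiotropy (valid under the InSIDE assumption), the slope
  a pleiotropy-corrected causal estimate.
* Weighted median — weighted 50% quantile of the Wald ratios; consistent
  when valid instruments carry ≥ 50% of the weight.
* Mode-based — argmax of a weighted kernel density over the Wald ratios;
  consistent when the largest cluster of similar ratios comes from valid
  instruments.

Estimators are scikit-learn style: parameters in ``__init__``, ``fit(data)``
on a :class:`~summr.harmonize.HarmonizedDataset`, fitted attributes with a
trailing underscore, and an :class:`MREstimate` record in ``estimate_``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .harmonize import HarmonizedDataset, HarmonizedVariant

__all__ = [
    "MREstimate",
    "IVW",
    "MREgger",
    "WeightedMedian",
    "ModeBased",
    "LeaveOneOutEntry",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_based",
    "cochran_q",
    "leave_one_out",
]

Z_95 = float(stats.norm.ppf(0.975))

_P_FLOOR = float(np.nextafter(0, 1))


def _two_sided_p(z: float) -> float:
    return max(2 * float(stats.norm.sf(abs(z))), _P_FLOOR)


@dataclass
class MREstimate:
    """A causal-effect estimate from one MR method.

    ``q``/``q_pvalue`` are Cochran heterogeneity diagnostics where defined;
    the intercept fields are present only for MR-Egger.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_variants: int
    q: float | None = None
    q_pvalue: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.method}: se must be > 0, got {self.se}")
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError(f"{self.method}: CI [{self.ci_low}, {self.ci_high}] excludes beta")
        if self.q is not None and self.q < -1e-12:
            raise ValueError(f"{self.method}: negative Q")
        has_intercept = self.intercept is not None
        if has_intercept != (self.method == "egger"):
            raise ValueError("intercept fields present iff method is egger")

    @property
    def odds_ratio(self) -> float:
        """exp(beta): the causal OR when the outcome is binary (log-odds scale)."""
        return float(np.exp(self.beta))

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_variants": self.n_variants,
            "q": self.q,
            "q_pvalue": self.q_pvalue,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_pvalue": self.intercept_pvalue,
        }
        out.update(self.metadata)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _check_data(data: HarmonizedDataset, min_variants: int, method: str) -> None:
    if data.n_exposures != 1:
        raise ValueError(f"{method} is univariable; got {data.n_exposures} exposures")
    k = data.n_retained
    if k < min_variants:
        raise ValueError(f"{method} requires >= {min_variants} variants, got {k}")


def _ratio_weights(data: HarmonizedDataset, second_order: bool) -> tuple[np.ndarray, np.ndarray]:
    """Wald ratios and their inverse-variance weights (first- or second-order delta)."""
    bx, by, sx, sy = data.beta_x, data.beta_y, data.se_x, data.se_y
    if np.any(bx == 0):
        raise ValueError("beta_x = 0 gives an undefined Wald ratio")
    ratios = by / bx
    var = sy**2 / bx**2
    if second_order:
        var = var + by**2 * sx**2 / bx**4
    return ratios, 1.0 / var


def wald_ratio(v: HarmonizedVariant) -> MREstimate:
    """Single-variant causal estimate β_Y/β_X with first-order delta-method se."""
    if not v.retained:
        raise ValueError(f"{v.variant_id}: variant was excluded during harmonization")
    bx = v.beta_x[0]
    if bx == 0:
        raise ValueError(f"{v.variant_id}: beta_x = 0 gives an undefined ratio")
    beta = v.beta_y / bx
    se = v.se_y / abs(bx)
    return MREstimate(
        method="wald",
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z_95 * se),
        ci_high=float(beta + Z_95 * se),
        pvalue=_two_sided_p(beta / se),
        n_variants=1,
        metadata={"variant_id": v.variant_id},
    )


def cochran_q(data: HarmonizedDataset, beta_hat: float) -> tuple[float, float]:
    """Cochran heterogeneity statistic of the Wald ratios around ``beta_hat``.

    Q = Σ w_j (θ_j − beta_hat)² with first-order inverse-variance weights;
    the p-value is from chi-square with k − 1 degrees of freedom.
    """
    _check_data(data, 2, "cochran_q")
    ratios, weights = _ratio_weights(data, second_order=False)
    q = float(np.sum(weights * (ratios - beta_hat) ** 2))
    p = float(stats.chi2.sf(q, data.n_retained - 1))
    return q, max(p, _P_FLOOR)


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------


class _BaseMREstimator(BaseEstimator):
    """Common fit plumbing: validates input, stores the MREstimate."""

    _method = "base"
    _min_variants = 2

    def fit(self, data: HarmonizedDataset) -> "_BaseMREstimator":
        _check_data(data, self._min_variants, self._method)
        self.estimate_ = self._fit(data)
        est = self.estimate_
        self.beta_ = est.beta
        self.se_ = est.se
        self.ci_ = (est.ci_low, est.ci_high)
        self.pvalue_ = est.pvalue
        self.n_variants_ = est.n_variants
        return self

    def _fit(self, data: HarmonizedDataset) -> MREstimate:  # pragma: no cover
        raise NotImplementedError


class IVW(_BaseMREstimator):
    """Inverse-variance-weighted estimator (weighted regression through the origin).

    Parameters
    ----------
    effects_model : {"random", "fixed"}
        ``"random"`` scales the fixed-effect standard error by the
        multiplicative overdispersion factor max(1, sqrt(Q/(k−1))); the
        factor never deflates (no underdispersion).
    """

    _method = "ivw"
    _min_variants = 1

    def __init__(self, effects_model: str = "random"):
        self.effects_model = effects_model

    def _fit(self, data: HarmonizedDataset) -> MREstimate:
        if self.effects_model not in ("fixed", "random"):
            raise ValueError(f"effects_model must be fixed or random, got {self.effects_model}")
        k = data.n_retained
        if k == 1:
            est = wald_ratio(data.retained[0])
            est.method = f"ivw_{self.effects_model}"
            est.intercept = None
            est.metadata["note"] = "single variant: IVW degrades to the Wald ratio"
            return est
        bx, by, sy = data.beta_x, data.beta_y, data.se_y
        w = 1.0 / sy**2
        denom = float(np.sum(w * bx**2))
        if denom == 0:
            raise ValueError("all beta_x are zero: degenerate instruments")
        beta = float(np.sum(w * bx * by)) / denom
        se_fixed = denom**-0.5
        q, q_p = cochran_q(data, beta)
        phi = max(1.0, np.sqrt(q / (k - 1)))
        se = se_fixed * phi if self.effects_model == "random" else se_fixed
        return MREstimate(
            method=f"ivw_{self.effects_model}",
            beta=beta,
            se=float(se),
            ci_low=float(beta - Z_95 * se),
            ci_high=float(beta + Z_95 * se),
            pvalue=_two_sided_p(beta / se),
            n_variants=k,
            q=q,
            q_pvalue=q_p,
            metadata={"se_fixed": float(se_fixed), "overdispersion": float(phi)},
        )


class MREgger(_BaseMREstimator):
    """MR-Egger regression: weighted regression of β_Y on β_X with a free intercept.

    Rows are oriented so every β_X is non-negative before fitting (the model
    is not equivariant to per-variant sign flips once the intercept is
    free).  Standard errors carry the multiplicative overdispersion factor
    max(1, sqrt(Q_egger/(k−2))); confidence intervals and p-values use the t
    distribution with k − 2 degrees of freedom (small-sample convention).
    """

    _method = "egger"
    _min_variants = 3

    def _fit(self, data: HarmonizedDataset) -> MREstimate:
        k = data.n_retained
        sign = np.where(data.beta_x < 0, -1.0, 1.0)
        bx = sign * data.beta_x
        by = sign * data.beta_y
        w = 1.0 / data.se_y**2
        design = np.column_stack([np.ones(k), bx])
        xtwx = design.T @ (design * w[:, None])
        try:
            cov_unscaled = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as exc:
            raise ValueError("degenerate design: beta_x has no spread") from exc
        coef = cov_unscaled @ (design.T @ (w * by))
        resid = by - design @ coef
        q_egger = float(np.sum(w * resid**2))
        phi = max(1.0, np.sqrt(q_egger / (k - 2)))
        se_int, se_slope = np.sqrt(np.diag(cov_unscaled)) * phi
        t_crit = float(stats.t.ppf(0.975, k - 2))
        intercept, slope = float(coef[0]), float(coef[1])

        def t_p(est, se):
            return max(2 * float(stats.t.sf(abs(est / se), k - 2)), _P_FLOOR)

        return MREstimate(
            method="egger",
            beta=slope,
            se=float(se_slope),
            ci_low=slope - t_crit * se_slope,
            ci_high=slope + t_crit * se_slope,
            pvalue=t_p(slope, se_slope),
            n_variants=k,
            q=q_egger,
            q_pvalue=max(float(stats.chi2.sf(q_egger, k - 2)), _P_FLOOR),
            intercept=intercept,
            intercept_se=float(se_int),
            intercept_pvalue=t_p(intercept, se_int),
            metadata={"overdispersion": float(phi)},
        )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50% quantile with mid-point interpolation."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / np.sum(w)
    return float(np.interp(0.5, cum, r))


class _BootstrapMixin:
    def _bootstrap_se(self, data: HarmonizedDataset, point_fn, n_boot: int, seed: int) -> float:
        """Parametric bootstrap: redraw (β_X, β_Y) from normals at the observed values."""
        rng = np.random.default_rng(seed)
        bx, by = data.beta_x, data.beta_y
        sx, sy = data.se_x, data.se_y
        k = len(bx)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bx_b = rng.normal(bx, sx)
            by_b = rng.normal(by, sy)
            bad = bx_b == 0
            if np.any(bad):  # probability ~0; keep ratios defined
                bx_b[bad] = np.finfo(float).tiny
            boots[b] = point_fn(bx_b, by_b, sx, sy)
        return float(np.std(boots, ddof=1))


class WeightedMedian(_BaseMREstimator, _BootstrapMixin):
    """Weighted median of the Wald ratios.

    Consistent when valid instruments contribute at least half of the total
    inverse-variance weight.  The standard error comes from a seeded
    parametric bootstrap (``n_boot`` redraws of the per-variant effects).
    """

    _method = "weighted_median"
    _min_variants = 3

    def __init__(self, n_boot: int = 1000, random_state: int | None = None,
                 second_order_weights: bool = False):
        self.n_boot = n_boot
        self.random_state = random_state
        self.second_order_weights = second_order_weights

    def _fit(self, data: HarmonizedDataset) -> MREstimate:
        if self.random_state is None:
            raise ValueError("WeightedMedian is stochastic: random_state must be set")
        ratios, weights = _ratio_weights(data, self.second_order_weights)
        beta = _weighted_median(ratios, weights)

        so = self.second_order_weights

        def point(bx, by, sx, sy):
            var = sy**2 / bx**2
            if so:
                var = var + by**2 * sx**2 / bx**4
            return _weighted_median(by / bx, 1.0 / var)

        se = self._bootstrap_se(data, point, self.n_boot, self.random_state)
        return MREstimate(
            method="weighted_median",
            beta=beta,
            se=se,
            ci_low=beta - Z_95 * se,
            ci_high=beta + Z_95 * se,
            pvalue=_two_sided_p(beta / se),
            n_variants=data.n_retained,
            metadata={"n_boot": self.n_boot, "seed": self.random_state,
                      "second_order_weights": so},
        )


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float,
                n_grid: int = 2001) -> tuple[float, float]:
    """Argmax of the weighted Gaussian KDE over the ratios; returns (mode, bandwidth)."""
    if np.ptp(ratios) == 0:
        return float(ratios[0]), 0.0
    mad = np.median(np.abs(ratios - np.median(ratios)))
    scale = 1.4826 * mad
    if scale == 0:
        scale = float(np.std(ratios))
    h = bandwidth_factor * scale
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)
    wn = weights / np.sum(weights)
    dens = np.sum(wn[None, :] * stats.norm.pdf((grid[:, None] - ratios[None, :]) / h), axis=1)
    return float(grid[int(np.argmax(dens))]), float(h)


class ModeBased(_BaseMREstimator, _BootstrapMixin):
    """Mode of the smoothed distribution of Wald ratios.

    A weighted Gaussian kernel density is evaluated over the ratios with
    bandwidth = ``bandwidth_factor`` × 1.4826·MAD(ratios); the estimate is
    the argmax located on a 2,001-point grid spanning the ratios ± 3
    bandwidths.  Consistent when the largest cluster of similar per-variant
    estimates comes from valid instruments, even if they are a minority.
    """

    _method = "mode_based"
    _min_variants = 3

    def __init__(self, bandwidth_factor: float = 1.0, n_boot: int = 1000,
                 random_state: int | None = None, second_order_weights: bool = False):
        self.bandwidth_factor = bandwidth_factor
        self.n_boot = n_boot
        self.random_state = random_state
        self.second_order_weights = second_order_weights

    def _fit(self, data: HarmonizedDataset) -> MREstimate:
        if self.random_state is None:
            raise ValueError("ModeBased is stochastic: random_state must be set")
        ratios, weights = _ratio_weights(data, self.second_order_weights)
        beta, bandwidth = _mode_point(ratios, weights, self.bandwidth_factor)

        so = self.second_order_weights
        bf = self.bandwidth_factor

        def point(bx, by, sx, sy):
            var = sy**2 / bx**2
            if so:
                var = var + by**2 * sx**2 / bx**4
            return _mode_point(by / bx, 1.0 / var, bf)[0]

        se = self._bootstrap_se(data, point, self.n_boot, self.random_state)
        return MREstimate(
            method="mode_based",
            beta=beta,
            se=se,
            ci_low=beta - Z_95 * se,
            ci_high=beta + Z_95 * se,
            pvalue=_two_sided_p(beta / se),
            n_variants=data.n_retained,
            metadata={"n_boot": self.n_boot, "seed": self.random_state,
                      "bandwidth": bandwidth, "bandwidth_factor": bf,
                      "second_order_weights": so},
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def ivw(data: HarmonizedDataset, effects_model: str = "random") -> MREstimate:
    """Inverse-variance-weighted causal estimate; see :class:`IVW`."""
    return IVW(effects_model=effects_model).fit(data).estimate_


def egger(data: HarmonizedDataset) -> MREstimate:
    """MR-Egger slope and directional-pleiotropy intercept; see :class:`MREgger`."""
    return MREgger().fit(data).estimate_


def weighted_median(data: HarmonizedDataset, n_boot: int = 1000, seed: int | None = None,
                    second_order_weights: bool = False) -> MREstimate:
    """Weighted-median causal estimate; see :class:`WeightedMedian`."""
    est = WeightedMedian(n_boot=n_boot, random_state=seed,
                         second_order_weights=second_order_weights)
    return est.fit(data).estimate_


def mode_based(data: HarmonizedDataset, bandwidth_factor: float = 1.0, n_boot: int = 1000,
               seed: int | None = None, second_order_weights: bool = False) -> MREstimate:
    """Mode-based causal estimate; see :class:`ModeBased`."""
    est = ModeBased(bandwidth_factor=bandwidth_factor, n_boot=n_boot, random_state=seed,
                    second_order_weights=second_order_weights)
    return est.fit(data).estimate_


@dataclass
class LeaveOneOutEntry:
    """Refit with one variant dropped, plus how far the estimate moved."""

    variant_id: str
    estimate: MREstimate
    shift: float
    flagged: bool

    def to_dict(self) -> dict:
        out = {"dropped_variant": self.variant_id, "shift": self.shift, "flagged": self.flagged}
        out.update(self.estimate.to_dict())
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def leave_one_out(
    data: HarmonizedDataset,
    effects_model: str = "random",
    flag_se_multiple: float = 1.0,
) -> list[LeaveOneOutEntry]:
    """Refit IVW k times, omitting each variant in turn.

    A variant is flagged when its omission moves the point estimate by more
    than ``flag_se_multiple`` × the full-data standard error — evidence that
    a single variant is driving the pooled estimate.
    """
    _check_data(data, 3, "leave_one_out")
    full = ivw(data, effects_model)
    retained = data.retained
    out = []
    for j, v in enumerate(retained):
        sub = HarmonizedDataset(
            exposure_ids=data.exposure_ids,
            outcome_id=data.outcome_id,
            variants=[u for i, u in enumerate(retained) if i != j],
        )
        est = ivw(sub, effects_model)
        shift = abs(est.beta - full.beta)
        out.append(
            LeaveOneOutEntry(
                variant_id=v.variant_id,
                estimate=est,
                shift=float(shift),
                flagged=bool(shift > flag_se_multiple * full.se),
            )
        )
    return out
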