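"""Allele harmonization between exposure and outcome summary statistics.

The two GWASs may report effects for opposite alleles or on opposite DNA
strands.  Harmonization aligns every shared variant to the exposure's effect
allele, negating the outcome beta where the labels are swapped, and drops
variants that cannot be aligned: strand-ambiguous palindromic pairs (A/T,
C/G) whose allele frequency is too close to 0.5 to resolve the strand, and
variants whose alleles are irreconcilable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SummaryStats, VariantAssociation

__all__ = [
    "HarmonizedVariant",
    "HarmonizedDataset",
    "harmonize_pair",
    "harmonize_dataset",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STATUS_ALIGNED = "aligned"
STATUS_FLIPPED = "flipped"
STATUS_PALINDROMIC = "excluded_palindromic"
STATUS_MISMATCH = "excluded_mismatch"
RETAINED_STATUSES = (STATUS_ALIGNED, STATUS_FLIPPED)


def _complement(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


def _is_snv(a: str, b: str) -> bool:
    return len(a) == 1 and len(b) == 1


def _is_palindromic_pair(a: str, b: str) -> bool:
    return {a, b} == {"A", "T"} or {a, b} == {"C", "G"}


@dataclass
class HarmonizedVariant:
    """One variant's aligned exposure/outcome effect pair.

    For multi-exposure datasets ``beta_x``/``se_x`` hold one value per
    exposure.  Excluded variants carry no effect fields, only a status.
    """

    variant_id: str
    status: str
    beta_x: tuple[float, ...] | None = None
    se_x: tuple[float, ...] | None = None
    beta_y: float | None = None
    se_y: float | None = None
    eaf: float | None = None

    @property
    def retained(self) -> bool:
        return self.status in RETAINED_STATUSES


@dataclass
class HarmonizedDataset:
    """Per-variant aligned effect pairs for one (or several) exposures and one outcome."""

    exposure_ids: tuple[str, ...]
    outcome_id: str
    variants: list[HarmonizedVariant]
    exclusion_log: Counter = field(default_factory=Counter)

    def __post_init__(self):
        ids = [v.variant_id for v in self.variants]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate variant_id in harmonized dataset")

    # -- array views over the retained variants ------------------------------
    @property
    def retained(self) -> list[HarmonizedVariant]:
        return [v for v in self.variants if v.retained]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_ids)

    @property
    def variant_ids(self) -> np.ndarray:
        return np.array([v.variant_id for v in self.retained])

    @property
    def beta_x(self) -> np.ndarray:
        """(k,) for a single exposure, (k, m) for m exposures."""
        arr = np.array([v.beta_x for v in self.retained], dtype=float)
        return arr[:, 0] if self.n_exposures == 1 else arr

    @property
    def se_x(self) -> np.ndarray:
        arr = np.array([v.se_x for v in self.retained], dtype=float)
        return arr[:, 0] if self.n_exposures == 1 else arr

    @property
    def beta_y(self) -> np.ndarray:
        return np.array([v.beta_y for v in self.retained], dtype=float)

    @property
    def se_y(self) -> np.ndarray:
        return np.array([v.se_y for v in self.retained], dtype=float)

    def subset(self, keep_ids: Iterable[str]) -> "HarmonizedDataset":
        """Retained variants restricted to ``keep_ids`` (order preserved)."""
        keep = set(keep_ids)
        return HarmonizedDataset(
            exposure_ids=self.exposure_ids,
            outcome_id=self.outcome_id,
            variants=[v for v in self.retained if v.variant_id in keep],
            exclusion_log=Counter(),
        )

    @classmethod
    def from_arrays(
        cls,
        beta_x: np.ndarray,
        se_x: np.ndarray,
        beta_y: np.ndarray,
        se_y: np.ndarray,
        variant_ids: Sequence[str] | None = None,
        exposure_ids: tuple[str, ...] = ("exposure",),
        outcome_id: str = "outcome",
        eaf: np.ndarray | None = None,
    ) -> "HarmonizedDataset":
        """Build an already-aligned dataset directly from effect arrays."""
        beta_x = np.atleast_1d(np.asarray(beta_x, dtype=float))
        se_x = np.atleast_1d(np.asarray(se_x, dtype=float))
        if beta_x.ndim == 1:
            beta_x = beta_x[:, None]
            se_x = se_x[:, None]
        k, m = beta_x.shape
        if len(exposure_ids) != m:
            exposure_ids = tuple(f"exposure_{i+1}" for i in range(m))
        if variant_ids is None:
            variant_ids = [f"rs{i+1}" for i in range(k)]
        variants = [
            HarmonizedVariant(
                variant_id=str(variant_ids[j]),
                status=STATUS_ALIGNED,
                beta_x=tuple(beta_x[j]),
                se_x=tuple(se_x[j]),
                beta_y=float(beta_y[j]),
                se_y=float(se_y[j]),
                eaf=None if eaf is None else float(eaf[j]),
            )
            for j in range(k)
        ]
        return cls(exposure_ids=exposure_ids, outcome_id=outcome_id, variants=variants)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.variants:
            row = {"variant_id": v.variant_id, "status": v.status, "eaf": v.eaf}
            for i, trait in enumerate(self.exposure_ids):
                row[f"beta_x.{trait}"] = None if v.beta_x is None else v.beta_x[i]
                row[f"se_x.{trait}"] = None if v.se_x is None else v.se_x[i]
            row["beta_y"] = v.beta_y
            row["se_y"] = v.se_y
            rows.append(row)
        return pd.DataFrame(rows)


def _orientation(x: VariantAssociation, y: VariantAssociation) -> str | None:
    """How y's allele labels relate to x's: 'same', 'swapped', or None.

    Strand flips (complemented alleles) are tried only for non-palindromic
    single-nucleotide pairs; indels are compared as exact strings.
    """
    xa, xo, ya, yo = x.effect_allele, x.other_allele, y.effect_allele, y.other_allele
    if (ya, yo) == (xa, xo):
        return "same"
    if (ya, yo) == (xo, xa):
        return "swapped"
    if _is_snv(ya, yo) and _is_snv(xa, xo) and not _is_palindromic_pair(ya, yo):
        ca, co = _complement(ya), _complement(yo)
        if (ca, co) == (xa, xo):
            return "same"
        if (ca, co) == (xo, xa):
            return "swapped"
    return None


def harmonize_pair(
    x: VariantAssociation,
    y: VariantAssociation,
    af_window: tuple[float, float] = (0.4, 0.6),
    *,
    palindrome_filter: bool = True,
) -> HarmonizedVariant:
    """Align one outcome record to the exposure record's effect allele.

    Matching labels keep the outcome beta (``aligned``); swapped labels
    negate it (``flipped``).  Palindromic pairs are resolved by comparing
    which side of 0.5 each dataset's allele frequency falls on, and are
    excluded when either frequency lies inside ``af_window`` (or is missing);
    irreconcilable alleles are excluded as mismatches.
    """
    if x.variant_id != y.variant_id:
        raise ValueError(f"variant_id mismatch: {x.variant_id} vs {y.variant_id}")
    lo, hi = af_window
    if not 0 <= lo <= hi <= 1:
        raise ValueError(f"invalid af_window {af_window}")

    def excluded(status: str) -> HarmonizedVariant:
        return HarmonizedVariant(variant_id=x.variant_id, status=status)

    orient = _orientation(x, y)
    if orient is None:
        return excluded(STATUS_MISMATCH)
    sign = 1.0 if orient == "same" else -1.0
    y_eaf_for_x_allele = None
    if y.eaf is not None:
        y_eaf_for_x_allele = y.eaf if orient == "same" else 1 - y.eaf

    if _is_palindromic_pair(x.effect_allele, x.other_allele):
        if palindrome_filter:
            if x.eaf is None or y.eaf is None:
                # strand unresolvable without both frequencies: conservative drop
                return excluded(STATUS_PALINDROMIC)
            if lo <= x.eaf <= hi or lo <= y.eaf <= hi:
                return excluded(STATUS_PALINDROMIC)
            # label match is strand-ambiguous; trust the frequencies instead
            if (x.eaf - 0.5) * (y_eaf_for_x_allele - 0.5) < 0:
                sign = -sign
        elif x.eaf is not None and y_eaf_for_x_allele is not None:
            if (x.eaf - 0.5) * (y_eaf_for_x_allele - 0.5) < 0:
                sign = -sign

    return HarmonizedVariant(
        variant_id=x.variant_id,
        status=STATUS_ALIGNED if sign > 0 else STATUS_FLIPPED,
        beta_x=(x.beta,),
        se_x=(x.se,),
        beta_y=sign * y.beta,
        se_y=y.se,
        eaf=x.eaf,
    )


def _records(stats) -> list[VariantAssociation]:
    if isinstance(stats, SummaryStats):
        return stats.records
    return list(stats)


def _trait_id(stats, default: str) -> str:
    if isinstance(stats, SummaryStats):
        return stats.meta.trait_id
    recs = _records(stats)
    return recs[0].trait_id or default if recs else default


def harmonize_dataset(
    exposure_stats,
    outcome_stats,
    af_window: tuple[float, float] = (0.4, 0.6),
    *,
    palindrome_filter: bool = True,
) -> HarmonizedDataset:
    """Intersect exposure and outcome tables on variant_id and align each pair.

    Exposure input order is preserved.  The exclusion log counts variants
    absent from the outcome table, palindromic exclusions and allele
    mismatches; retained + excluded-by-harmonization = shared variants.
    """
    x_records = _records(exposure_stats)
    y_map: dict[str, VariantAssociation] = {}
    for rec in _records(outcome_stats):
        y_map.setdefault(rec.variant_id, rec)

    log: Counter = Counter()
    variants: list[HarmonizedVariant] = []
    seen: set[str] = set()
    for x in x_records:
        if x.variant_id in seen:
            log["duplicate_exposure_record"] += 1
            continue
        seen.add(x.variant_id)
        y = y_map.get(x.variant_id)
        if y is None:
            log["absent_from_outcome"] += 1
            continue
        hv = harmonize_pair(x, y, af_window, palindrome_filter=palindrome_filter)
        variants.append(hv)
        if not hv.retained:
            log[hv.status] += 1
    if not variants:
        raise ValueError(
            "no shared variants between exposure and outcome summary statistics"
        )
    return HarmonizedDataset(
        exposure_ids=(_trait_id(exposure_stats, "exposure"),),
        outcome_id=_trait_id(outcome_stats, "outcome"),
        variants=variants,
        exclusion_log=log,
    )
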