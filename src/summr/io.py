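"""Reading, validating and writing GWAS summary statistics and MR results.

Summary statistics arrive as delimited text with one row per variant.  Column
headers differ between consortia, so reading goes through a :class:`Dialect`
that maps canonical field names onto the file's headers.  Every row is
validated against the :class:`VariantAssociation` invariants; offending rows
are reported with their line numbers rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "TraitMeta",
    "Dialect",
    "SummaryStats",
    "RowError",
    "DialectError",
    "ValidationError",
    "read_summary_stats",
    "write_results",
    "records_to_frame",
    "frame_to_records",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: canonical field order used for tabular output
CANONICAL_FIELDS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "n_case",
    "n_control",
)

_REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")


class DialectError(ValueError):
    """A column mapping does not cover a required field."""


class ValidationError(ValueError):
    """A record violates a summary-statistic invariant."""


@dataclass
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the additive effect of ``effect_allele`` on the trait (per
    unit for continuous traits, log-odds for binary traits); ``eaf`` is the
    effect-allele frequency.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None
    n_case: int | None = None
    n_control: int | None = None
    trait_id: str = ""

    def validate(self) -> "VariantAssociation":
        """Check the record invariants, raising :class:`ValidationError`."""
        if not self.variant_id:
            raise ValidationError("variant_id must be a non-empty string")
        for name in ("effect_allele", "other_allele"):
            allele = getattr(self, name)
            if not allele or not _ALLELE_RE.match(str(allele)):
                raise ValidationError(
                    f"{self.variant_id}: {name} {allele!r} is not a non-empty A/C/G/T string"
                )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: effect_allele equals other_allele")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"{self.variant_id}: pvalue must be in (0, 1], got {self.pvalue}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.variant_id}: beta must be finite")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.variant_id}: eaf must be in [0, 1], got {self.eaf}")
        if (
            self.n is not None
            and self.n_case is not None
            and self.n_control is not None
            and self.n_case + self.n_control != self.n
        ):
            raise ValidationError(
                f"{self.variant_id}: n_case + n_control != n "
                f"({self.n_case} + {self.n_control} != {self.n})"
            )
        return self

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous A/T or C/G single-nucleotide pairs."""
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass
class TraitMeta:
    """Trait-level metadata carried alongside a summary-statistic table."""

    trait_id: str
    trait_type: str = "continuous"  # continuous | binary
    unit_label: str = ""
    n: int | None = None
    n_case: int | None = None
    n_control: int | None = None

    def validate(self) -> "TraitMeta":
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(f"trait_type must be continuous or binary, got {self.trait_type}")
        if self.trait_type == "binary" and (self.n_case is None or self.n_control is None):
            raise ValidationError(f"{self.trait_id}: binary traits must carry n_case and n_control")
        return self

    @property
    def case_fraction(self) -> float | None:
        if self.n_case is None or self.n_control is None:
            return None
        return self.n_case / (self.n_case + self.n_control)


@dataclass(frozen=True)
class Dialect:
    """Column mapping from canonical field names to a file's headers.

    ``columns`` maps canonical names (see :data:`CANONICAL_FIELDS`) to the
    header used in the file.  Unmapped canonical names default to themselves,
    so ``Dialect()`` reads a canonically-headed file unchanged.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    sep: str = "\t"

    def resolve(self, header: Sequence[str]) -> dict[str, str]:
        """Return canonical -> file-column for every available field.

        Raises :class:`DialectError` naming the first required canonical
        field with no matching column.
        """
        resolved: dict[str, str] = {}
        for canon in CANONICAL_FIELDS:
            col = self.columns.get(canon, canon)
            if col in header:
                resolved[canon] = col
        for canon in _REQUIRED_FIELDS:
            if canon not in resolved:
                raise DialectError(
                    f"required column for field {canon!r} "
                    f"(mapped to {self.columns.get(canon, canon)!r}) not found in header"
                )
        return resolved


@dataclass
class RowError:
    """A validation failure for one input row."""

    line: int
    message: str


@dataclass
class SummaryStats:
    """A validated summary-statistic table: records, trait metadata, row errors."""

    records: list[VariantAssociation]
    meta: TraitMeta
    errors: list[RowError] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def _opt_float(value: Any) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_int(value: Any) -> int | None:
    out = _opt_float(value)
    return None if out is None else int(out)


def read_summary_stats(
    path: str | Path,
    dialect: Dialect | None = None,
    *,
    trait_id: str | None = None,
    trait_type: str = "continuous",
    unit_label: str = "",
    on_invalid: str = "log",
) -> SummaryStats:
    """Read a summary-statistic file into validated records.

    Parameters
    ----------
    path
        Delimited text file with one row per variant.
    dialect
        Column mapping; ``None`` means canonical headers, tab-separated.
    on_invalid
        ``"log"`` collects failing rows (with line numbers) into
        ``SummaryStats.errors``; ``"raise"`` aborts on the first failure.
    """
    if on_invalid not in ("log", "raise"):
        raise ValueError("on_invalid must be 'log' or 'raise'")
    dialect = dialect or Dialect()
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.sep)
    resolved = dialect.resolve(list(df.columns))
    trait_id = trait_id or path.stem

    records: list[VariantAssociation] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header line
        raw = dict(zip(df.columns, row))
        try:
            rec = VariantAssociation(
                variant_id=str(raw[resolved["variant_id"]]),
                effect_allele=str(raw[resolved["effect_allele"]]).upper(),
                other_allele=str(raw[resolved["other_allele"]]).upper(),
                beta=float(raw[resolved["beta"]]),
                se=float(raw[resolved["se"]]),
                pvalue=float(raw[resolved["pvalue"]]),
                chrom=str(raw[resolved["chrom"]]) if "chrom" in resolved else None,
                pos=_opt_int(raw[resolved["pos"]]) if "pos" in resolved else None,
                eaf=_opt_float(raw[resolved["eaf"]]) if "eaf" in resolved else None,
                n=_opt_int(raw[resolved["n"]]) if "n" in resolved else None,
                n_case=_opt_int(raw[resolved["n_case"]]) if "n_case" in resolved else None,
                n_control=_opt_int(raw[resolved["n_control"]]) if "n_control" in resolved else None,
                trait_id=trait_id,
            ).validate()
        except (ValidationError, TypeError, ValueError) as exc:
            if on_invalid == "raise":
                raise ValidationError(f"line {line}: {exc}") from exc
            errors.append(RowError(line=line, message=str(exc)))
            continue
        records.append(rec)

    n = records[0].n if records and records[0].n is not None else None
    n_case = records[0].n_case if records else None
    n_control = records[0].n_control if records else None
    meta = TraitMeta(
        trait_id=trait_id,
        trait_type=trait_type,
        unit_label=unit_label,
        n=n,
        n_case=n_case,
        n_control=n_control,
    )
    if trait_type == "binary":
        meta.validate()
    return SummaryStats(records=records, meta=meta, errors=errors)


def records_to_frame(records: Iterable[VariantAssociation]) -> pd.DataFrame:
    """Records -> canonical DataFrame (one column per canonical field)."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(CANONICAL_FIELDS) + ["trait_id"])
    return df


def frame_to_records(
    df: pd.DataFrame, trait_id: str = "", validate: bool = True
) -> list[VariantAssociation]:
    """Canonical DataFrame -> records; the inverse of :func:`records_to_frame`."""
    records = []
    for raw in df.to_dict("records"):
        rec = VariantAssociation(
            variant_id=str(raw["variant_id"]),
            effect_allele=str(raw["effect_allele"]),
            other_allele=str(raw["other_allele"]),
            beta=float(raw["beta"]),
            se=float(raw["se"]),
            pvalue=float(raw["pvalue"]),
            chrom=None if pd.isna(raw.get("chrom")) else str(raw.get("chrom")),
            pos=_opt_int(raw.get("pos")),
            eaf=_opt_float(raw.get("eaf")),
            n=_opt_int(raw.get("n")),
            n_case=_opt_int(raw.get("n_case")),
            n_control=_opt_int(raw.get("n_control")),
            trait_id=str(raw.get("trait_id") or trait_id),
        )
        if validate:
            rec.validate()
        records.append(rec)
    return records


def _to_jsonable(obj: Any) -> Any:
    if obj is None or isinstance(obj, (str, bool, int)):
        return obj
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _to_jsonable(float(obj))
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    return str(obj)


def _result_frame(results: Any) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    if hasattr(results, "to_frame"):
        return results.to_frame()
    if isinstance(results, (list, tuple)):
        if not results:
            return pd.DataFrame()
        if all(hasattr(item, "to_dict") for item in results):
            return pd.DataFrame([_to_jsonable(item.to_dict()) for item in results])
        return pd.concat(
            [_result_frame(item) for item in results], ignore_index=True
        )
    if hasattr(results, "to_dict"):
        return pd.DataFrame([_to_jsonable(results.to_dict())])
    return pd.DataFrame([_to_jsonable(results)])


def write_results(results: Any, path: str | Path, format: str = "tsv") -> Path:
    """Write any result object (or list of them) to ``path``.

    ``tsv`` goes through the object's ``to_frame``/``to_dict`` with floats at
    17 significant digits, so reading back reproduces every numeric field;
    ``json`` serializes ``to_dict`` (dataclasses handled automatically).
    """
    path = Path(path)
    if format == "tsv":
        df = _result_frame(results)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(_to_jsonable(results), fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
    return path
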