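"""Pairwise linkage-disequilibrium lookup used by the clumping step.

An :class:`LDSource` answers r²(a, b) queries.  It never computes LD from
genotypes; it wraps a precomputed table (long 3-column format or a square
matrix with a header of variant ids).  Pairs absent from the table are
treated as independent (r² = 0); callers can inspect ``missing_queries`` to
report how often that fallback fired.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["LDSource"]


class LDSource:
    """Symmetric r² lookup over variant-id pairs.

    Parameters
    ----------
    pairs
        Mapping ``(id_a, id_b) -> r2``.  Order of the ids in a key does not
        matter; values must lie in [0, 1].
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._table: dict[tuple[str, str], float] = {}
        self.missing_queries = 0
        for (a, b), r2 in (pairs or {}).items():
            self._set(a, b, r2)

    def _set(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not 0 <= r2 <= 1:
            raise ValueError(f"r2({a}, {b}) = {r2} outside [0, 1]")
        if a == b:
            if r2 != 1:
                raise ValueError(f"r2({a}, {a}) must be 1, got {r2}")
            return
        key = (a, b) if a < b else (b, a)
        existing = self._table.get(key)
        if existing is not None and not np.isclose(existing, r2):
            raise ValueError(f"conflicting r2 values for pair {key}: {existing} vs {r2}")
        self._table[key] = r2

    def r2(self, a: str, b: str) -> float:
        """r² between two variants; 1 on the diagonal, 0 for unknown pairs."""
        if a == b:
            return 1.0
        key = (a, b) if a < b else (b, a)
        value = self._table.get(key)
        if value is None:
            self.missing_queries += 1
            return 0.0
        return value

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return a == b or ((a, b) if a < b else (b, a)) in self._table

    def __len__(self) -> int:
        return len(self._table)

    @classmethod
    def from_table(cls, source: str | Path | pd.DataFrame, sep: str = "\t") -> "LDSource":
        """Long format: three columns ``id_a``, ``id_b``, ``r2`` (header optional names)."""
        df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=sep)
        if df.shape[1] < 3:
            raise ValueError("LD table needs 3 columns: id_a, id_b, r2")
        a_col, b_col, r_col = df.columns[:3]
        out = cls()
        for a, b, r2 in zip(df[a_col], df[b_col], df[r_col]):
            out._set(str(a), str(b), float(r2))
        return out

    @classmethod
    def from_matrix(cls, source: str | Path | pd.DataFrame, sep: str = "\t") -> "LDSource":
        """Square matrix with a header row of variant ids (row order matches)."""
        df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=sep)
        ids = [str(c) for c in df.columns]
        mat = df.to_numpy(dtype=float)
        if mat.shape != (len(ids), len(ids)):
            raise ValueError(f"LD matrix is {mat.shape}, expected square over {len(ids)} ids")
        if not np.allclose(mat, mat.T, atol=1e-12):
            raise ValueError("LD matrix is not symmetric")
        out = cls()
        for i, a in enumerate(ids):
            if not np.isclose(mat[i, i], 1.0):
                raise ValueError(f"diagonal r2 for {a} is {mat[i, i]}, expected 1")
            for j in range(i + 1, len(ids)):
                out._set(a, ids[j], mat[i, j])
        return out

    @classmethod
    def independent(cls) -> "LDSource":
        """An empty source: every pair is treated as unlinked."""
        return cls()
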