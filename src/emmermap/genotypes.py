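"""Genotype matrix container for recombinant inbred line (RIL) populations.

A RIL genotype matrix is lines x markers with four call codes:

* ``0`` — homozygous for the parent-1 allele
* ``2`` — homozygous for the parent-2 allele
* ``1`` — heterozygous (residual heterozygosity of single-seed descent)
* ``.`` — missing

Internally calls are stored as an ``int8`` array with ``-1`` for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
PARENT1 = 0
HET = 1
PARENT2 = 2

_CODE_TO_CHAR = {PARENT1: "0", HET: "1", PARENT2: "2", MISSING: "."}
_CHAR_TO_CODE = {v: k for k, v in _CODE_TO_CHAR.items()}


@dataclass
class GenotypeMatrix:
    """Rectangular matrix of RIL genotype calls.

    Parameters
    ----------
    calls
        ``(n_lines, n_markers)`` int8 array with values in {0, 1, 2, -1}.
    line_ids, marker_ids
        Row and column labels, unique within their axis.
    """

    calls: np.ndarray
    line_ids: list = field(default_factory=list)
    marker_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        n, m = self.calls.shape
        if n < 2 or m < 2:
            raise ValueError("a genotype matrix needs >=2 lines and >=2 markers")
        if not self.line_ids:
            self.line_ids = [f"RIL{i + 1}" for i in range(n)]
        if not self.marker_ids:
            self.marker_ids = [f"M{j + 1}" for j in range(m)]
        if len(self.line_ids) != n or len(self.marker_ids) != m:
            raise ValueError("label lengths do not match the call matrix")
        bad = ~np.isin(self.calls, [PARENT1, HET, PARENT2, MISSING])
        if bad.any():
            raise ValueError(f"invalid call codes at {np.argwhere(bad)[:5]}")

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_ids.index(marker_id)]

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        idx = [self.marker_ids.index(m) for m in marker_ids]
        return GenotypeMatrix(self.calls[:, idx].copy(), list(self.line_ids), list(marker_ids))

    def to_dataframe(self) -> pd.DataFrame:
        chars = np.vectorize(_CODE_TO_CHAR.get)(self.calls)
        return pd.DataFrame(chars, index=pd.Index(self.line_ids, name="line"),
                            columns=self.marker_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        arr = df.astype(str).to_numpy()
        try:
            calls = np.vectorize(_CHAR_TO_CODE.__getitem__)(arr).astype(np.int8)
        except KeyError as exc:
            raise ValueError(f"unknown genotype code {exc}") from None
        return cls(calls, list(df.index.astype(str)), list(df.columns.astype(str)))

    def write(self, path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "GenotypeMatrix":
        return cls.from_dataframe(pd.read_csv(path, sep=sep, index_col=0, dtype=str))
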