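"""Rectangular binary symptom panels (one measurement occasion each)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ising import Encoding


@dataclass
class BinaryPanel:
    """One occasion's n x p matrix of binary symptom responses.

    Values are stored as floats so that missing cells (NaN) injected for
    robustness testing can be represented; complete panels contain only the
    declared encoding alphabet ({-1, +1} or {0, 1}).
    """

    values: np.ndarray
    item_names: list[str]
    age: float
    wave_index: int = 0
    encoding: Encoding = Encoding.PM1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("panel values must be a 2-D array")
        if self.values.shape[1] != len(self.item_names):
            raise ValueError("item_names length does not match column count")
        finite = self.values[np.isfinite(self.values)]
        alphabet = set(self.encoding.alphabet)
        bad = set(np.unique(finite)) - alphabet
        if bad:
            raise ValueError(
                f"values {sorted(bad)} outside the {self.encoding.value} "
                f"alphabet {sorted(alphabet)}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def sufficient_stats(self) -> tuple[int, np.ndarray, np.ndarray]:
        """Return (n, per-item sums, upper-triangular cross-product sums).

        These are the complete sufficient statistics of the pairwise Ising
        likelihood; downstream cost is independent of n after this one pass.
        """
        if self.has_missing:
            raise ValueError(
                "panel has missing cells; read with policy='listwise' or "
                "drop incomplete rows before fitting"
            )
        v = self.values
        s = v.sum(axis=0)
        iu, ju = np.triu_indices(self.p, k=1)
        c = np.einsum("ni,nj->ij", v, v)[iu, ju]
        return self.n, s, c

    def state_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Histogram of observed configurations: (2^p state index, count)."""
        if self.has_missing:
            raise ValueError("panel has missing cells")
        bits = (self.values == self.encoding.alphabet[1]).astype(np.int64)
        idx = bits @ (1 << np.arange(self.p - 1, -1, -1, dtype=np.int64))
        return np.bincount(idx, minlength=2**self.p), idx

    def relabel(self, target: Encoding) -> "BinaryPanel":
        """Return the same observations written in the other alphabet."""
        if target == self.encoding:
            return self
        lo, hi = self.encoding.alphabet
        tlo, thi = target.alphabet
        vals = np.where(np.isnan(self.values), np.nan,
                        np.where(self.values == hi, thi, tlo))
        return BinaryPanel(vals, list(self.item_names), self.age,
                           self.wave_index, target)
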