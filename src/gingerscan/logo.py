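"""Target-site-duplication composition statistics and sequence-logo
information content."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class PositionFrequencyMatrix:
    """Column-wise empirical base frequencies over ``n_sites`` sequences.

    ``freqs`` has shape (length, 4) in A/C/G/T order; every row sums to 1.
    """

    freqs: np.ndarray
    n_sites: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError("freqs must have shape (length, 4)")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PFM column must sum to 1")

    def __len__(self) -> int:
        return self.freqs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freqs, columns=list(ALPHABET))
        df.index.name = "position"
        return df


def tsd_matrix(tsds: Sequence[str]) -> PositionFrequencyMatrix:
    """Empirical position frequency matrix of equal-length A/C/G/T strings."""
    if not tsds:
        raise ValueError("no TSD sequences given")
    length = len(tsds[0])
    counts = np.zeros((length, 4), dtype=float)
    for s in tsds:
        if len(s) != length:
            raise ValueError(
                f"mixed TSD lengths: expected {length}, got {len(s)} ({s!r})")
        for j, b in enumerate(s.upper()):
            if b not in _INDEX:
                raise ValueError(f"non-ACGT character {b!r} in {s!r}")
            counts[j, _INDEX[b]] += 1
    return PositionFrequencyMatrix(freqs=counts / len(tsds), n_sites=len(tsds))


def information_content(pfm: PositionFrequencyMatrix,
                        small_sample_correction: bool = False) -> np.ndarray:
    """Per-position information content in bits: ``IC_j = 2 - H_j`` with
    ``H_j = -sum_b f_bj log2 f_bj`` (0 log 0 := 0).  The optional small-
    sample correction subtracts ``e(n) = 3 / (2 ln2 n)`` (4-letter
    alphabet), floored at 0."""
    f = pfm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f), 0.0)
    entropy = -terms.sum(axis=1)
    ic = 2.0 - entropy
    if small_sample_correction:
        ic = ic - 3.0 / (2.0 * np.log(2) * pfm.n_sites)
    return np.clip(ic, 0.0, 2.0)
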