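"""Fixed-length classifier input vectors from syllable feature pairs.

A pair of consecutive syllables becomes one vector of length
``2 * (7 + 27 * N)``: per syllable the seven scalar features f1..f7 followed
by the row-major flattened N x 27 Mel-energy block of its nucleus.  Nuclei
longer than N frames keep their middle N frames; shorter nuclei are
zero-padded symmetrically (extra row at the end when the deficit is odd),
keeping the vowel centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .features import SyllableFeatureSet

__all__ = [
    "VectorConfig",
    "StressVector",
    "VectorStandardizer",
    "PairVectorizer",
    "select_nucleus_frames",
    "build_pair_vector",
    "fit_standardizer",
]


@dataclass
class StressVector:
    values: np.ndarray
    word: str = ""
    pair_index: int = 0


class VectorStandardizer(BaseEstimator, TransformerMixin):
    """Per-dimension (mean, sd) standardization with sd floored at 1e-8."""

    sd_floor = 1e-8

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("standardizer needs >= 2 training vectors")
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.maximum(X.std(axis=0, ddof=0), self.sd_floor)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        return (X - self.mean_) / self.scale_


@dataclass
class VectorConfig:
    """N = maximum nucleus frames per syllable (default 10 = ~100 ms of
    vowel at the 10 ms hop); optional fitted standardizer."""

    N: int = 10
    standardizer: VectorStandardizer | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")

    @property
    def vector_length(self) -> int:
        return 2 * (7 + 27 * self.N)


def select_nucleus_frames(block: np.ndarray, N: int) -> np.ndarray:
    """Middle-N truncation / symmetric zero padding of an n x 27 Mel block."""
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2 or block.shape[0] < 1:
        raise ValueError("Mel block must be a non-empty 2-D array")
    n = block.shape[0]
    if n == N:
        return block
    if n > N:
        lo = (n - N) // 2
        return block[lo:lo + N]
    deficit = N - n
    top = deficit // 2
    bottom = deficit - top  # extra row at the end when deficit is odd
    width = block.shape[1]
    return np.vstack([np.zeros((top, width)), block, np.zeros((bottom, width))])


def _syllable_block(s: SyllableFeatureSet, N: int) -> np.ndarray:
    if s.f8.shape[1] != 27:
        raise ValueError(f"Mel block must have 27 columns, got {s.f8.shape[1]}")
    return np.concatenate([s.scalars(), select_nucleus_frames(s.f8, N).ravel()])


def build_pair_vector(
    s1: SyllableFeatureSet,
    s2: SyllableFeatureSet,
    config: VectorConfig | None = None,
    word: str = "",
    pair_index: int = 0,
) -> StressVector:
    """Concatenate the two syllable blocks (first syllable first)."""
    config = config or VectorConfig()
    values = np.concatenate([_syllable_block(s1, config.N),
                             _syllable_block(s2, config.N)])
    if config.standardizer is not None:
        values = config.standardizer.transform(values[None, :])[0]
    return StressVector(values, word=word, pair_index=pair_index)


def fit_standardizer(vectors) -> VectorStandardizer:
    """Fit per-dimension standardization from training StressVectors."""
    rows = [v.values if isinstance(v, StressVector) else np.asarray(v)
            for v in vectors]
    return VectorStandardizer().fit(np.vstack(rows))


class PairVectorizer(BaseEstimator, TransformerMixin):
    """Transformer over (s1, s2) SyllableFeatureSet pairs.

    ``fit`` learns the per-dimension standardization (identity if
    ``standardize=False``); ``transform`` returns the stacked vector matrix.
    """

    def __init__(self, N: int = 10, standardize: bool = True):
        self.N = N
        self.standardize = standardize

    def _raw(self, pairs) -> np.ndarray:
        cfg = VectorConfig(N=self.N)
        return np.vstack([build_pair_vector(s1, s2, cfg).values
                          for s1, s2 in pairs])

    def fit(self, pairs, y=None):
        raw = self._raw(pairs)
        self.standardizer_ = VectorStandardizer().fit(raw) if self.standardize else None
        return self

    def transform(self, pairs) -> np.ndarray:
        raw = self._raw(pairs)
        if getattr(self, "standardizer_", None) is not None:
            raw = self.standardizer_.transform(raw)
        return raw
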