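"""Reduced Binary Pattern (RBP) features.

A trace is mapped to a bit sequence by pairwise order comparisons at a
configurable index distance alpha (the scaling factor; alpha=1 recovers the
basic comparison of adjacent samples), the bits are grouped into m-bit words
read most-significant-bit first, and the relative frequency of the 2^m
possible words is the feature vector.  Because only order relations enter,
the feature is invariant under any strictly increasing transform of the
signal amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputTooShortError, ParameterError


@dataclass
class RBPConfig:
    m: int = 8
    alpha: int = 1
    mode: str = "value_indexed"  # or "rank_sorted"
    stride: int = 1

    def __post_init__(self) -> None:
        if not 2 <= self.m <= 16:
            raise ParameterError(f"m must be in [2, 16], got {self.m}")
        if self.alpha < 1:
            raise ParameterError(f"alpha must be >= 1, got {self.alpha}")
        if self.stride < 1:
            raise ParameterError(f"stride must be >= 1, got {self.stride}")
        if self.mode not in ("value_indexed", "rank_sorted"):
            raise ParameterError(f"unknown mode {self.mode!r}")


@dataclass
class RBPFeature:
    values: np.ndarray  # length 2^m, non-negative, sums to 1
    config: RBPConfig
    n_words: int


def to_binary_sequence(x, alpha: int = 1) -> np.ndarray:
    """bit[i] = 1 iff x[i] > x[i+alpha] (ties and increases give 0)."""
    x = np.asarray(x, dtype=float)
    if x.size <= alpha:
        raise InputTooShortError(
            f"need more than alpha={alpha} samples, got {x.size}"
        )
    return (x[:-alpha] > x[alpha:]).astype(np.uint8)


def words_to_decimals(bits, m: int, stride: int = 1) -> np.ndarray:
    """Sliding m-bit windows (MSB first) converted to integers in [0, 2^m)."""
    bits = np.asarray(bits, dtype=np.int64)
    if bits.size < m:
        raise InputTooShortError(f"need at least m={m} bits, got {bits.size}")
    weights = 1 << np.arange(m - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(bits, m)[::stride]
    return windows @ weights


def rbp_feature(x, config: RBPConfig) -> RBPFeature:
    """Relative word-frequency vector of length 2^m over the trace ``x``."""
    bits = to_binary_sequence(x, config.alpha)
    decimals = words_to_decimals(bits, config.m, config.stride)
    counts = np.bincount(decimals, minlength=2**config.m).astype(float)
    values = counts / decimals.size
    if config.mode == "rank_sorted":
        values = np.sort(values)[::-1].copy()
    return RBPFeature(values=values, config=config, n_words=int(decimals.size))
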