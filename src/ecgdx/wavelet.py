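"""Wavelet features from fixed-length R-R cycle segments.

Each R-R cycle is resampled (linear interpolation) to a fixed number of
points, cut into three parts, and the first and last parts of the same cycle
are concatenated into one segment (the middle part around the low-information
mid-cycle region is discarded).  Segments are grouped in consecutive runs,
an n-level discrete wavelet transform is applied to each segment of a group,
and the selected coefficients are concatenated in segment order to form one
feature vector per group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .exceptions import (
    InsufficientPeaksError,
    InsufficientSegmentsError,
    ParameterError,
)
from .qrs import RPeakList
from .signal_io import ECGRecord

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    """Cycle resampling length and the (pre, mid, post) three-way cut.

    Defaults follow the PTB-style scheme: 284-point cycles cut 85/156/43,
    giving 128-point segments.
    """

    cycle_len: int = 284
    cuts: tuple[int, int, int] = (85, 156, 43)
    group_size: int = 4

    def __post_init__(self) -> None:
        pre, mid, post = self.cuts
        if min(pre, mid, post) < 1:
            raise ParameterError("all three cuts must be >= 1")
        if pre + mid + post != self.cycle_len:
            raise ParameterError(
                f"cuts {self.cuts} must sum to cycle_len={self.cycle_len}"
            )
        if self.group_size < 1:
            raise ParameterError("group_size must be >= 1")

    @property
    def segment_len(self) -> int:
        return self.cuts[0] + self.cuts[2]


# TVGH-style scheme: 256-point cycles with 169/85 pre/post cuts
TVGH_SEGMENTATION = SegmentationConfig(cycle_len=256, cuts=(169, 2, 85))


@dataclass
class WaveletConfig:
    n: int = 4
    family: str = "db4"
    seg: SegmentationConfig = field(default_factory=SegmentationConfig)
    coeff_set: str = "approx_only"  # or "approx_plus_details"
    per_segment_dwt: bool = True  # False: one DWT over the concatenated group

    def __post_init__(self) -> None:
        if not 1 <= self.n <= 9:
            raise ParameterError(f"DWT level must be in [1, 9], got {self.n}")
        if self.family not in pywt.wavelist(kind="discrete"):
            raise ParameterError(f"unknown discrete wavelet family {self.family!r}")
        if self.coeff_set not in ("approx_only", "approx_plus_details"):
            raise ParameterError(f"unknown coeff_set {self.coeff_set!r}")
        max_n = int(np.floor(np.log2(self.seg.segment_len)))
        if self.n > max_n:
            raise ParameterError(
                f"DWT level {self.n} exceeds the maximum admissible level "
                f"{max_n} for {self.seg.segment_len}-point segments"
            )


@dataclass
class WaveletFeature:
    values: np.ndarray
    config: WaveletConfig


def segment_cycles(
    record: ECGRecord, peaks: RPeakList, seg: SegmentationConfig | None = None
) -> list[np.ndarray]:
    """One fixed-length segment per R-R cycle.

    The raw samples of each cycle ``[peak_k, peak_{k+1})`` are linearly
    resampled to ``cycle_len`` points; the segment concatenates the first
    ``pre`` and last ``post`` resampled points.  Cycles shorter than 4 raw
    samples are skipped with a warning.
    """
    seg = seg or SegmentationConfig()
    if len(peaks) < 2:
        raise InsufficientPeaksError("need >= 2 R peaks to cut cycles")
    pre, _, post = seg.cuts
    x = record.samples
    out: list[np.ndarray] = []
    for a, b in zip(peaks.indices[:-1], peaks.indices[1:]):
        raw = x[a:b]
        if raw.size < 4:
            logger.warning("skipping degenerate %d-sample cycle at index %d", raw.size, a)
            continue
        grid = np.linspace(0.0, raw.size - 1.0, seg.cycle_len)
        cycle = np.interp(grid, np.arange(raw.size), raw)
        out.append(np.concatenate([cycle[:pre], cycle[-post:]]))
    return out


def group_segments(segments: list[np.ndarray], group_size: int = 4) -> list[np.ndarray]:
    """Consecutive non-overlapping runs of ``group_size`` segments.

    Each group is a (group_size, segment_len) array; a trailing remainder of
    fewer than ``group_size`` segments is discarded.
    """
    if group_size < 1:
        raise ParameterError("group_size must be >= 1")
    if len(segments) < group_size:
        raise InsufficientSegmentsError(
            f"need >= {group_size} segments, got {len(segments)}"
        )
    n_groups = len(segments) // group_size
    return [
        np.stack(segments[k * group_size : (k + 1) * group_size])
        for k in range(n_groups)
    ]


def wavelet_feature(group: np.ndarray, config: WaveletConfig | None = None) -> WaveletFeature:
    """n-level DWT coefficients of one segment group, concatenated.

    With ``per_segment_dwt`` (default) each segment is transformed
    independently and its selected coefficients (level-n approximation, or
    approximation plus all details) are concatenated in segment order;
    otherwise one DWT is taken over the flattened group.
    """
    config = config or WaveletConfig()
    group = np.atleast_2d(np.asarray(group, dtype=float))
    vectors = group if config.per_segment_dwt else group.reshape(1, -1)
    pieces: list[np.ndarray] = []
    for seg_vec in vectors:
        max_n = int(np.floor(np.log2(seg_vec.size)))
        if config.n > max_n:
            raise ParameterError(
                f"DWT level {config.n} exceeds the maximum admissible level "
                f"{max_n} for {seg_vec.size}-point input"
            )
        # periodized transform: exactly orthogonal (perfect reconstruction and
        # energy conservation) and admits levels up to floor(log2(len))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            coeffs = pywt.wavedec(
                seg_vec, config.family, level=config.n, mode="periodization"
            )
        if config.coeff_set == "approx_only":
            pieces.append(coeffs[0])
        else:
            pieces.append(np.concatenate(coeffs))
    return WaveletFeature(values=np.concatenate(pieces), config=config)


def record_wavelet_features(
    record: ECGRecord, peaks: RPeakList, config: WaveletConfig | None = None
) -> list[WaveletFeature]:
    """All per-group wavelet features of one record, in temporal order."""
    config = config or WaveletConfig()
    segments = segment_cycles(record, peaks, config.seg)
    groups = group_segments(segments, config.seg.group_size)
    return [wavelet_feature(g, config) for g in groups]
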