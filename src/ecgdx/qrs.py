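"""Real-time-style QRS detection (slope / amplitude / width analysis).

The detector follows the classic adaptive-threshold recipe: band-pass
5-15 Hz, five-point derivative, squaring, 150 ms moving-window integration,
dual running signal/noise peak estimates with a 200 ms refractory period and
a search-back pass triggered at 1.66x the running R-R average.  Every
accepted detection is refined to the local maximum of the band-passed signal
within a +/-50 ms window.  All thresholds are relative to running peak
statistics, so the detector is invariant to positive rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .exceptions import InputTooShortError, InsufficientPeaksError, ParameterError
from .signal_io import ECGRecord


@dataclass
class QRSConfig:
    band_low_hz: float = 5.0
    band_high_hz: float = 15.0
    integration_window_s: float = 0.150
    refractory_s: float = 0.200
    refine_window_s: float = 0.050
    searchback_factor: float = 1.66
    # classic adaptive-threshold constants: EMA weight for peak estimates and
    # the signal/noise mixing fraction of the detection threshold
    ema_weight: float = 0.125
    threshold_fraction: float = 0.25
    warmup_s: float = 2.0  # threshold initialization span, excluded from output


@dataclass
class RPeakList:
    """Ascending 0-based R-peak sample positions for one record."""

    indices: np.ndarray
    fs: float
    n_samples: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.indices.size:
            if np.any(np.diff(self.indices) <= 0):
                raise ParameterError("R-peak indices must be strictly increasing")
            if np.any(np.diff(self.indices) < 0.2 * self.fs):
                raise ParameterError("R peaks closer than the 0.2 s refractory period")
            if self.indices[0] < 0:
                raise ParameterError("negative R-peak index")
            if self.n_samples is not None and self.indices[-1] >= self.n_samples:
                raise ParameterError("R-peak index beyond record length")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs


def _bandpass(x: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    sos = _sig.butter(3, [low, high], btype="bandpass", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, x)


def _preprocess(x: np.ndarray, fs: float, cfg: QRSConfig):
    """Return (band-passed, moving-window-integrated) signals."""
    f = _bandpass(x, fs, cfg.band_low_hz, cfg.band_high_hz)
    # five-point derivative emphasises QRS slope
    kernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / 8.0
    d = np.convolve(f, kernel, mode="same")
    squared = d * d
    win = max(int(round(cfg.integration_window_s * fs)), 1)
    integ = np.convolve(squared, np.ones(win) / win, mode="same")
    return f, integ


def detect_r_peaks(record: ECGRecord, config: QRSConfig | None = None) -> RPeakList:
    """Locate R peaks with adaptive dual thresholds and search-back.

    Detections inside the warmup window (used only to seed the threshold
    estimates) are not reported.  A flat or peak-free record yields an empty
    peak list.
    """
    cfg = config or QRSConfig()
    x = np.asarray(record.samples, dtype=float)
    fs = record.fs
    if x.size < 2 * fs:
        raise InputTooShortError(
            f"need >= 2 s of signal, got {x.size / fs:.2f} s"
        )

    f, integ = _preprocess(x, fs, cfg)
    refractory = int(round(cfg.refractory_s * fs))
    cand, _ = _sig.find_peaks(integ, distance=max(refractory, 1))
    if cand.size == 0 or np.max(integ) <= 0:
        return RPeakList(np.array([], dtype=int), fs, n_samples=x.size)

    warm = int(round(cfg.warmup_s * fs))
    spki = float(np.max(integ[:warm])) if warm > 1 else float(np.max(integ))
    npki = float(np.mean(integ[:warm])) if warm > 1 else 0.0
    w = cfg.ema_weight
    frac = cfg.threshold_fraction

    accepted: list[int] = []
    noise_cand: list[int] = []  # sub-threshold candidates, for search-back
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + frac * (spki - npki)

    for idx in cand:
        v = integ[idx]
        if v > threshold():
            if accepted:
                rr_history.append(float(idx - accepted[-1]))
                if len(rr_history) > 8:
                    rr_history.pop(0)
            spki = w * v + (1.0 - w) * spki
            accepted.append(int(idx))
        else:
            npki = w * v + (1.0 - w) * npki
            noise_cand.append(int(idx))
            # search-back: expected beat overdue at 1.66x the running RR mean
            if accepted and rr_history:
                rr_avg = float(np.mean(rr_history))
                if idx - accepted[-1] > cfg.searchback_factor * rr_avg:
                    gap = [
                        j
                        for j in noise_cand
                        if accepted[-1] + refractory <= j <= idx
                    ]
                    if gap:
                        best = max(gap, key=lambda j: integ[j])
                        if integ[best] > 0.5 * threshold():
                            spki = 0.25 * integ[best] + 0.75 * spki
                            rr_history.append(float(best - accepted[-1]))
                            accepted.append(best)
                            accepted.sort()
                            noise_cand = [j for j in noise_cand if j > idx]

    # refine each detection to the band-passed local maximum
    half = int(round(cfg.refine_window_s * fs))
    refined: list[int] = []
    for idx in accepted:
        lo, hi = max(idx - half, 0), min(idx + half + 1, x.size)
        refined.append(lo + int(np.argmax(f[lo:hi])))

    refined = sorted(set(refined))
    out: list[int] = []
    for idx in refined:
        if idx < warm:
            continue
        if out and idx - out[-1] < refractory:
            # keep the stronger of two detections inside the refractory span
            if f[idx] > f[out[-1]]:
                out[-1] = idx
            continue
        out.append(idx)
    return RPeakList(np.array(out, dtype=int), fs, n_samples=x.size)


def rr_intervals(peaks: RPeakList) -> np.ndarray:
    """Consecutive R-R durations in seconds (length = n_peaks - 1)."""
    if len(peaks) < 2:
        raise InsufficientPeaksError(
            f"need >= 2 R peaks to form intervals, got {len(peaks)}"
        )
    return np.diff(peaks.indices) / peaks.fs


def export_peaks_tsv(path, peaks: RPeakList) -> None:
    """Write peaks as two-column TSV (sample_index, time_s)."""
    with open(path, "w") as fh:
        fh.write("sample_index\ttime_s\n")
        for idx, t in zip(peaks.indices, peaks.times_s):
            fh.write(f"{idx}\t{t:.6f}\n")


def match_peaks(
    truth: np.ndarray, detected: np.ndarray, fs: float, tol_s: float = 0.050
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected peaks to ground truth.

    Returns (true positives, false negatives, false positives) with matches
    accepted within ``tol_s`` seconds.
    """
    truth = np.asarray(truth, dtype=int)
    detected = np.asarray(detected, dtype=int)
    tol = tol_s * fs
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for t in truth:
        if detected.size == 0:
            break
        dists = np.abs(detected - t)
        dists[used] = np.iinfo(np.int64).max
        j = int(np.argmin(dists))
        if not used[j] and abs(int(detected[j]) - int(t)) <= tol:
            used[j] = True
            tp += 1
    fn = truth.size - tp
    fp = int(detected.size - used.sum())
    return tp, fn, fp
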