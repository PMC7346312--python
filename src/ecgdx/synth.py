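"""Synthetic labeled single-lead ECG cohorts with exact ground truth.

Each beat is a sum of five Gaussians (P, Q, R, S, T) placed at fixed
fractions of the beat period, a simplified fixed-template variant of the
Gaussian-wave ECG models used for simulation studies.  On top of the beat
train the generator adds an ST-segment level shift (boxcar between the S and
T waves), 0.3 Hz sinusoidal baseline wander, and white Gaussian noise.
Because the beats are synthesized analytically, the true R-peak sample
positions are known exactly and returned alongside the trace.

The class effect mimics smoking-linked repolarization changes reported for
real ECGs — ST-segment depression plus a reduced T-wave amplitude — applied
to one class's shared template.  The magnitudes are simulation parameters,
not claims about real smokers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError
from .signal_io import ECGRecord, LABEL_NONSMOKER, LABEL_SMOKER


@dataclass(frozen=True)
class Wave:
    amp_mv: float
    center_frac: float  # position within the beat, as a fraction of the period
    width_frac: float  # Gaussian sigma, as a fraction of the period


@dataclass(frozen=True)
class BeatTemplate:
    """Five-wave Gaussian beat plus an additive ST-segment level."""

    p: Wave = Wave(0.15, 0.10, 0.035)
    q: Wave = Wave(-0.12, 0.215, 0.010)
    r: Wave = Wave(1.20, 0.25, 0.013)
    s: Wave = Wave(-0.25, 0.285, 0.010)
    t: Wave = Wave(0.35, 0.45, 0.050)
    st_offset_mv: float = 0.0
    st_window_frac: tuple[float, float] = (0.31, 0.40)

    def __post_init__(self) -> None:
        waves = self.waves()
        if any(w.width_frac <= 0 for w in waves):
            raise ParameterError("wave widths must be positive")
        centers = [w.center_frac for w in waves]
        if sorted(centers) != centers:
            raise ParameterError("wave centers must be ascending within the beat")
        if any(abs(w.amp_mv) >= self.r.amp_mv for w in (self.p, self.q, self.s, self.t)):
            raise ParameterError("R amplitude must dominate the other waves")

    def waves(self) -> tuple[Wave, Wave, Wave, Wave, Wave]:
        return (self.p, self.q, self.r, self.s, self.t)

    def with_effect(self, effect: dict | None) -> "BeatTemplate":
        """Apply class-effect deltas: ``st_offset`` (additive, mV) and
        ``t_amp_scale`` (multiplicative on the T amplitude)."""
        if not effect:
            return self
        tpl = self
        if "st_offset" in effect:
            tpl = replace(tpl, st_offset_mv=tpl.st_offset_mv + effect["st_offset"])
        if "t_amp_scale" in effect:
            tpl = replace(
                tpl, t=replace(tpl.t, amp_mv=tpl.t.amp_mv * effect["t_amp_scale"])
            )
        return tpl


@dataclass
class CohortSpec:
    """Study conditions for one synthetic two-class cohort."""

    n_per_class: int = 200
    fs: float = 500.0
    duration_s: float = 20.0
    hr_mean: float = 70.0
    hr_sd: float = 5.0
    noise_sd: float = 0.05
    baseline_wander_amp: float = 0.1
    effect: dict = field(
        default_factory=lambda: {"st_offset": -0.15, "t_amp_scale": 0.8}
    )
    template: BeatTemplate = field(default_factory=BeatTemplate)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ParameterError("n_per_class must be >= 1")
        if self.fs < 100:
            raise ParameterError("fs must be >= 100 Hz")
        if self.duration_s < 5:
            raise ParameterError("duration_s must be >= 5 s")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class Cohort:
    records: list[ECGRecord]
    truth_peaks: list[np.ndarray]  # exact R-peak sample indices per record
    spec: CohortSpec


def generate_record(
    template: BeatTemplate,
    fs: float,
    duration_s: float,
    hr_bpm: float,
    noise_sd: float = 0.0,
    wander_amp: float = 0.0,
    seed: int = 0,
    subject_id: str = "synthetic",
    label: str = "unknown",
) -> tuple[ECGRecord, np.ndarray]:
    """Synthesize one trace and its exact R-peak indices.

    Beat periods are 60/hr seconds with seeded uniform jitter of +/-3% per
    beat; waves are evaluated only within +/-5 sigma of their centers for
    speed.  Baseline wander is a 0.3 Hz sinusoid with a seeded random phase.
    """
    if hr_bpm <= 0 or fs <= 0 or duration_s <= 0:
        raise ParameterError("hr_bpm, fs and duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    y = np.zeros(n)

    base_period = 60.0 / hr_bpm
    onsets: list[float] = []
    periods: list[float] = []
    t0 = 0.0
    while t0 < duration_s:
        period = base_period * (1.0 + rng.uniform(-0.03, 0.03))
        onsets.append(t0)
        periods.append(period)
        t0 += period

    r_indices: list[int] = []
    for onset, period in zip(onsets, periods):
        for wave in template.waves():
            mu = onset + wave.center_frac * period
            sd = wave.width_frac * period
            lo = max(int((mu - 5 * sd) * fs), 0)
            hi = min(int((mu + 5 * sd) * fs) + 1, n)
            if lo >= hi:
                continue
            tt = t[lo:hi]
            y[lo:hi] += wave.amp_mv * np.exp(-((tt - mu) ** 2) / (2 * sd**2))
        if template.st_offset_mv != 0.0:
            a, b = template.st_window_frac
            lo = max(int((onset + a * period) * fs), 0)
            hi = min(int((onset + b * period) * fs), n)
            y[lo:hi] += template.st_offset_mv
        r_idx = int(round((onset + template.r.center_frac * period) * fs))
        if 0 <= r_idx < n:
            r_indices.append(r_idx)

    if wander_amp:
        phase = rng.uniform(0, 2 * np.pi)
        y += wander_amp * np.sin(2 * np.pi * 0.3 * t + phase)
    if noise_sd:
        y += rng.normal(0.0, noise_sd, size=n)

    record = ECGRecord(
        samples=y, fs=fs, lead="i", subject_id=subject_id, label=label
    )
    return record, np.array(r_indices, dtype=int)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Balanced two-class cohort; class 1 (smoker) carries the effect deltas.

    Per-record heart rate is drawn from N(hr_mean, hr_sd); every record gets
    an independent stream spawned from the cohort seed, so generation is
    fully deterministic and order-independent.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(2 * spec.n_per_class)
    templates = {
        LABEL_NONSMOKER: spec.template,
        LABEL_SMOKER: spec.template.with_effect(spec.effect),
    }
    records: list[ECGRecord] = []
    truth: list[np.ndarray] = []
    k = 0
    for label in (LABEL_NONSMOKER, LABEL_SMOKER):
        for i in range(spec.n_per_class):
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            hr = float(np.clip(rng.normal(spec.hr_mean, spec.hr_sd), 35.0, 180.0))
            rec_seed = int(child.generate_state(1)[0] % (2**31))
            rec, peaks = generate_record(
                templates[label],
                fs=spec.fs,
                duration_s=spec.duration_s,
                hr_bpm=hr,
                noise_sd=spec.noise_sd,
                wander_amp=spec.baseline_wander_amp,
                seed=rec_seed,
                subject_id=f"{label[:3]}{i:04d}",
                label=label,
            )
            records.append(rec)
            truth.append(peaks)
    return Cohort(records=records, truth_peaks=truth, spec=spec)


def clean_rms(template: BeatTemplate, hr_bpm: float = 60.0, fs: float = 500.0) -> float:
    """RMS of a noise-free, wander-free beat train (for SNR calibration)."""
    rec, _ = generate_record(template, fs=fs, duration_s=10.0, hr_bpm=hr_bpm, seed=0)
    return float(np.sqrt(np.mean(rec.samples**2)))


def noise_sd_for_snr(
    template: BeatTemplate, snr_db: float, hr_bpm: float = 60.0, fs: float = 500.0
) -> float:
    """White-noise sigma giving the requested SNR against the clean train."""
    return clean_rms(template, hr_bpm, fs) / (10.0 ** (snr_db / 20.0))
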