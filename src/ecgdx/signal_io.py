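"""Reading, writing and pre-filtering of single-lead ECG records.

Supports two on-disk forms: WFDB-style header/signal pairs restricted to
signal format 16 (16-bit two's-complement little-endian integers, the
encoding used by the PTB diagnostic ECG database), and bare one-column CSV
traces with a caller-supplied sampling rate.  Pre-filtering offers a
linear-phase FIR band-pass (applied forward-backward so R-peak positions are
not shifted) and multilevel wavelet denoising with universal soft
thresholding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pywt
from scipy import signal as _sig

from .exceptions import (
    EmptyInputError,
    FormatError,
    LeadNotFoundError,
    ParameterError,
)

LABEL_SMOKER = "smoker"
LABEL_NONSMOKER = "nonsmoker"
LABEL_UNKNOWN = "unknown"


@dataclass
class ECGRecord:
    """One single-lead ECG trace in physical units (mV)."""

    samples: np.ndarray
    fs: float
    lead: str = ""
    subject_id: str = ""
    label: str = LABEL_UNKNOWN
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise EmptyInputError("record contains no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("record contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class FilterSpec:
    """Pre-processing filter description.

    kind:
        ``fir_bandpass`` — linear-phase FIR band-pass, zero-lag (forward-
        backward) application; ``wavelet_denoise`` — multilevel DWT with
        universal soft thresholding of detail coefficients;
        ``none`` — identity.
    """

    kind: str = "fir_bandpass"
    low_hz: float = 0.5
    high_hz: float = 40.0
    fir_order: int = 256
    denoise_wavelet: str = "db4"
    denoise_level: int = 4
    threshold_rule: str = "universal_soft"

    def __post_init__(self) -> None:
        if self.kind not in ("fir_bandpass", "wavelet_denoise", "none"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        if self.kind == "fir_bandpass":
            if not 0 <= self.low_hz < self.high_hz:
                raise ParameterError(
                    f"need 0 <= low_hz < high_hz, got {self.low_hz}, {self.high_hz}"
                )
            if self.fir_order < 2:
                raise ParameterError("fir_order must be >= 2")
        if self.kind == "wavelet_denoise" and self.denoise_level < 1:
            raise ParameterError("denoise_level must be >= 1")


# ---------------------------------------------------------------------------
# WFDB format-16 header/signal pairs
# ---------------------------------------------------------------------------

_COMMENT_KV = re.compile(r"^#\s*([^:]+?)\s*:\s*(.*?)\s*$")


def _parse_gain_field(token: str) -> tuple[float, float | None]:
    """Parse a WFDB gain token ``gain(baseline)/units`` -> (gain, baseline)."""
    m = re.match(r"^([-+0-9.eE]+)(?:\(([-+0-9]+)\))?(?:/(\S+))?$", token)
    if m is None:
        raise FormatError(f"cannot parse gain field {token!r}")
    gain = float(m.group(1))
    baseline = int(m.group(2)) if m.group(2) is not None else None
    return gain, baseline


def read_wfdb_record(header_path: str | Path, lead: str = "i") -> ECGRecord:
    """Read one lead of a WFDB format-16 record in physical units (mV).

    Only signal format 16 (16-bit little-endian two's complement, samples
    interleaved across channels in one ``.dat`` file) is supported; other
    formats are rejected.  ``#``-comment lines of the form ``key: value``
    are collected into ``meta``.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"header file not found: {header_path}")
    lines = header_path.read_text().splitlines()
    body = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    comments = [ln for ln in lines if ln.lstrip().startswith("#")]
    if not body:
        raise EmptyInputError(f"header has no record line: {header_path}")

    rec_tokens = body[0].split()
    if len(rec_tokens) < 3:
        raise FormatError(f"unparseable record line {body[0]!r} in {header_path}")
    record_name = rec_tokens[0]
    try:
        n_sig = int(rec_tokens[1])
        fs = float(rec_tokens[2].split("/")[0])
    except ValueError as exc:
        raise FormatError(f"unparseable record line {body[0]!r}: {exc}") from None

    sig_lines = body[1 : 1 + n_sig]
    if len(sig_lines) < n_sig:
        raise FormatError(f"header declares {n_sig} signals, found {len(sig_lines)}")

    leads: list[str] = []
    specs: list[tuple[str, float, float]] = []  # (filename, gain, baseline)
    for ln in sig_lines:
        toks = ln.split()
        if len(toks) < 3:
            raise FormatError(f"unparseable signal line {ln!r} in {header_path}")
        fname, fmt = toks[0], toks[1]
        if fmt.split("x")[0].split(":")[0] != "16":
            raise FormatError(
                f"unsupported WFDB signal format {fmt!r} (only format 16 is supported)"
            )
        gain, baseline = _parse_gain_field(toks[2])
        if gain == 0:
            gain = 200.0  # WFDB default gain when unspecified/zero
        if baseline is None:
            # baseline defaults to the ADC-zero field when present
            baseline = float(toks[4]) if len(toks) > 4 else 0.0
        name = " ".join(toks[8:]) if len(toks) > 8 else f"ch{len(leads)}"
        leads.append(name)
        specs.append((fname, gain, float(baseline)))

    try:
        idx = [l.lower() for l in leads].index(lead.lower())
    except ValueError:
        raise LeadNotFoundError(
            f"lead {lead!r} not in record {record_name}; available: {sorted(leads)}"
        ) from None

    dat_path = header_path.parent / specs[idx][0]
    if not dat_path.exists():
        raise FormatError(f"signal file not found: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size == 0:
        raise EmptyInputError(f"signal file is empty: {dat_path}")
    n_frames = raw.size // n_sig
    adc = raw[: n_frames * n_sig].reshape(n_frames, n_sig)[:, idx]

    _, gain, baseline = specs[idx]
    samples = (adc.astype(float) - baseline) / gain

    meta: dict[str, str] = {}
    for i, c in enumerate(comments):
        m = _COMMENT_KV.match(c.strip())
        if m:
            meta[m.group(1)] = m.group(2)
        else:
            meta[f"comment_{i}"] = c.lstrip("# ").rstrip()

    return ECGRecord(
        samples=samples,
        fs=fs,
        lead=leads[idx],
        subject_id=record_name,
        label=parse_smoking_label(meta),
        meta=meta,
    )


def write_wfdb_record(
    header_path: str | Path,
    signals_mv: dict[str, np.ndarray],
    fs: float,
    gain: float = 2000.0,
    comments: dict[str, str] | None = None,
) -> Path:
    """Write a multi-lead WFDB format-16 pair; returns the header path.

    Samples are quantized as ``round(mV * gain)`` (baseline 0) and clipped to
    the int16 range, so a read-back agrees with the input to within one
    quantization step (1/gain mV).
    """
    header_path = Path(header_path)
    record_name = header_path.stem
    dat_name = record_name + ".dat"
    names = list(signals_mv)
    arrays = [np.asarray(signals_mv[n], dtype=float) for n in names]
    n = min(a.size for a in arrays)
    adc = np.stack(
        [np.clip(np.rint(a[:n] * gain), -32768, 32767).astype("<i2") for a in arrays],
        axis=1,
    )
    lines = [f"{record_name} {len(names)} {fs:g} {n}"]
    for name in names:
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 {name}")
    for key, val in (comments or {}).items():
        lines.append(f"# {key}: {val}")
    header_path.write_text("\n".join(lines) + "\n")
    adc.tofile(header_path.parent / dat_name)
    return header_path


def parse_smoking_label(meta: dict) -> str:
    """Extract a smoking label from header metadata; never raises.

    A case-insensitive ``Smoker`` key with value ``yes``/``no`` maps to
    smoker/nonsmoker; anything else (including absence) is unknown.
    """
    if not meta:
        return LABEL_UNKNOWN
    for key, value in meta.items():
        if str(key).strip().lower() == "smoker":
            v = str(value).strip().lower()
            if v == "yes":
                return LABEL_SMOKER
            if v == "no":
                return LABEL_NONSMOKER
    return LABEL_UNKNOWN


# ---------------------------------------------------------------------------
# CSV traces
# ---------------------------------------------------------------------------


def read_csv_record(
    path: str | Path,
    fs: float,
    label: str = LABEL_UNKNOWN,
    subject_id: str = "",
) -> ECGRecord:
    """Read a one-column CSV/text trace (mV per line; blank lines skipped).

    A non-numeric first line is treated as a header; a non-numeric cell
    anywhere else raises a format error citing the 1-based line number.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            cell = line.strip().rstrip(",")
            if not cell:
                continue
            try:
                values.append(float(cell))
            except ValueError:
                if lineno == 1 and not values:
                    continue  # optional header row
                raise FormatError(
                    f"non-numeric value {cell!r} on line {lineno} of {path}"
                ) from None
    if not values:
        raise EmptyInputError(f"no numeric samples in {path}")
    return ECGRecord(
        samples=np.array(values),
        fs=fs,
        subject_id=subject_id or path.stem,
        label=label,
    )


def write_csv_record(path: str | Path, record: ECGRecord) -> Path:
    path = Path(path)
    np.savetxt(path, record.samples, fmt="%.6f")
    return path


# ---------------------------------------------------------------------------
# Pre-filtering
# ---------------------------------------------------------------------------


def apply_filter(record: ECGRecord, spec: FilterSpec) -> ECGRecord:
    """Return a filtered copy of ``record``; length and fs are preserved."""
    x = record.samples
    if spec.kind == "none":
        y = x.copy()
    elif spec.kind == "fir_bandpass":
        nyq = record.fs / 2.0
        if spec.high_hz >= nyq:
            raise ParameterError(
                f"high cutoff {spec.high_hz} Hz must be below Nyquist {nyq} Hz"
            )
        numtaps = spec.fir_order + 1
        if numtaps % 2 == 0:
            numtaps += 1  # force Type I (odd length) for a band-pass
        if spec.low_hz <= 0:
            taps = _sig.firwin(numtaps, spec.high_hz, pass_zero=True, fs=record.fs)
        else:
            taps = _sig.firwin(
                numtaps, [spec.low_hz, spec.high_hz], pass_zero=False, fs=record.fs
            )
        padlen = min(3 * numtaps, x.size - 1)
        y = _sig.filtfilt(taps, [1.0], x, padlen=padlen)
    else:  # wavelet_denoise
        level = min(
            spec.denoise_level, pywt.dwt_max_level(x.size, spec.denoise_wavelet)
        )
        if level < 1:
            raise ParameterError("record too short for one decomposition level")
        coeffs = pywt.wavedec(x, spec.denoise_wavelet, level=level)
        # universal threshold, noise scale from the finest detail level (MAD)
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if coeffs[-1].size else 0.0
        thr = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))
        if thr > 0:
            coeffs = [coeffs[0]] + [pywt.threshold(c, thr, "soft") for c in coeffs[1:]]
        y = pywt.waverec(coeffs, spec.denoise_wavelet)[: x.size]

    return ECGRecord(
        samples=y,
        fs=record.fs,
        lead=record.lead,
        subject_id=record.subject_id,
        label=record.label,
        meta=dict(record.meta),
    )


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping subject_id -> label."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"expected two tab-separated columns on line {lineno}")
        out[parts[0].strip()] = parts[1].strip().lower()
    return out
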