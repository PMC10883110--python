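"""Core EEG signal operations: referencing, filtering, resampling, GFP.

The global field power (GFP) of an average-referenced recording at sample
t is the spatial standard deviation across electrodes,

    GFP_t = sqrt( (1/n) * sum_i u_i(t)^2 ),

with u_i the re-referenced channel voltages and n the channel count.
Topographies at local maxima of the GFP curve have the best spatial
signal-to-noise ratio and are the items clustered by the microstate stage.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

logger = logging.getLogger("microdfc")

REFERENCE_RTOL = 1e-9


@dataclass
class Recording:
    """A channels x samples multichannel EEG recording.

    data is stored in microvolt-like units, one row per channel.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains NaN or infinite values")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def is_average_referenced(self, rtol: float = REFERENCE_RTOL) -> bool:
        scale = max(float(np.abs(self.data).max(initial=0.0)), 1.0)
        return bool(np.abs(self.data.mean(axis=0)).max(initial=0.0) <= rtol * scale)


@dataclass
class GfpSeries:
    """Per-sample global field power of one recording."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("GFP series must be 1-D")
        if (self.values < 0).any():
            raise ValueError("GFP values must be nonnegative")


def apply_average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average; idempotent."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data)


def bandpass_filter(
    rec: Recording, low: float, high: float, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward).

    Zero-phase filtering is required so that microstate segment boundaries
    are not shifted in time by the filter's group delay.
    """
    nyq = rec.fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {nyq}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=np.ascontiguousarray(data))


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Resample to a lower rate with anti-aliasing (polyphase FIR)."""
    if target_fs >= rec.fs:
        raise ValueError(f"target rate {target_fs} must be below {rec.fs} Hz")
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=np.ascontiguousarray(data), fs=target_fs)


def compute_gfp(rec: Recording) -> GfpSeries:
    """Spatial standard deviation across electrodes at each sample.

    If the input is not average-referenced a warning is logged and the
    reference is applied internally, since the GFP definition assumes
    zero-mean topographies.
    """
    if not rec.is_average_referenced():
        logger.warning(
            "recording %s is not average-referenced; applying reference for GFP",
            rec.subject_id or "<unnamed>",
        )
        rec = apply_average_reference(rec)
    values = np.sqrt(np.mean(rec.data**2, axis=0))
    return GfpSeries(values=values, fs=rec.fs)


def find_gfp_peaks(gfp: GfpSeries) -> np.ndarray:
    """Indices of strict local maxima of the GFP curve.

    A peak is strictly greater than its neighbors; a plateau that is a
    maximum contributes its first sample. Endpoints are never returned.
    """
    v = gfp.values
    n = v.size
    if n < 3:
        return np.empty(0, dtype=np.intp)
    peaks: list[int] = []
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=np.intp)


# ---------------------------------------------------------------------------
# I/O: delimited text matrices with a JSON sidecar, and optional EDF reading.
# ---------------------------------------------------------------------------


def write_recording_text(rec: Recording, path: str | Path, meta: dict | None = None) -> Path:
    """Write samples-as-rows x channels-as-columns TSV with a JSON sidecar."""
    path = Path(path)
    header = "\t".join(rec.channel_labels)
    np.savetxt(path, rec.data.T, fmt="%.6f", delimiter="\t", header=header, comments="")
    sidecar = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
    }
    if meta:
        sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording_text(path: str | Path) -> Recording:
    path = Path(path)
    with open(path) as fh:
        labels = fh.readline().strip().split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return Recording(
        data=np.atleast_2d(data).T,
        fs=float(meta.get("fs", 250.0)),
        channel_labels=labels,
        subject_id=str(meta.get("subject_id", path.stem)),
        group=meta.get("group"),
    )


def read_recording_edf(path: str | Path, group: str | None = None) -> Recording:
    """Read an EDF file through MNE (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError("EDF reading requires the optional 'mne' dependency") from exc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=[str(c) for c in raw.ch_names],
        subject_id=Path(path).stem,
        group=group,
    )
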