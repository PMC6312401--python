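"""Epoched EEG container, versioned on-disk format, and signal-level preprocessing.

The container is deliberately simple and cross-language: a JSON header
(shapes, sampling rate, epoch origin, channel labels, format version), a raw
little-endian float32 binary payload in trial-major order, and the design
table as a CSV sidecar.  All preprocessing operations are pure functions
returning new :class:`EpochsArray` instances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from ._utils import logger
from .design import ExperimentDesign

FORMAT_VERSION = 1

#: BioSemi 64-electrode layout in the international 10-20 nomenclature.
BIOSEMI64 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]

#: Occipito-parietal sensor group used for ERP component analyses.
OCCIPITO_PARIETAL = ["O1", "O2", "Oz", "POz", "PO7", "PO3", "PO8", "PO4", "P3", "Pz", "P2"]


class EpochsFormatError(ValueError):
    """Raised when an on-disk container is malformed or inconsistent."""


@dataclass
class EpochsArray:
    """Trials x sensors x samples tensor in microvolts with aligned metadata.

    ``t0`` is the time of the first sample relative to first-Gabor onset, so
    the second Gabor appears at ``design.table['onset_second_s']`` (0.6 s)
    on the same axis.  ``rejected_mask`` marks trials excluded from all
    downstream fits; rejection never alters stored voltages.
    """

    data: np.ndarray
    sample_rate: float
    t0: float
    channel_labels: list[str]
    design: ExperimentDesign
    rejected_mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_sensors, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError(
                f"channel_labels: expected {self.data.shape[1]} labels, "
                f"got {len(self.channel_labels)}"
            )
        if len(self.design) != self.data.shape[0]:
            raise ValueError(
                f"design: {len(self.design)} rows for {self.data.shape[0]} trials"
            )
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.data.shape[0], dtype=bool)
        self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)
        if self.rejected_mask.shape != (self.data.shape[0],):
            raise ValueError("rejected_mask must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def sensor_indices(self, labels) -> np.ndarray:
        try:
            return np.array([self.channel_labels.index(l) for l in labels])
        except ValueError as err:
            raise KeyError(f"unknown sensor label: {err}") from None

    def retained(self) -> np.ndarray:
        """Indices of trials that survived artefact rejection."""
        return np.flatnonzero(~self.rejected_mask)

    def copy_with(self, **kw) -> "EpochsArray":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# on-disk container
# ---------------------------------------------------------------------------

def write_epochs(epochs: EpochsArray, path) -> Path:
    """Write an epochs container directory (header.json + data.bin + design.csv)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = np.ascontiguousarray(epochs.data, dtype="<f4")
    header = {
        "format_version": FORMAT_VERSION,
        "shape": list(epochs.data.shape),
        "dtype": "<f4",
        "order": "trial-major",
        "n_bytes": int(payload.nbytes),
        "sample_rate": float(epochs.sample_rate),
        "t0": float(epochs.t0),
        "channel_labels": list(epochs.channel_labels),
        "rejected_mask": epochs.rejected_mask.astype(int).tolist(),
        "design": {
            "n_blocks": epochs.design.n_blocks,
            "trials_per_block": epochs.design.trials_per_block,
        },
    }
    (path / "header.json").write_text(json.dumps(header, indent=1))
    (path / "data.bin").write_bytes(payload.tobytes())
    epochs.design.to_csv(path / "design.csv")
    return path


def read_epochs(path) -> EpochsArray:
    """Read a container written by :func:`write_epochs`; validates byte counts."""
    path = Path(path)
    try:
        header = json.loads((path / "header.json").read_text())
    except FileNotFoundError:
        raise EpochsFormatError(f"missing header.json in {path}") from None
    if header.get("format_version") != FORMAT_VERSION:
        raise EpochsFormatError(
            f"format_version: expected {FORMAT_VERSION}, found {header.get('format_version')}"
        )
    shape = tuple(header["shape"])
    raw = (path / "data.bin").read_bytes()
    expected = int(header["n_bytes"])
    if len(raw) != expected:
        raise EpochsFormatError(
            f"data.bin: expected {expected} bytes, found {len(raw)}"
        )
    data = np.frombuffer(raw, dtype=header["dtype"]).reshape(shape)
    design = ExperimentDesign.from_csv(path / "design.csv")
    if len(design) != shape[0]:
        raise EpochsFormatError(
            f"design.csv: {len(design)} rows for {shape[0]} trials"
        )
    return EpochsArray(
        data=data.copy(),
        sample_rate=header["sample_rate"],
        t0=header["t0"],
        channel_labels=list(header["channel_labels"]),
        design=design,
        rejected_mask=np.asarray(header["rejected_mask"], dtype=bool),
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def rereference_common_average(epochs: EpochsArray) -> EpochsArray:
    """Subtract the instantaneous mean over sensors from every sensor."""
    if epochs.n_sensors < 2:
        raise ValueError("common-average reference requires at least 2 sensors")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=data)


def filter_epochs(epochs: EpochsArray, low_hz: float = None, high_hz: float = None,
                  order: int = 4) -> EpochsArray:
    """Zero-phase Butterworth filtering (forward-backward, `sosfiltfilt`).

    ``low_hz`` alone gives a high-pass (e.g. the 0.5 Hz drift filter),
    both cut-offs give a band-pass (e.g. 2-40 Hz for ERP waveforms).
    """
    nyq = epochs.sample_rate / 2
    if low_hz is None and high_hz is None:
        raise ValueError("specify at least one cut-off frequency")
    for f in (low_hz, high_hz):
        if f is not None and not (0 < f < nyq):
            raise ValueError(f"cut-off {f} Hz outside (0, Nyquist={nyq} Hz)")
    if low_hz is not None and high_hz is not None:
        if low_hz >= high_hz:
            raise ValueError("low cut-off must be below high cut-off")
        sos = sp_signal.butter(order, [low_hz, high_hz], btype="bandpass",
                               fs=epochs.sample_rate, output="sos")
    elif low_hz is not None:
        sos = sp_signal.butter(order, low_hz, btype="highpass",
                               fs=epochs.sample_rate, output="sos")
    else:
        sos = sp_signal.butter(order, high_hz, btype="lowpass",
                               fs=epochs.sample_rate, output="sos")
    data = sp_signal.sosfiltfilt(sos, epochs.data.astype(np.float64), axis=-1)
    return epochs.copy_with(data=data.astype(np.float32))


def _window_slice(epochs: EpochsArray, window: tuple[float, float]) -> slice:
    times = epochs.times
    lo, hi = window
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError(
            f"window {window} outside epoch [{times[0]:.3f}, {times[-1]:.3f}] s"
        )
    idx = np.flatnonzero((times >= lo - 1e-9) & (times <= hi + 1e-9))
    return slice(idx[0], idx[-1] + 1)


def baseline_correct(epochs: EpochsArray, window: tuple[float, float] = (-0.1, 0.0),
                     anchor: str = "second_gabor") -> EpochsArray:
    """Subtract the per-trial, per-sensor mean over a baseline window.

    ``anchor`` selects the event the window is relative to: the second Gabor
    (the default, the study's main baseline) or the first Gabor (the control
    baseline that precedes any orientation information in the pair).
    """
    if anchor not in ("first_gabor", "second_gabor"):
        raise ValueError(f"unknown baseline anchor {anchor!r}")
    offset = 0.0 if anchor == "first_gabor" else float(
        epochs.design.table["onset_second_s"].iloc[0]
    )
    sl = _window_slice(epochs, (window[0] + offset, window[1] + offset))
    base = epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def reject_threshold(epochs: EpochsArray, threshold_uv: float = 100.0) -> EpochsArray:
    """Flag trials whose absolute peak voltage exceeds the threshold.

    Flags accumulate into ``rejected_mask``; retained data values are never
    modified.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peaks = np.abs(epochs.data).max(axis=(1, 2))
    mask = epochs.rejected_mask | (peaks > threshold_uv)
    return epochs.copy_with(rejected_mask=mask)


def crop_epochs(epochs: EpochsArray, tmin: float, tmax: float) -> EpochsArray:
    """Restrict the time axis to [tmin, tmax] (seconds from first-Gabor onset)."""
    sl = _window_slice(epochs, (tmin, tmax))
    return epochs.copy_with(data=epochs.data[:, :, sl], t0=float(epochs.times[sl.start]))


def resample_epochs(epochs: EpochsArray, new_rate: float) -> EpochsArray:
    """Polyphase resampling to a new sampling rate (e.g. 1024 -> 256 Hz)."""
    from fractions import Fraction

    frac = Fraction(float(new_rate) / epochs.sample_rate).limit_denominator(1000)
    data = sp_signal.resample_poly(epochs.data.astype(np.float64), frac.numerator,
                                   frac.denominator, axis=-1)
    return epochs.copy_with(data=data.astype(np.float32), sample_rate=float(new_rate))


def condition_erp(epochs: EpochsArray, grouping: str = "condition",
                  sensors=None, include_targets: bool = False):
    """Per-condition event-related potentials: trial mean then sensor mean.

    Returns a DataFrame indexed by time with one column per group level.
    Rejected trials are always excluded; coloured-target trials are excluded
    by default (ERP analyses) but can be retained (encoding analyses).
    """
    import pandas as pd

    labels = epochs.design.labels(grouping)
    keep = ~epochs.rejected_mask
    if not include_targets:
        keep &= ~epochs.design.table["is_target"].to_numpy()
    if sensors is None:
        sensor_idx = np.arange(epochs.n_sensors)
    else:
        sensor_idx = epochs.sensor_indices(sensors)
    out = {}
    for level in pd.unique(labels):
        sel = keep & (labels == level)
        if not sel.any():
            raise ValueError(f"no retained trials in condition cell {level!r}")
        out[level] = epochs.data[np.ix_(sel, sensor_idx)].mean(axis=(0, 1))
    return pd.DataFrame(out, index=pd.Index(epochs.times, name="time"))
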