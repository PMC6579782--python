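"""Preprocessing chain: mastoid re-reference, band-pass + notch filtering,
epoching with baseline correction, amplitude-based artifact rejection, and
spherical inverse-distance interpolation of bad channels.

Artifact handling is deliberately a deterministic peak-to-peak criterion
rather than an ICA decomposition; a hook (`ica_hook` on
:func:`preprocess_recording`) lets callers insert an external component
step between filtering and epoching if they need one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import signal

from .montage import Montage
from .synth import Recording

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_MS = (-200.0, 1000.0)
DEFAULT_BASELINE_MS = (-200.0, 0.0)
DEFAULT_REJECT_UV = 150.0


@dataclass(frozen=True)
class EpochSet:
    """Stimulus-locked trials: (n_trials, n_channels, n_times) in microvolt.

    ``times_ms`` is the latency of each sample relative to stimulus onset;
    the default window is the half-open [-200, 1000) ms.  After baseline
    correction every trial/channel has zero mean over the baseline window.
    """

    data: np.ndarray
    times_ms: np.ndarray
    labels: tuple[str, ...]
    rate: float
    montage: Montage
    baseline_window_ms: tuple[float, float] | None = DEFAULT_BASELINE_MS

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, channels, time), got {data.shape}")
        if data.shape[0] != len(self.labels):
            raise ValueError("labels length must equal trial count")
        if data.shape[1] != self.montage.n_channels:
            raise ValueError("channel axis must match montage")
        if data.shape[2] != len(self.times_ms):
            raise ValueError("time axis must match times_ms")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times_ms", np.asarray(self.times_ms, dtype=float))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, keep: np.ndarray) -> "EpochSet":
        keep = np.asarray(keep)
        return replace(
            self,
            data=self.data[keep],
            labels=tuple(np.asarray(self.labels, dtype=object)[keep]),
        )

    def condition_trials(self, condition: str) -> np.ndarray:
        from .synth import matches_condition

        return np.array([matches_condition(l, condition) for l in self.labels])


def rereference_to_mastoids(rec: Recording) -> Recording:
    """Subtract the mean of the two mastoid channels from every channel."""
    m1, m2 = rec.montage.mastoid_labels
    try:
        i1, i2 = rec.montage.index(m1), rec.montage.index(m2)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    ref = 0.5 * (rec.data[i1] + rec.data[i2])
    return replace(rec, data=rec.data - ref[None, :])


def filter_recording(
    rec: Recording,
    hp_hz: float = 0.1,
    lp_hz: float = 30.0,
    notch_hz: float | None = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase Butterworth band-pass plus IIR notch.

    Both stages run forward-backward (filtfilt), so the passband is phase
    neutral and the effective attenuation is squared.
    """
    nyq = rec.rate / 2.0
    if not (0 < hp_hz < lp_hz < nyq):
        raise ValueError(f"need 0 < hp ({hp_hz}) < lp ({lp_hz}) < Nyquist ({nyq})")
    # generous reflect padding: the 0.1 Hz high-pass has a multi-second
    # impulse response and the default padlen leaves visible edge drift
    n = rec.n_samples
    padlen = min(n - 1, int(3 * rec.rate / hp_hz))
    sos = signal.butter(order, [hp_hz, lp_hz], btype="bandpass", fs=rec.rate, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1, padlen=padlen)
    if notch_hz is not None:
        if not (0 < notch_hz < nyq):
            raise ValueError(f"notch frequency {notch_hz} outside (0, Nyquist={nyq})")
        b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.rate)
        data = signal.filtfilt(b, a, data, axis=1, padlen=min(n - 1, int(3 * rec.rate)))
    return replace(rec, data=data)


def epoch_recording(
    rec: Recording,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    baseline_ms: tuple[float, float] | None = DEFAULT_BASELINE_MS,
) -> EpochSet:
    """Cut half-open [start, stop) ms epochs around each event and baseline.

    Events whose window would run off either end of the recording are
    dropped with a warning.  At 500 Hz the default window gives exactly
    600 samples per epoch.
    """
    w0, w1 = window_ms
    if w1 <= w0:
        raise ValueError("window must have positive length")
    if baseline_ms is not None:
        b0, b1 = baseline_ms
        if not (w0 <= b0 < b1 <= w1):
            raise ValueError("baseline window must lie within the epoch window")
    first = int(round(w0 * rec.rate / 1000.0))
    n_samp = int(round((w1 - w0) * rec.rate / 1000.0))
    times_ms = (first + np.arange(n_samp)) * 1000.0 / rec.rate

    trials, labels = [], []
    n_dropped = 0
    for onset, label in zip(rec.events.onsets, rec.events.labels):
        start = int(onset) + first
        if start < 0 or start + n_samp > rec.n_samples:
            n_dropped += 1
            logger.warning(
                "dropping event at sample %d (%s): window [%d, %d) exceeds recording",
                onset, label, start, start + n_samp,
            )
            continue
        trials.append(rec.data[:, start : start + n_samp])
        labels.append(label)
    if not trials:
        raise ValueError("no events fit inside the recording")
    data = np.stack(trials)

    if baseline_ms is not None:
        in_base = (times_ms >= b0) & (times_ms < b1)
        data = data - data[:, :, in_base].mean(axis=2, keepdims=True)
    return EpochSet(data, times_ms, tuple(labels), rec.rate, rec.montage, baseline_ms)


def reject_artifact_epochs(
    epochs: EpochSet,
    peak_to_peak_uv: float = DEFAULT_REJECT_UV,
    return_log: bool = False,
):
    """Drop trials whose peak-to-peak range on any scalp channel exceeds
    the threshold; mastoid reference channels are not inspected."""
    if peak_to_peak_uv <= 0:
        raise ValueError("peak-to-peak threshold must be positive")
    scalp_idx = [epochs.montage.index(c) for c in epochs.montage.scalp_channels]
    ptp = epochs.data[:, scalp_idx, :].max(axis=2) - epochs.data[:, scalp_idx, :].min(axis=2)
    worst = ptp.max(axis=1)
    keep = worst <= peak_to_peak_uv
    if not keep.any():
        raise ValueError(
            f"all {epochs.n_trials} trials exceed {peak_to_peak_uv} uV peak-to-peak; "
            "review the rejection threshold"
        )
    surviving = pd.Series([l for l, k in zip(epochs.labels, keep) if k]).value_counts()
    logger.info("artifact rejection kept %d/%d trials: %s",
                int(keep.sum()), epochs.n_trials, surviving.to_dict())
    out = epochs.select(keep)
    if not return_log:
        return out
    worst_ch = np.asarray(epochs.montage.scalp_channels)[ptp.argmax(axis=1)]
    log = pd.DataFrame(
        {
            "trial": np.arange(epochs.n_trials),
            "channel": worst_ch,
            "peak_to_peak_uv": worst,
            "decision": np.where(keep, "keep", "reject"),
        }
    )
    return out, log


def interpolation_weights(montage: Montage, bad: str) -> tuple[list[int], np.ndarray]:
    """Inverse great-circle-distance weights over the good scalp channels."""
    good = [c for c in montage.scalp_channels if c != bad]
    if len(good) < 2:
        raise ValueError("need at least 2 good scalp channels to interpolate")
    dists = montage.great_circle_distances(bad)
    idx = [montage.index(c) for c in good]
    w = 1.0 / np.maximum(dists[idx], 1e-12)
    return idx, w / w.sum()


def interpolate_channel(epochs: EpochSet, bad: str) -> EpochSet:
    """Replace one scalp channel by the inverse-distance-weighted average of
    the remaining scalp channels (weights sum to one)."""
    bad_idx = epochs.montage.index(bad)
    idx, w = interpolation_weights(epochs.montage, bad)
    data = epochs.data.copy()
    data[:, bad_idx, :] = np.tensordot(w, epochs.data[:, idx, :], axes=(0, 1))
    return replace(epochs, data=data)


def preprocess_recording(
    rec: Recording,
    hp_hz: float = 0.1,
    lp_hz: float = 30.0,
    notch_hz: float | None = 50.0,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    baseline_ms: tuple[float, float] | None = DEFAULT_BASELINE_MS,
    reject_uv: float | None = DEFAULT_REJECT_UV,
    bad_channels: tuple[str, ...] = (),
    ica_hook: Callable[[Recording], Recording] | None = None,
) -> EpochSet:
    """The full default chain: re-reference, filter, (hook), epoch, reject,
    interpolate bad channels."""
    rec = rereference_to_mastoids(rec)
    rec = filter_recording(rec, hp_hz, lp_hz, notch_hz)
    if ica_hook is not None:
        rec = ica_hook(rec)
    epochs = epoch_recording(rec, window_ms, baseline_ms)
    if reject_uv is not None:
        epochs = reject_artifact_epochs(epochs, reject_uv)
    for bad in bad_channels:
        epochs = interpolate_channel(epochs, bad)
    return epochs
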