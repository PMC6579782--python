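"""Phase-locking-value (PLV) functional connectivity.

Instantaneous phase comes from the analytic signal (Hilbert transform) of
each trial, optionally after an extra zero-phase band-pass.  The PLV of a
channel pair is the across-trial mean resultant length of the phase
difference at each timepoint,

    PLV(t) = | (1/K) sum_k exp(i (phi_a,k(t) - phi_b,k(t))) |,

time-averaged over the post-stimulus window.  It is 1 for perfectly
locked pairs, and for K independent uniform phases its expectation is
sqrt(pi)/(2 sqrt(K)) — the finite-trial bias that motivates matching
trial counts between conditions before contrasting matrices.

By default no extra filtering is applied here: the preprocessing chain
has already restricted the recording to its analysis band, and a 1.2-s
epoch is too short to band-pass again at a 0.1 Hz low edge.  Pass
``band_hz`` explicitly to analyse a narrower band (low edge must fit at
least one cycle in the epoch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocessing import EpochSet

DEFAULT_PLV_WINDOW_MS = (0.0, 1000.0)


@dataclass(frozen=True)
class PhaseTensor:
    """Per-trial instantaneous phase, (trials, channels, time), radians."""

    phase: np.ndarray
    times_ms: np.ndarray
    labels: tuple[str, ...]
    channel_names: tuple[str, ...]
    rate: float
    band_hz: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        ph = np.asarray(self.phase, dtype=float)
        if ph.ndim != 3:
            raise ValueError("phase must be (trials, channels, time)")
        object.__setattr__(self, "phase", ph)

    @property
    def n_trials(self) -> int:
        return self.phase.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {list(self.channel_names)}") from None


@dataclass(frozen=True)
class PLVMatrix:
    """Symmetric channels x channels phase-locking matrix, diagonal 1."""

    plv: np.ndarray
    channel_names: tuple[str, ...]
    window_ms: tuple[float, float]
    n_trials: int
    subject: str = ""
    group: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.plv, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.channel_names):
            raise ValueError("plv must be square and match channel_names")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("plv must be symmetric")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValueError("plv entries must lie in [0, 1]")
        object.__setattr__(self, "plv", m)


def instantaneous_phase(
    epochs: EpochSet,
    band_hz: tuple[float, float] | None = None,
    scalp_only: bool = True,
) -> PhaseTensor:
    """Analytic-signal phase per trial/channel/timepoint.

    ``band_hz=None`` trusts the upstream filter band; otherwise a 4th-order
    zero-phase Butterworth band-pass is applied per trial first, and the
    epoch must hold at least one full cycle of the band's low edge.
    """
    if scalp_only:
        names = epochs.montage.scalp_channels
        rows = [epochs.montage.index(c) for c in names]
        data = epochs.data[:, rows, :]
    else:
        names = tuple(epochs.montage.channel_names)
        data = epochs.data
    if band_hz is not None:
        lo, hi = band_hz
        nyq = epochs.rate / 2.0
        if not (0 < lo < hi < nyq):
            raise ValueError(f"band {band_hz} outside (0, Nyquist={nyq})")
        epoch_s = data.shape[2] / epochs.rate
        if epoch_s * lo < 1.0:
            raise ValueError(
                f"epoch ({epoch_s:.2f} s) holds less than one cycle of the "
                f"band low edge ({lo} Hz); filter upstream instead"
            )
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=epochs.rate, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=2)
    phase = np.angle(signal.hilbert(data, axis=2))
    return PhaseTensor(phase, epochs.times_ms, epochs.labels, tuple(names), epochs.rate, band_hz)


def _window_columns(phases: PhaseTensor, window_ms: tuple[float, float]) -> np.ndarray:
    w0, w1 = window_ms
    sel = (phases.times_ms >= w0) & (phases.times_ms < w1)
    if not sel.any():
        raise ValueError(f"window {window_ms} ms selects no samples")
    return sel


def plv_pair(
    phases: PhaseTensor,
    ch_a: str,
    ch_b: str,
    window_ms: tuple[float, float] = DEFAULT_PLV_WINDOW_MS,
    trials: np.ndarray | None = None,
) -> float:
    """Time-averaged across-trial PLV of one channel pair."""
    ia, ib = phases.channel_index(ch_a), phases.channel_index(ch_b)
    sel = _window_columns(phases, window_ms)
    ph = phases.phase if trials is None else phases.phase[trials]
    if ph.shape[0] < 2:
        raise ValueError("PLV needs at least 2 trials (it is degenerate at 1)")
    dphi = ph[:, ia, :][:, sel] - ph[:, ib, :][:, sel]
    return float(np.abs(np.exp(1j * dphi).mean(axis=0)).mean())


def plv_matrix(
    phases: PhaseTensor,
    window_ms: tuple[float, float] = DEFAULT_PLV_WINDOW_MS,
    trials: np.ndarray | None = None,
    **labels,
) -> PLVMatrix:
    """PLV over all unordered channel pairs (vectorized), diagonal 1."""
    sel = _window_columns(phases, window_ms)
    ph = phases.phase if trials is None else phases.phase[trials]
    k = ph.shape[0]
    if k < 2:
        raise ValueError("PLV needs at least 2 trials (it is degenerate at 1)")
    z = np.exp(1j * ph[:, :, sel])
    resultant = np.einsum("kat,kbt->abt", z, z.conj(), optimize=True) / k
    m = np.abs(resultant).mean(axis=2)
    m = 0.5 * (m + m.T)  # exact symmetry against float noise
    np.fill_diagonal(m, 1.0)
    return PLVMatrix(np.clip(m, 0.0, 1.0), phases.channel_names, window_ms, k, **labels)


def condition_plv(
    phases: PhaseTensor,
    condition: str,
    window_ms: tuple[float, float] = DEFAULT_PLV_WINDOW_MS,
    n_trials: int | None = None,
    seed: int = 0,
    **labels,
) -> PLVMatrix:
    """PLV matrix of one (pooled) condition, optionally subsampled to a
    fixed trial count so matrices with different K are comparable."""
    from .synth import matches_condition

    idx = np.flatnonzero([matches_condition(l, condition) for l in phases.labels])
    if idx.size < 2:
        raise ValueError(f"condition {condition!r} has {idx.size} trials; need >= 2")
    if n_trials is not None and idx.size > n_trials:
        idx = np.sort(np.random.default_rng(seed).choice(idx, size=n_trials, replace=False))
    return plv_matrix(phases, window_ms, trials=idx, condition=condition, **labels)
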