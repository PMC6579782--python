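"""Synthetic emotional-oddball EEG generator.

Emulates a passive auditory oddball block — frequent neutral standards with
rare happy/angry deviants — recorded from a 10-20 cap, for three cohorts
(healthy controls, minimally conscious state, unresponsive wakefulness
syndrome).  Each synthetic subject is 1/f background noise plus per-event
ERP templates (frontal N1 and P3a, parieto-occipital LPP) plus, optionally,
a narrow-band oscillation shared between chosen channel pairs whose
trial-to-trial phase offset is von Mises distributed.  The von Mises
concentration kappa controls inter-channel phase locking with a closed-form
expected phase-locking value, the Bessel ratio I1(kappa)/I0(kappa), which
makes parameter recovery testable.

All generation is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import i0e, i1e

from .montage import FRONTAL, PARIETO_OCCIPITAL, Montage, standard_montage

STANDARD = "neutral"
DEVIANTS = ("happy", "angry")
CONDITIONS = (STANDARD,) + DEVIANTS

#: Pooled label for the two affective deviants; contrasts in this package
#: compare neutral vs emotional, never happy vs angry.
EMOTIONAL = "emotional"


def matches_condition(label: str, condition: str) -> bool:
    """Does an event label fall under a (possibly pooled) condition name?"""
    if condition == "all":
        return True
    if condition == EMOTIONAL:
        return label in DEVIANTS
    return label == condition


@dataclass(frozen=True)
class EventSequence:
    """Stimulus onsets (sample indices) and their condition labels."""

    onsets: np.ndarray  # int sample indices, strictly increasing
    labels: tuple[str, ...]
    inter_onset_ms: float = 2200.0  # 700 ms stimulus + 1500 ms ISI

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=np.int64)
        if onsets.ndim != 1 or len(onsets) != len(self.labels):
            raise ValueError("onsets and labels must have equal length")
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        unknown = set(self.labels) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown event labels: {sorted(unknown)}")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in CONDITIONS}


def generate_oddball_sequence(
    n_standard: int,
    n_happy: int,
    n_angry: int,
    seed: int,
    rate: float = 500.0,
    inter_onset_ms: float = 2200.0,
    start_ms: float = 1000.0,
) -> EventSequence:
    """Random oddball block with no two deviants in adjacent positions.

    Deviant slots are drawn uniformly from all non-adjacent arrangements
    (the gap construction: choose positions in a shortened sequence, then
    shift), and the happy/angry identities are randomly permuted over the
    chosen slots.  Onsets are regular at ``inter_onset_ms``.

    Feasibility requires ``n_standard >= n_happy + n_angry - 1``.
    """
    for name, n in (("n_standard", n_standard), ("n_happy", n_happy), ("n_angry", n_angry)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0, got {n}")
    n_dev = n_happy + n_angry
    n_total = n_standard + n_dev
    if n_total == 0:
        raise ValueError("at least one event is required")
    if n_dev > 0 and n_standard < n_dev - 1:
        raise ValueError(
            "no arrangement without adjacent deviants exists: requires "
            f"n_standard >= n_happy + n_angry - 1 ({n_standard} < {n_dev - 1})"
        )
    rng = np.random.default_rng(seed)
    labels = np.array([STANDARD] * n_total, dtype=object)
    if n_dev:
        slots = np.sort(rng.choice(n_total - n_dev + 1, size=n_dev, replace=False))
        slots = slots + np.arange(n_dev)  # re-inflate: guarantees gaps >= 1
        identities = rng.permutation(["happy"] * n_happy + ["angry"] * n_angry)
        labels[slots] = identities
    onsets = np.round(
        (start_ms + np.arange(n_total) * inter_onset_ms) * rate / 1000.0
    ).astype(np.int64)
    return EventSequence(onsets, tuple(labels), inter_onset_ms)


def expected_plv_from_kappa(kappa: float) -> float:
    """Asymptotic PLV of a von Mises phase-jitter model: I1(kappa)/I0(kappa).

    This is the mean resultant length of the jitter distribution, i.e. the
    phase-locking value an infinite number of trials would measure.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    if kappa == 0:
        return 0.0
    # exponentially scaled Bessels: the e^kappa factors cancel in the ratio
    return float(i1e(kappa) / i0e(kappa))


def finite_sample_plv(
    kappa: float, n_trials: int, n_sim: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo expectation (and SE) of the K-trial mean resultant length.

    A K-trial PLV estimate is positively biased (E ~ sqrt(pi)/(2 sqrt(K))
    at kappa=0); tests comparing measured PLV to theory at small K should
    use this finite-sample expectation rather than the Bessel ratio.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    rng = np.random.default_rng(seed)
    if kappa == 0:
        phases = rng.uniform(-np.pi, np.pi, size=(n_sim, n_trials))
    else:
        phases = rng.vonmises(0.0, kappa, size=(n_sim, n_trials))
    r = np.abs(np.exp(1j * phases).mean(axis=1))
    return float(r.mean()), float(r.std(ddof=1) / np.sqrt(n_sim))


@dataclass(frozen=True)
class CouplingSpec:
    """One phase-coupled channel pair, active on one (pooled) condition."""

    ch_a: str
    ch_b: str
    condition: str  # neutral / happy / angry / emotional / all
    kappa: float

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if self.condition not in CONDITIONS + (EMOTIONAL, "all"):
            raise ValueError(f"unknown coupling condition {self.condition!r}")


@dataclass(frozen=True)
class SubjectSpec:
    """Everything that determines one synthetic subject.

    erp_amplitudes maps component -> condition -> amplitude in microvolt;
    condition keys may be event labels or the pooled name "emotional".
    Negative amplitudes give negative deflections (the N1 convention).
    """

    group: str = "HC"
    erp_amplitudes: dict = field(default_factory=dict)
    coupling: tuple[CouplingSpec, ...] = ()
    coupling_freq_hz: float = 10.0
    coupling_amplitude_uv: float = 5.0
    noise_scale: float = 10.0  # microvolt RMS of the 1/f background
    seed: int = 0

    def amplitude(self, component: str, label: str) -> float:
        table = self.erp_amplitudes.get(component, {})
        if label in table:
            return float(table[label])
        if label in DEVIANTS and EMOTIONAL in table:
            return float(table[EMOTIONAL])
        return 0.0


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel EEG in microvolt with event markers."""

    data: np.ndarray  # (n_channels, n_samples)
    rate: float
    montage: Montage
    events: EventSequence

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data must be (n_channels={self.montage.n_channels}, n_samples), "
                f"got {data.shape}"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.events) and self.events.onsets[-1] >= data.shape[1]:
            raise ValueError("event onsets exceed recording length")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def one_over_f_noise(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS pink (1/f power) noise via spectral shaping."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * scale, n=n_samples)
    return x / np.sqrt(np.mean(x**2))


def _erp_templates(rate: float, duration_ms: float = 1000.0) -> dict[str, np.ndarray]:
    """Unit-peak post-stimulus component shapes sampled at ``rate``.

    N1: Gaussian at 150 ms (sigma 25 ms); P3a: Gaussian at 300 ms (sigma
    40 ms); LPP: 400-1000 ms plateau with 100 ms raised-cosine ramps.
    """
    n = int(round(duration_ms * rate / 1000.0))
    t = np.arange(n) * 1000.0 / rate  # ms after onset
    n1 = np.exp(-0.5 * ((t - 150.0) / 25.0) ** 2)
    p3a = np.exp(-0.5 * ((t - 300.0) / 40.0) ** 2)
    lpp = np.zeros_like(t)
    lpp[(t >= 500.0) & (t <= 900.0)] = 1.0
    up = (t >= 400.0) & (t < 500.0)
    lpp[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - 400.0) / 100.0))
    down = (t > 900.0) & (t <= 1000.0)
    lpp[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - 900.0) / 100.0))
    return {"N1": n1, "P3a": p3a, "LPP": lpp}


# the late positivity is broadest: highest over central parieto-occipital
# sites, so it is injected over the central row as well
COMPONENT_CHANNELS = {
    "N1": FRONTAL,
    "P3a": FRONTAL,
    "LPP": ("C3", "Cz", "C4") + PARIETO_OCCIPITAL,
}


def synthesize_subject(
    spec: SubjectSpec,
    montage: Montage | None = None,
    events: EventSequence | None = None,
    rate: float = 500.0,
) -> Recording:
    """Render one subject: pink noise + event-locked ERPs + coupled bursts.

    The coupled oscillation is a ``coupling_freq_hz`` cosine burst over the
    first second after each matching event: channel a receives a uniformly
    random trial phase, channel b the same phase plus a von Mises offset of
    concentration kappa, so the across-trial PLV of the pair tends to
    I1(kappa)/I0(kappa).
    """
    if montage is None:
        montage = standard_montage()
    if events is None:
        events = generate_oddball_sequence(86, 12, 12, seed=spec.seed)
    rng = np.random.default_rng(spec.seed)
    n_ev = int(round(1000.0 * rate / 1000.0))  # samples in the 1 s event window
    n_samples = int(events.onsets[-1]) + n_ev + int(rate)  # 1 s tail pad
    n_ch = montage.n_channels

    data = np.zeros((n_ch, n_samples))
    if spec.noise_scale > 0:
        for ch in range(n_ch):
            data[ch] = spec.noise_scale * one_over_f_noise(n_samples, rng)

    templates = _erp_templates(rate)
    scalp = set(montage.scalp_channels)
    comp_rows = {
        comp: [montage.index(c) for c in chans if c in scalp]
        for comp, chans in COMPONENT_CHANNELS.items()
    }
    for onset, label in zip(events.onsets, events.labels):
        for comp, template in templates.items():
            amp = spec.amplitude(comp, label)
            if amp == 0.0 or not comp_rows[comp]:
                continue
            seg = slice(onset, onset + n_ev)
            data[comp_rows[comp], seg] += amp * template

    t_abs = np.arange(n_samples) / rate
    omega = 2 * np.pi * spec.coupling_freq_hz
    for cp in spec.coupling:
        ia, ib = montage.index(cp.ch_a), montage.index(cp.ch_b)
        for onset, label in zip(events.onsets, events.labels):
            if not matches_condition(label, cp.condition):
                continue
            phi = rng.uniform(0, 2 * np.pi)
            delta = rng.vonmises(0.0, cp.kappa) if cp.kappa > 0 else rng.uniform(-np.pi, np.pi)
            seg = slice(onset, onset + n_ev)
            tt = omega * t_abs[seg]
            data[ia, seg] += spec.coupling_amplitude_uv * np.cos(tt + phi)
            data[ib, seg] += spec.coupling_amplitude_uv * np.cos(tt + phi + delta)

    return Recording(data, rate, montage, events)


def subject_seed(master_seed: int, group_index: int, subject_index: int) -> int:
    """Stable per-subject seed; adding subjects never perturbs existing ones."""
    ss = np.random.SeedSequence(entropy=(int(master_seed), group_index, subject_index))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_group_dataset(
    group_specs: dict[str, SubjectSpec],
    n_per_group: int,
    seed: int,
    montage: Montage | None = None,
    rate: float = 500.0,
    oddball_counts: tuple[int, int, int] = (86, 12, 12),
) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate ``n_per_group`` subjects per group from per-group templates.

    Returns the recordings plus a metadata table (subject, group, seed)
    aligned with the recording list.  Every subject gets its own stimulus
    order and noise realization, derived deterministically from ``seed``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if montage is None:
        montage = standard_montage()
    recordings: list[Recording] = []
    rows = []
    for gi, (group, template) in enumerate(group_specs.items()):
        for si in range(n_per_group):
            sseed = subject_seed(seed, gi, si)
            sub = replace(template, group=group, seed=sseed)
            events = generate_oddball_sequence(*oddball_counts, seed=sseed, rate=rate)
            recordings.append(synthesize_subject(sub, montage, events, rate))
            rows.append({"subject": f"{group}{si + 1:02d}", "group": group, "seed": sseed})
    return recordings, pd.DataFrame(rows)
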