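"""Run configuration: YAML-backed parameters for the whole pipeline.

Defaults reproduce the study design this package emulates: a 110-stimulus
oddball block (86 neutral / 12 happy / 12 angry), 500 Hz sampling,
0.1-30 Hz band-pass with a 50 Hz notch, half-open [-200, 1000) ms epochs
baselined on [-200, 0) ms, 150 uV peak-to-peak rejection, post-stimulus
0-1000 ms PLV window, 1000 permutations and q = 0.05 for the
mass-univariate FDR, alpha = 0.05 elsewhere.

The default group profiles encode the qualitative cohort signatures the
analyses should recover: healthy controls carry an emotional LPP and
strong emotional fronto-/parieto-occipital phase coupling; minimally
conscious patients an emotional P3a and weak temporal coupling; patients
with unresponsive wakefulness only an emotional N1 modulation plus a
faint temporal coupling that should surface uncorrected but not survive
Bonferroni.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .synth import CouplingSpec, SubjectSpec

GROUPS = ("HC", "MCS", "UWS")


def default_group_specs() -> dict[str, SubjectSpec]:
    """The three cohort templates (amplitudes in microvolt, kappa unitless)."""
    hc_pairs = [("F3", "O1"), ("F4", "O2"), ("Fz", "Oz"),
                ("P3", "O1"), ("P4", "O2"), ("Pz", "Oz")]
    mcs_pairs = [("T7", "P7"), ("T8", "P8")]
    return {
        "HC": SubjectSpec(
            group="HC",
            erp_amplitudes={
                "N1": {"neutral": -3.0, "emotional": -4.0},
                "P3a": {"neutral": 2.0, "emotional": 2.5},
                "LPP": {"neutral": 1.0, "emotional": 8.0},
            },
            coupling=tuple(CouplingSpec(a, b, "emotional", 8.0) for a, b in hc_pairs),
        ),
        "MCS": SubjectSpec(
            group="MCS",
            erp_amplitudes={
                "N1": {"neutral": -3.0, "emotional": -4.0},
                "P3a": {"neutral": 2.0, "emotional": 5.0},
            },
            coupling=tuple(CouplingSpec(a, b, "emotional", 2.0) for a, b in mcs_pairs),
        ),
        "UWS": SubjectSpec(
            group="UWS",
            erp_amplitudes={"N1": {"neutral": -2.0, "emotional": -4.0}},
            coupling=(CouplingSpec("T7", "T8", "emotional", 0.5),),
        ),
    }


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, validated before any stage."""

    seed: int = 0
    # simulation
    n_per_group: int = 15
    rate: float = 500.0
    oddball_counts: tuple[int, int, int] = (86, 12, 12)
    noise_scale: float = 10.0  # uV RMS pink background
    coupling_freq_hz: float = 10.0
    coupling_amplitude_uv: float = 20.0
    # preprocessing
    hp_hz: float = 0.1
    lp_hz: float = 30.0
    notch_hz: float | None = 50.0
    window_ms: tuple[float, float] = (-200.0, 1000.0)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    reject_uv: float | None = 150.0
    # PLV
    plv_band_hz: tuple[float, float] | None = None  # None: the filter band
    plv_window_ms: tuple[float, float] = (0.0, 1000.0)
    match_trial_counts: bool = True
    # statistics
    n_perm: int = 1000
    q: float = 0.05
    alpha: float = 0.05
    with_sigma: bool = False
    n_rand: int = 20

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nyq = self.rate / 2.0
        if not (0 < self.hp_hz < self.lp_hz < nyq):
            raise ValueError("need 0 < hp < lp < Nyquist")
        if self.notch_hz is not None and not (0 < self.notch_hz < nyq):
            raise ValueError("notch frequency outside (0, Nyquist)")
        w0, w1 = self.window_ms
        b0, b1 = self.baseline_ms
        if not (w0 <= b0 < b1 <= w1):
            raise ValueError("baseline must lie within the epoch window")
        p0, p1 = self.plv_window_ms
        if not (w0 <= p0 < p1 <= w1):
            raise ValueError("PLV window must lie within the epoch window")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if any(c < 0 for c in self.oddball_counts):
            raise ValueError("oddball counts must be >= 0")
        if not (0 < self.q < 1 and 0 < self.alpha < 1):
            raise ValueError("q and alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must be in [0, 2**31)")

    def group_specs(self) -> dict[str, SubjectSpec]:
        specs = {}
        for name, spec in default_group_specs().items():
            specs[name] = SubjectSpec(
                group=name,
                erp_amplitudes=spec.erp_amplitudes,
                coupling=spec.coupling,
                coupling_freq_hz=self.coupling_freq_hz,
                coupling_amplitude_uv=self.coupling_amplitude_uv,
                noise_scale=self.noise_scale,
            )
        return specs

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("oddball_counts", "window_ms", "baseline_ms", "plv_window_ms",
                    "plv_band_hz"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("oddball_counts", "window_ms", "baseline_ms", "plv_window_ms",
                    "plv_band_hz"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
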