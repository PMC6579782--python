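"""Event-related potential statistics.

Condition averages, mass-univariate paired tests over every
(channel, timepoint) cell with sign-flip permutation p-values and
Benjamini-Yekutieli false-discovery-rate adjustment, and mean-amplitude
component measurement (N1, P3a, LPP).

The test statistic is the ordinary paired t, but its p-value comes from
the permutation distribution obtained by flipping the sign of each
subject's condition difference: the exact null for exchangeable paired
data.  All 2^n flips are enumerated when n <= 12; otherwise ``n_perm``
random flips are drawn and the add-one estimate p = (b + 1) / (m + 1)
is used.  The Benjamini-Yekutieli step-up (valid under arbitrary
dependence, at the price of the harmonic-sum factor c(m) = sum 1/i)
then controls FDR across all cells of one contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .montage import FRONTAL, PARIETO_OCCIPITAL
from .preprocessing import EpochSet

EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class ERPWaveform:
    """Trial-average waveform for one condition: (channels, time) microvolt."""

    mean: np.ndarray
    n_trials: int
    condition: str
    times_ms: np.ndarray
    channel_names: tuple[str, ...]


@dataclass(frozen=True)
class MassUnivariateResult:
    """Per-cell t, raw permutation p, BY-adjusted p and the q<0.05 mask."""

    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    sig_mask: np.ndarray
    n_perm: int
    q: float


#: Default measurement windows (ms) and channel groups per component.
COMPONENT_DEFAULTS = {
    "N1": ((100.0, 200.0), FRONTAL),
    "P3a": ((250.0, 400.0), FRONTAL),  # window not standardized; configurable
    "LPP": ((400.0, 1000.0), PARIETO_OCCIPITAL),
}


@dataclass(frozen=True)
class ComponentMeasure:
    component: str
    window_ms: tuple[float, float]
    channels: tuple[str, ...]

    @classmethod
    def default(cls, component: str) -> "ComponentMeasure":
        window, channels = COMPONENT_DEFAULTS[component]
        return cls(component, window, tuple(channels))


def condition_average(epochs: EpochSet, condition: str) -> ERPWaveform:
    """Arithmetic trial average of one (possibly pooled) condition."""
    mask = epochs.condition_trials(condition)
    if not mask.any():
        raise ValueError(
            f"no trials with condition {condition!r}; present: {sorted(set(epochs.labels))}"
        )
    return ERPWaveform(
        mean=epochs.data[mask].mean(axis=0),
        n_trials=int(mask.sum()),
        condition=condition,
        times_ms=epochs.times_ms,
        channel_names=tuple(epochs.montage.channel_names),
    )


def by_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values (step-up with c(m) = sum 1/i)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p.ravel(), method="fdr_by")
    return p_adj.reshape(p.shape)


def _paired_t_from_diff(d_mean: np.ndarray, d_ss: np.ndarray, n: int) -> np.ndarray:
    # sum of squares about the mean; invariant pieces precomputed by caller
    var = (d_ss - n * d_mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d_mean / np.sqrt(var / n)
        t = np.where(
            var == 0, np.where(d_mean == 0, 0.0, np.where(d_mean > 0, np.inf, -np.inf)), t
        )
    return t


def mass_univariate_paired_t(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int | None = None,
) -> MassUnivariateResult:
    """Paired sign-flip permutation t-test at every cell, BY-corrected.

    ``values_a``/``values_b`` are per-subject arrays with the subject on
    the first axis and any cell layout after it (e.g. channels x time);
    subjects must be aligned.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 paired subjects")
    cell_shape = a.shape[1:]
    d = (a - b).reshape(n, -1)
    m_cells = d.shape[1]

    d_ss = (d**2).sum(axis=0)  # invariant under sign flips
    t_obs = _paired_t_from_diff(d.mean(axis=0), d_ss, n)

    if n <= EXACT_ENUMERATION_MAX_N:
        signs = np.array(
            [[1 if (k >> i) & 1 else -1 for i in range(n)] for k in range(2**n)],
            dtype=float,
        )
        perm_means = signs @ d / n
        t_perm = _paired_t_from_diff(perm_means, d_ss[None, :], n)
        exceed = (np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
        p_raw = exceed / signs.shape[0]
        n_used = signs.shape[0]
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        perm_means = signs @ d / n
        t_perm = _paired_t_from_diff(perm_means, d_ss[None, :], n)
        exceed = (np.abs(t_perm) >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
        p_raw = (exceed + 1) / (n_perm + 1)
        n_used = n_perm

    p_adj = by_adjust(p_raw)
    return MassUnivariateResult(
        t=t_obs.reshape(cell_shape),
        p_raw=p_raw.reshape(cell_shape),
        p_adj=p_adj.reshape(cell_shape),
        sig_mask=(p_adj < q).reshape(cell_shape),
        n_perm=n_used,
        q=q,
    )


def measure_component(erp: ERPWaveform, measure: ComponentMeasure) -> float:
    """Mean amplitude over the component's window x channel set (microvolt)."""
    w0, w1 = measure.window_ms
    in_window = (erp.times_ms >= w0) & (erp.times_ms < w1)
    if not in_window.any():
        raise ValueError(
            f"window [{w0}, {w1}) ms lies outside the epoch "
            f"[{erp.times_ms[0]}, {erp.times_ms[-1]}] ms"
        )
    rows = []
    for c in measure.channels:
        if c in erp.channel_names:
            rows.append(erp.channel_names.index(c))
    if not rows:
        raise ValueError(f"none of {measure.channels} present in the waveform")
    return float(erp.mean[np.ix_(rows, np.flatnonzero(in_window))].mean())
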