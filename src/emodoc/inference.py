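"""Group-level statistics: 3 x 2 mixed repeated-measures ANOVA with
Mauchly / Greenhouse-Geisser sphericity handling, Bonferroni post hocs,
per-group simple effects, and edge-wise PLV contrasts.

The ANOVA is the classical univariate mixed design: one between-subject
factor (group) tested against the subject-within-group mean square, one
within-subject factor (stimulation condition) and the interaction tested
against the condition x subject-within-group mean square.  Greenhouse-
Geisser epsilon multiplies both degrees of freedom of the within-subject
tests; with only two conditions a single within-subject contrast exists,
sphericity holds trivially, epsilon is exactly 1 and Mauchly's test is
reported as not applicable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject", "group", "condition", "value")


def validate_property_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (subject, group, condition, value) long-format contract."""
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"property table lacks columns {sorted(missing)}")
    if table["value"].isna().any():
        raise ValueError("missing values are not allowed (no imputation)")
    conditions = sorted(table["condition"].unique())
    per_subject = table.groupby("subject")["condition"].agg(lambda s: sorted(s))
    bad = per_subject[per_subject.apply(lambda c: c != conditions)]
    if len(bad):
        raise ValueError(
            f"incomplete within-subject data for subjects {list(bad.index)}: "
            f"each needs exactly one row per condition {conditions}"
        )
    n_groups = table.groupby("subject")["group"].nunique()
    if (n_groups > 1).any():
        raise ValueError("each subject must belong to exactly one group")
    return table


def _wide(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """-> (values subjects x conditions, group label per subject, conditions)."""
    validate_property_table(table)
    wide = table.pivot(index="subject", columns="condition", values="value")
    groups = table.drop_duplicates("subject").set_index("subject")["group"]
    groups = groups.loc[wide.index]
    return wide.to_numpy(), groups.to_numpy(), list(wide.columns)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis.T)
    return q[:, : k - 1].T


def mauchly_test(within: np.ndarray) -> tuple[float, float, int, float | None]:
    """Mauchly's sphericity test on subjects x k condition data.

    Returns (W, chi2, df, p); for k = 2 the single within-subject contrast
    makes sphericity automatic and p is None (not applicable).
    """
    y = np.asarray(within, dtype=float)
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n <= k:
        raise ValueError(f"need more subjects ({n}) than conditions ({k})")
    if k == 2:
        return 1.0, 0.0, 0, None
    c = _orthonormal_contrasts(k)
    s = c @ np.cov(y, rowvar=False) @ c.T
    p_dim = k - 1
    w = float(np.linalg.det(s) / (np.trace(s) / p_dim) ** p_dim)
    d = 1 - (2 * p_dim**2 + p_dim + 2) / (6.0 * p_dim * (n - 1))
    chi2 = -(n - 1) * d * np.log(max(w, np.finfo(float).tiny))
    df = int(p_dim * (p_dim + 1) / 2 - 1)
    p = float(stats.chi2.sf(chi2, df))
    return w, float(chi2), df, p


def gg_epsilon(within: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon, clipped to [1/(k-1), 1]."""
    y = np.asarray(within, dtype=float)
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if k == 2:
        return 1.0
    if n <= k:
        raise ValueError(f"need more subjects ({n}) than conditions ({k})")
    c = _orthonormal_contrasts(k)
    s = c @ np.cov(y, rowvar=False) @ c.T
    eps = np.trace(s) ** 2 / ((k - 1) * np.trace(s @ s))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


@dataclass(frozen=True)
class RmAnovaResult:
    """Mixed-design ANOVA table plus sphericity diagnostics."""

    effects: pd.DataFrame  # index: group / stimulation / interaction
    epsilon_gg: float
    mauchly_w: float
    mauchly_p: float | None  # None when not applicable (k = 2)

    def to_dict(self) -> dict:
        out = {
            eff: {
                k: (None if pd.isna(v) else (v if isinstance(v, str) else float(v)))
                for k, v in row.items()
            }
            for eff, row in self.effects.iterrows()
        }
        out["sphericity"] = {
            "epsilon_gg": self.epsilon_gg,
            "mauchly_W": self.mauchly_w,
            "mauchly_p": self.mauchly_p if self.mauchly_p is not None else "not applicable",
        }
        return out


def _f_ratio(ss_eff, df_eff, ss_err, df_err) -> tuple[float, float]:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f = 0.0 if ms_eff <= 0 else np.inf
        logger.warning("zero error mean square: F reported as %s", f)
    else:
        f = ms_eff / ms_err
    p = float(stats.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
    if f == 0.0 and ms_err <= 0:
        p = 1.0
    return float(f), p


def mixed_rm_anova(table: pd.DataFrame) -> RmAnovaResult:
    """One between-subject factor, one within-subject factor, complete data.

    Handles unequal group sizes (weighted-means decomposition; with a
    single between factor and complete within data this matches the
    classical mixed-model sums of squares).
    """
    y, groups, conditions = _wide(table)
    n, k = y.shape
    labels, counts = np.unique(groups, return_counts=True)
    a = len(labels)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 subjects")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[groups == g].mean() for g in labels])
    cond_means = y.mean(axis=0)
    cell_means = np.vstack([y[groups == g].mean(axis=0) for g in labels])

    ss_group = k * float(counts @ (group_means - grand) ** 2)
    ss_subj = k * float(
        sum(((subj_means[groups == g] - gm) ** 2).sum() for g, gm in zip(labels, group_means))
    )
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    # interaction = cell means minus both margins (cross terms vanish even
    # with unequal group sizes because every subject has every condition)
    inter_dev = cell_means - group_means[:, None] - cond_means[None, :] + grand
    ss_inter = float((counts[:, None] * inter_dev**2).sum())
    # within-cell residual: Y - cell mean - subject mean + group mean
    gi = np.array([labels.tolist().index(g) for g in groups])
    cell_per_subj = cell_means[gi]
    resid = y - cell_per_subj - subj_means[:, None] + group_means[gi][:, None]
    ss_err = float((resid**2).sum())

    # sums of squares that are pure cancellation noise are exact zeros
    tol = 1e-12 * max(float(((y - grand) ** 2).sum()), np.finfo(float).tiny)
    ss_group, ss_subj, ss_cond, ss_inter, ss_err = (
        0.0 if ss < tol else ss
        for ss in (ss_group, ss_subj, ss_cond, ss_inter, ss_err)
    )

    df_group, df_subj = a - 1, n - a
    df_cond, df_inter = k - 1, (a - 1) * (k - 1)
    df_err = (n - a) * (k - 1)

    f_g, p_g = _f_ratio(ss_group, df_group, ss_subj, df_subj)
    f_c, p_c = _f_ratio(ss_cond, df_cond, ss_err, df_err)
    f_i, p_i = _f_ratio(ss_inter, df_inter, ss_err, df_err)

    eps = gg_epsilon(y) if k > 2 else 1.0
    w, _, _, mauchly_p = mauchly_test(y)

    def p_gg(f, d1, d2):
        if not np.isfinite(f):
            return 0.0
        return float(stats.f.sf(f, eps * d1, eps * d2))

    effects = pd.DataFrame(
        {
            "F": [f_g, f_c, f_i],
            "df_num": [df_group, df_cond, df_inter],
            "df_den": [df_subj, df_err, df_err],
            "p": [p_g, p_c, p_i],
            "p_gg": [p_g, p_gg(f_c, df_cond, df_err), p_gg(f_i, df_inter, df_err)],
        },
        index=["group", "stimulation", "group x stimulation"],
    )
    return RmAnovaResult(effects, eps, w, mauchly_p)


def bonferroni_posthoc(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise group contrasts on subject means, Bonferroni-adjusted."""
    y, groups, _ = _wide(table)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("post hoc needs at least 2 groups")
    subj_means = y.mean(axis=1)
    pairs = list(combinations(labels, 2))
    rows = []
    for ga, gb in pairs:
        t, p = stats.ttest_ind(subj_means[groups == ga], subj_means[groups == gb])
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "t": float(t),
                "p_raw": float(p),
                "p_adj": min(1.0, float(p) * len(pairs)),
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_adj"] < alpha
    return out


def simple_effects(
    table: pd.DataFrame,
    conditions: tuple[str, str] = ("emotional", "neutral"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group paired t of condition A minus B, Bonferroni over groups."""
    validate_property_table(table)
    groups = sorted(table["group"].unique())
    rows = []
    for g in groups:
        sub = table[table["group"] == g].pivot(
            index="subject", columns="condition", values="value"
        )
        if len(sub) < 2:
            logger.warning("group %s has %d subject(s); simple effect skipped", g, len(sub))
            continue
        d = sub[conditions[0]] - sub[conditions[1]]
        t, p = stats.ttest_rel(sub[conditions[0]], sub[conditions[1]])
        if np.isnan(t):  # zero-variance difference
            t, p = 0.0, 1.0
        rows.append(
            {
                "group": g,
                "mean_difference": float(d.mean()),
                "t": float(t),
                "p_raw": float(p),
                "p_adj": min(1.0, float(p) * len(groups)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = out["p_adj"] < alpha
    return out


@dataclass(frozen=True)
class EdgeComparisonResult:
    """Per-edge t statistics with uncorrected and Bonferroni masks."""

    edges: pd.DataFrame  # ch_a, ch_b, t, p, direction, sig_uncorrected, sig_bonferroni
    n_edges: int
    paired: bool
    alpha: float

    @property
    def n_uncorrected(self) -> int:
        return int(self.edges["sig_uncorrected"].sum())

    @property
    def n_bonferroni(self) -> int:
        return int(self.edges["sig_bonferroni"].sum())


def _triu_vectors(mats) -> tuple[np.ndarray, list[tuple[str, str]]]:
    names = mats[0].channel_names
    for m in mats:
        if m.channel_names != names:
            raise ValueError("PLV matrices disagree on channel names")
    iu = np.triu_indices(len(names), k=1)
    vec = np.stack([m.plv[iu] for m in mats])
    pairs = [(names[i], names[j]) for i, j in zip(*iu)]
    return vec, pairs


def edgewise_contrast(
    a: list,
    b: list,
    paired: bool = True,
    alpha: float = 0.05,
    method: str = "t",
    n_perm: int = 1000,
    seed: int | None = None,
) -> EdgeComparisonResult:
    """Edge-by-edge contrast of two sets of PLV matrices.

    ``method="t"`` uses parametric paired / two-sample t-tests;
    ``method="permutation"`` (paired only) replaces the p-values with
    sign-flip permutation p-values from the same t statistic.
    """
    if not a or not b:
        raise ValueError("both matrix lists must be non-empty")
    va, pairs = _triu_vectors(a)
    vb, _ = _triu_vectors(b)
    if va.shape[1] != vb.shape[1]:
        raise ValueError("matrix sizes differ between the two sets")
    if paired and va.shape[0] != vb.shape[0]:
        raise ValueError("paired contrast needs equally many matrices, aligned by subject")

    if paired:
        mean_diff = (va - vb).mean(axis=0)
        if method == "permutation":
            from .erp import mass_univariate_paired_t

            res = mass_univariate_paired_t(va, vb, n_perm=n_perm, seed=seed)
            t, p = res.t, res.p_raw
        else:
            d = va - vb
            n = d.shape[0]
            sd = d.std(axis=0, ddof=1)
            md = d.mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = md / (sd / np.sqrt(n))
                t = np.where(sd == 0, np.where(md == 0, 0.0, np.where(md > 0, np.inf, -np.inf)), t)
            p = np.where(np.isfinite(t), 2 * stats.t.sf(np.abs(t), n - 1), 0.0)
            p = np.where(t == 0, 1.0, p)
    else:
        if method == "permutation":
            raise NotImplementedError("permutation p-values are only offered for paired contrasts")
        t, p = stats.ttest_ind(va, vb, axis=0)
        t = np.nan_to_num(t, nan=0.0)
        p = np.where(t == 0, 1.0, np.nan_to_num(p, nan=1.0))
        mean_diff = va.mean(axis=0) - vb.mean(axis=0)

    m = len(pairs)
    edges = pd.DataFrame(
        {
            "ch_a": [x for x, _ in pairs],
            "ch_b": [y for _, y in pairs],
            "t": t,
            "p": p,
            "direction": np.where(mean_diff >= 0, "increase", "decrease"),
            "sig_uncorrected": p < alpha,
            "sig_bonferroni": p < alpha / m,
        }
    )
    return EdgeComparisonResult(edges, m, paired, alpha)


def demographics_tests(continuous_a, continuous_b, counts_2x2=None) -> dict:
    """Thin utility: independent-samples t for a continuous variable and a
    chi-square for a 2x2 count table (cohort comparability checks)."""
    t, p = stats.ttest_ind(continuous_a, continuous_b)
    out = {"t": float(t), "p_t": float(p)}
    if counts_2x2 is not None:
        chi2, p_chi, _, _ = stats.chi2_contingency(np.asarray(counts_2x2))
        out.update({"chi2": float(chi2), "p_chi2": float(p_chi)})
    return out
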