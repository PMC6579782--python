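"""Mixed RM-ANOVA, sphericity diagnostics, post hocs, simple effects and
edge-wise contrasts."""

import numpy as np
import pandas as pd
import pytest

from emodoc.inference import (
    bonferroni_posthoc,
    edgewise_contrast,
    gg_epsilon,
    mauchly_test,
    mixed_rm_anova,
    simple_effects,
    validate_property_table,
)
from emodoc.plv import PLVMatrix


def make_table(values_by_group, conditions=("neutral", "emotional")):
    """values_by_group: {group: array (n_subjects, n_conditions)}."""
    rows = []
    for group, vals in values_by_group.items():
        for s, row in enumerate(np.atleast_2d(vals)):
            for c, v in zip(conditions, row):
                rows.append(
                    {"subject": f"{group}{s:02d}", "group": group, "condition": c, "value": v}
                )
    return pd.DataFrame(rows)


def anova_ss_oracle(values_by_group):
    """Literal sums-of-squares decomposition with explicit loops."""
    groups = list(values_by_group)
    k = np.atleast_2d(values_by_group[groups[0]]).shape[1]
    all_vals = np.concatenate([np.atleast_2d(v) for v in values_by_group.values()])
    n = all_vals.shape[0]
    grand = all_vals.mean()

    ss_group = 0.0
    ss_subj = 0.0
    for g in groups:
        y = np.atleast_2d(values_by_group[g])
        gm = y.mean()
        ss_group += y.shape[0] * k * (gm - grand) ** 2
        for s in range(y.shape[0]):
            ss_subj += k * (y[s].mean() - gm) ** 2
    ss_cond = 0.0
    for c in range(k):
        ss_cond += n * (all_vals[:, c].mean() - grand) ** 2
    ss_inter = 0.0
    ss_err = 0.0
    for g in groups:
        y = np.atleast_2d(values_by_group[g])
        gm = y.mean()
        for c in range(k):
            cell = y[:, c].mean()
            margin_c = all_vals[:, c].mean()
            ss_inter += y.shape[0] * (cell - gm - margin_c + grand) ** 2
            for s in range(y.shape[0]):
                ss_err += (y[s, c] - cell - y[s].mean() + gm) ** 2

    a = len(groups)
    df = {
        "group": (a - 1, n - a),
        "stimulation": (k - 1, (n - a) * (k - 1)),
        "interaction": ((a - 1) * (k - 1), (n - a) * (k - 1)),
    }
    f = {
        "group": (ss_group / df["group"][0]) / (ss_subj / df["group"][1]),
        "stimulation": (ss_cond / df["stimulation"][0]) / (ss_err / df["stimulation"][1]),
        "interaction": (ss_inter / df["interaction"][0]) / (ss_err / df["interaction"][1]),
    }
    return f, df


class TestMixedAnova:
    def test_no_condition_effect_gives_zero_f(self, rng):
        base = {g: rng.normal(size=5) for g in ("HC", "MCS", "UWS")}
        table = make_table({g: np.column_stack([v, v]) for g, v in base.items()})
        res = mixed_rm_anova(table)
        assert res.effects.loc["stimulation", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_degenerate_group_offsets_flagged(self):
        vals = {
            "HC": np.full((3, 2), 1.0),
            "MCS": np.full((3, 2), 2.0),
            "UWS": np.full((3, 2), 3.0),
        }
        res = mixed_rm_anova(make_table(vals))
        assert np.isinf(res.effects.loc["group", "F"])
        assert res.effects.loc["group x stimulation", "F"] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_ss_oracle_balanced(self, seed):
        rng = np.random.default_rng(seed)
        vals = {g: rng.normal(gi, 1.0, size=(5, 2)) for gi, g in enumerate(("HC", "MCS", "UWS"))}
        res = mixed_rm_anova(make_table(vals))
        f_oracle, df_oracle = anova_ss_oracle(vals)
        assert res.effects.loc["group", "F"] == pytest.approx(f_oracle["group"], abs=1e-8)
        assert res.effects.loc["stimulation", "F"] == pytest.approx(f_oracle["stimulation"], abs=1e-8)
        assert res.effects.loc["group x stimulation", "F"] == pytest.approx(
            f_oracle["interaction"], abs=1e-8
        )
        assert tuple(res.effects.loc["group", ["df_num", "df_den"]]) == df_oracle["group"]
        assert res.epsilon_gg == 1.0  # forced at k = 2
        assert res.mauchly_p is None

    def test_matches_pingouin_cross_check(self, rng):
        pg = pytest.importorskip("pingouin")
        vals = {g: rng.normal(gi * 0.5, 1.0, size=(6, 2)) for gi, g in enumerate(("HC", "MCS", "UWS"))}
        table = make_table(vals)
        res = mixed_rm_anova(table)
        ref = pg.mixed_anova(
            table, dv="value", within="condition", subject="subject", between="group"
        ).set_index("Source")
        assert res.effects.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-8)
        assert res.effects.loc["stimulation", "F"] == pytest.approx(
            ref.loc["condition", "F"], rel=1e-8
        )
        assert res.effects.loc["group x stimulation", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-8
        )

    def test_unbalanced_groups_supported(self, rng):
        vals = {
            "HC": rng.normal(size=(15, 2)),
            "MCS": rng.normal(size=(9, 2)),
            "UWS": rng.normal(size=(6, 2)),
        }
        res = mixed_rm_anova(make_table(vals))
        assert np.isfinite(res.effects["F"]).all()
        assert res.effects.loc["group", "df_den"] == 27

    def test_condition_label_swap_preserves_f(self, rng):
        vals = {g: rng.normal(size=(5, 2)) for g in ("HC", "MCS")}
        t1 = make_table(vals, conditions=("neutral", "emotional"))
        t2 = make_table({g: v[:, ::-1] for g, v in vals.items()},
                        conditions=("neutral", "emotional"))
        r1, r2 = mixed_rm_anova(t1), mixed_rm_anova(t2)
        np.testing.assert_allclose(r1.effects["F"], r2.effects["F"], atol=1e-10)

    def test_missing_cell_raises(self, rng):
        table = make_table({"HC": rng.normal(size=(3, 2))}).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            validate_property_table(table)


class TestSphericity:
    def test_two_conditions_not_applicable(self, rng):
        w, chi2, df, p = mauchly_test(rng.normal(size=(10, 2)))
        assert w == 1.0 and p is None
        assert gg_epsilon(rng.normal(size=(10, 2))) == 1.0

    def test_spherical_covariance_w_near_one(self, rng):
        y = rng.normal(size=(200, 3))  # identity covariance is spherical
        w, _, _, p = mauchly_test(y)
        assert w > 0.9 and p > 0.05

    def test_w_matches_determinant_trace_oracle(self, rng):
        y = rng.normal(size=(12, 3)) @ np.array([[1, 0.3, 0], [0, 1, 0.2], [0, 0, 1.5]])
        w, _, df, _ = mauchly_test(y)
        # independent evaluation from the contrast covariance eigenvalues
        from emodoc.inference import _orthonormal_contrasts

        c = _orthonormal_contrasts(3)
        s = c @ np.cov(y, rowvar=False) @ c.T
        lam = np.linalg.eigvalsh(s)
        w_oracle = np.prod(lam) / (lam.mean() ** len(lam))
        assert w == pytest.approx(w_oracle, rel=1e-10)
        assert df == 2

    def test_epsilon_spherical_near_one_and_bounds(self, rng):
        y = rng.normal(size=(300, 4))
        assert gg_epsilon(y) > 0.9
        # maximally non-spherical: all variance in one contrast direction
        base = rng.normal(size=(20, 1))
        y_bad = np.hstack([base, -base, np.zeros((20, 1))]) + rng.normal(scale=1e-6, size=(20, 3))
        assert gg_epsilon(y_bad) == pytest.approx(0.5, abs=1e-3)

    def test_too_few_subjects_raise(self, rng):
        with pytest.raises(ValueError):
            mauchly_test(rng.normal(size=(3, 3)))


class TestPosthocAndSimpleEffects:
    def test_three_groups_three_comparisons_times_three(self, rng):
        vals = {g: rng.normal(size=(6, 2)) for g in ("HC", "MCS", "UWS")}
        out = bonferroni_posthoc(make_table(vals))
        assert len(out) == 3
        np.testing.assert_allclose(out["p_adj"], np.minimum(1.0, out["p_raw"] * 3))
        assert np.all(out["p_adj"] >= out["p_raw"])

    def test_null_simulation_controls_type_one(self):
        hits = 0
        n_runs = 200
        for s in range(n_runs):
            rng = np.random.default_rng(s)
            vals = {g: rng.normal(size=(10, 2)) for g in ("HC", "MCS", "UWS")}
            out = bonferroni_posthoc(make_table(vals))
            hits += int((out["p_adj"] < 0.05).any())
        assert hits / n_runs <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_runs)

    def test_simple_effect_detects_hc_only_shift(self):
        detected = {"HC": 0, "MCS": 0, "UWS": 0}
        n_runs = 50
        for s in range(n_runs):
            rng = np.random.default_rng(1000 + s)
            vals = {g: np.tile(rng.normal(size=(15, 1)), (1, 2)) + rng.normal(scale=1.0, size=(15, 2))
                    for g in ("HC", "MCS", "UWS")}
            vals["HC"][:, 1] += 2.0  # 2 SD shift in the emotional condition
            out = simple_effects(make_table(vals)).set_index("group")
            for g in detected:
                detected[g] += int(out.loc[g, "p_adj"] < 0.05)
        assert detected["HC"] / n_runs > 0.9
        assert detected["MCS"] / n_runs < 0.2 and detected["UWS"] / n_runs < 0.2

    def test_single_group_table(self, rng):
        out = simple_effects(make_table({"HC": rng.normal(size=(5, 2))}))
        assert list(out["group"]) == ["HC"]


def _mats(arrays, names):
    return [
        PLVMatrix(0.5 * (a + a.T), names, (0.0, 1000.0), 10, subject=str(i))
        for i, a in enumerate(arrays)
    ]


class TestEdgewiseContrast:
    names = ("F3", "F4", "O1", "O2")

    def _random_mats(self, rng, n, base=0.3):
        out = []
        for _ in range(n):
            a = np.clip(base + rng.normal(scale=0.02, size=(4, 4)), 0, 1)
            a = 0.5 * (a + a.T)
            np.fill_diagonal(a, 1.0)
            out.append(a)
        return out

    def test_identical_sets_empty_masks(self, rng):
        mats = _mats(self._random_mats(rng, 5), self.names)
        res = edgewise_contrast(mats, mats, paired=True)
        assert res.n_uncorrected == 0 and res.n_bonferroni == 0

    def test_single_shifted_edge_flagged_increase(self, rng):
        base = self._random_mats(rng, 15)
        shifted = []
        for a in base:
            b = a.copy()
            b[0, 2] += 0.3
            b[2, 0] += 0.3
            shifted.append(np.clip(b, 0, 1))
        res = edgewise_contrast(_mats(shifted, self.names), _mats(base, self.names), paired=True)
        edges = res.edges.set_index(["ch_a", "ch_b"])
        hit = edges.loc[("F3", "O1")]
        assert bool(hit["sig_bonferroni"]) and hit["direction"] == "increase"
        others = edges.drop(index=("F3", "O1"))
        assert not others["sig_bonferroni"].any()

    def test_bonferroni_subset_of_uncorrected(self, rng):
        a = _mats(self._random_mats(rng, 8), self.names)
        b = _mats(self._random_mats(rng, 8, base=0.32), self.names)
        res = edgewise_contrast(a, b, paired=False)
        assert (res.edges["sig_bonferroni"] <= res.edges["sig_uncorrected"]).all()

    def test_permutation_flag_agrees_in_rank(self, rng):
        a = _mats(self._random_mats(rng, 10), self.names)
        b = _mats(self._random_mats(rng, 10, base=0.35), self.names)
        res_t = edgewise_contrast(a, b, paired=True)
        res_p = edgewise_contrast(a, b, paired=True, method="permutation", seed=0)
        np.testing.assert_allclose(res_t.edges["t"], res_p.edges["t"], atol=1e-10)

    def test_shape_mismatch_raises(self, rng):
        a = _mats(self._random_mats(rng, 4), self.names)
        with pytest.raises(ValueError, match="paired"):
            edgewise_contrast(a, a[:-1], paired=True)
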