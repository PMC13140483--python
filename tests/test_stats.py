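"""Normality gate, mixed rm-ANOVA, post hoc contrasts, descriptives."""

import numpy as np
import pandas as pd
import pytest

import hemopulse as hp
from helpers import brute_force_mixed_anova, chi2_by_hand, make_long_table
from hemopulse.errors import IntegrityError, TransformError
from hemopulse.stats import mixed_anova_arrays


def _random_groups(rng, n1=6, n2=5, p=3, scale=1.0):
    return [rng.normal(0, scale, (n1, p)) + rng.normal(0, 1, (n1, 1)),
            rng.normal(0.3, scale, (n2, p)) + rng.normal(0, 1, (n2, 1))]


class TestMixedAnova:
    def test_matches_brute_force_oracle_on_random_data(self, rng):
        for _ in range(100):
            groups = _random_groups(rng)
            table = make_long_table({"YA": groups[0], "MA": groups[1]})
            res = hp.rm_anova_2x3(table, "y")
            oracle = brute_force_mixed_anova(
                [groups[1], groups[0]])  # complete_cases sorts MA before YA
            for eff in ("group", "time", "group_x_time"):
                assert res.effects[eff].F == pytest.approx(
                    oracle[eff]["F"], rel=1e-8)
                assert res.effects[eff].partial_eta_sq == pytest.approx(
                    oracle[eff]["partial_eta_sq"], rel=1e-8)

    def test_sums_of_squares_are_conserved(self, rng):
        for _ in range(50):
            groups = _random_groups(rng, n1=8, n2=4)
            ss = mixed_anova_arrays(groups)
            parts = (ss["ss_group"] + ss["ss_subject"] + ss["ss_time"]
                     + ss["ss_interaction"] + ss["ss_residual"])
            assert parts == pytest.approx(ss["ss_total"], rel=1e-8)

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        groups = _random_groups(rng, n1=21, n2=18)
        table = make_long_table({"YA": groups[0], "MA": groups[1]})
        res = hp.rm_anova_2x3(table, "y")
        aov = pg.mixed_anova(data=table, dv="value", within="time",
                             subject="subject", between="group").set_index(
            "Source")
        assert res.effects["group"].F == pytest.approx(
            aov.loc["group", "F"], rel=1e-9)
        assert res.effects["time"].F == pytest.approx(
            aov.loc["time", "F"], rel=1e-9)
        assert res.effects["group_x_time"].F == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-9)
        assert res.effects["time"].partial_eta_sq == pytest.approx(
            aov.loc["time", "np2"], rel=1e-9)

    def test_null_group_effect_is_exactly_zero(self):
        # identical group means, subject offsets only, no time structure
        base = np.arange(5, dtype=float)[:, None] * np.ones((1, 3))
        table = make_long_table({"YA": base, "MA": base.copy()})
        res = hp.rm_anova_2x3(table, "y")
        assert res.effects["group"].F == 0.0
        assert res.effects["group"].partial_eta_sq == 0.0

    def test_partial_eta_sq_bounds(self, rng):
        groups = _random_groups(rng)
        ss = mixed_anova_arrays(groups)
        table = make_long_table({"YA": groups[0], "MA": groups[1]})
        res = hp.rm_anova_2x3(table, "y")
        for eff in res.effects.values():
            assert 0.0 <= eff.partial_eta_sq <= 1.0
        assert ss["ss_group"] > 0  # sanity: nonzero effect has nonzero eta

    def test_printed_interaction_direction_is_recoverable(self):
        """A young-only rise in MCA resistive index (as printed) yields a
        detectable interaction with the printed direction in most
        replicates at the study's group sizes."""
        cells = {"ri": {
            ("YA", "baseline"): (0.53, 0.058), ("YA", "30"): (0.58, 0.06),
            ("YA", "60"): (0.57, 0.04), ("MA", "baseline"): (0.56, 0.03),
            ("MA", "30"): (0.56, 0.04), ("MA", "60"): (0.57, 0.04)}}
        wins, sig = 0, 0
        n_rep = 60
        for k in range(n_rep):
            spec = hp.CohortSpec(cells, n_per_group={"YA": 21, "MA": 18},
                                 within_subject_correlation=0.6, seed=500 + k)
            tab = hp.simulate_cohort(spec)
            res = hp.rm_anova_2x3(tab, "ri")
            ya = tab[(tab.group == "YA")]
            d = (ya[ya.time == "30"]["value"].mean()
                 - ya[ya.time == "baseline"]["value"].mean())
            if d > 0:
                wins += 1
            if res.effects["group_x_time"].p < 0.05:
                sig += 1
        assert wins > n_rep / 2
        assert sig > n_rep / 2


class TestNormalityGate:
    def _table(self, values_fn, rng):
        groups = {"YA": np.empty((20, 3)), "MA": np.empty((20, 3))}
        for g in groups:
            groups[g] = values_fn(rng, (20, 3))
        return make_long_table(groups)

    def test_normal_data_passes_untransformed(self, rng):
        tab = self._table(lambda r, s: r.normal(50, 5, s), rng)
        out, report = hp.normality_gate(tab, "y")
        assert report.transform_applied == "none"
        assert out is tab

    def test_lognormal_data_is_log_transformed(self, rng):
        tab = self._table(lambda r, s: np.exp(r.normal(1, 0.9, s)), rng)
        out, report = hp.normality_gate(tab, "y")
        assert report.transform_applied == "log"
        assert report.cell_p_after["pooled_residuals"] >= 0.05
        assert np.allclose(
            np.sort(out[out.outcome == "y"]["value"]),
            np.sort(np.log(tab[tab.outcome == "y"]["value"])),
        )

    def test_constant_cell_flagged_not_transformed(self):
        groups = {"YA": np.full((5, 3), 4.0),
                  "MA": np.random.default_rng(0).normal(4, 1, (5, 3))}
        tab = make_long_table(groups)
        out, report = hp.normality_gate(tab, "y")
        assert ("YA", "baseline") in report.flagged_cells
        assert report.transform_applied == "none"

    def test_nonpositive_values_block_log_transform(self, rng):
        tab = self._table(lambda r, s: np.exp(r.normal(1, 1.2, s)), rng)
        tab.loc[tab.index[0], "value"] = -1.0
        with pytest.raises(TransformError):
            hp.normality_gate(tab, "y")


class TestPosthoc:
    def test_bonferroni_multiplies_and_caps(self, rng):
        groups = {"YA": rng.normal(0, 1, (12, 3)),
                  "MA": rng.normal(0, 1, (12, 3))}
        tab = make_long_table(groups)
        for c in hp.bonferroni_posthoc(tab, "y", "time_overall"):
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * c.p_raw))

    def test_zero_variance_contrast_flagged(self):
        groups = {"YA": np.tile([1.0, 1.0, 2.0], (5, 1)),
                  "MA": np.random.default_rng(1).normal(0, 1, (5, 3))}
        tab = make_long_table(groups)
        out = hp.bonferroni_posthoc(tab, "y", "time_within_group")
        flagged = [c for c in out if c.flagged == "zero_variance"]
        assert len(flagged) == 3  # all YA time pairs are deterministic
        assert all(c.p_adjusted is None for c in flagged)

    def test_young_only_time_effect_is_localised(self):
        """With a programmed time effect in one group only, the
        within-group family flags that group's baseline contrasts."""
        hits = 0
        n_rep = 25
        for k in range(n_rep):
            rng = np.random.default_rng(900 + k)
            ya = rng.normal(0, 1, (21, 3)) + np.array([0.0, 1.5, 1.5])
            ma = rng.normal(0, 1, (18, 3))
            tab = make_long_table({"YA": ya + rng.normal(0, 1, (21, 1)),
                                   "MA": ma + rng.normal(0, 1, (18, 1))})
            out = hp.bonferroni_posthoc(tab, "y", "time_within_group")
            ya_hits = {c.label: (c.p_adjusted is not None and
                                 c.p_adjusted < 0.05)
                       for c in out if c.family == "time_within_YA"}
            if (ya_hits.get("YA: baseline vs 30") and
                    ya_hits.get("YA: baseline vs 60")):
                hits += 1
        assert hits > 0.9 * n_rep


class TestDescriptives:
    def test_identical_groups_null_t(self):
        frame = pd.DataFrame({
            "group": ["YA"] * 4 + ["MA"] * 4,
            "age": [20, 22, 24, 26] * 2,
        })
        out = hp.describe_groups(frame).set_index("variable")
        assert out.loc["age", "statistic"] == pytest.approx(0.0)
        assert out.loc["age", "p"] == pytest.approx(1.0)

    def test_chi2_matches_hand_formula(self):
        # sex-by-group counts: 12 vs 9 female/male in one group, 13 vs 7
        table = np.array([[12, 9], [13, 7]])
        stat, p = hp.stats.chi2_counts(table)
        stat_hand, p_hand = chi2_by_hand(table)
        assert stat == pytest.approx(stat_hand, abs=1e-8)
        assert p == pytest.approx(p_hand, abs=1e-8)

    def test_welch_t_close_to_permutation_oracle(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(1.0, 1, 10)
        frame = pd.DataFrame({"group": ["YA"] * 10 + ["MA"] * 10,
                              "v": np.concatenate([x, y])})
        p_welch = hp.describe_groups(frame).set_index("variable").loc["v", "p"]
        pooled = np.concatenate([x, y])
        obs = abs(x.mean() - y.mean())
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            count += abs(pooled[:10].mean() - pooled[10:].mean()) >= obs
        p_perm = count / n_perm
        assert abs(p_welch - p_perm) < 0.05

    def test_categorical_column_routed_to_chi2(self):
        frame = pd.DataFrame({
            "group": ["YA"] * 21 + ["MA"] * 20,
            "sex": ["F"] * 12 + ["M"] * 9 + ["F"] * 13 + ["M"] * 7,
        })
        out = hp.describe_groups(frame).set_index("variable")
        assert out.loc["sex", "test"] == "chi2"


class TestStudyTableIntegrity:
    def test_duplicate_keys_rejected(self):
        tab = make_long_table({"YA": np.ones((3, 3))})
        dup = pd.concat([tab, tab.iloc[[0]]], ignore_index=True)
        with pytest.raises(IntegrityError):
            hp.stats.validate_study_table(dup)

    def test_subject_in_two_groups_rejected(self):
        tab = make_long_table({"YA": np.ones((3, 3))})
        bad = tab.copy()
        bad.loc[bad.index[0], "group"] = "MA"
        with pytest.raises(IntegrityError):
            hp.stats.validate_study_table(bad)
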