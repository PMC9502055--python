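"""Agreement statistics: formula oracles, invariances, planted-effect
recovery, and the model/results objects."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fetlock import (MethodAgreement, RomVariabilityAnova, anova3_partition,
                     bland_altman_rm, cv_percent, granger_agreement, pcc, rmse)

finite_floats = st.floats(-1e3, 1e3, allow_nan=False)
vectors = st.lists(finite_floats, min_size=3, max_size=40).map(np.asarray)


class TestRmse:
    def test_closed_forms(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
        assert rmse([0.0, 1.0], [5.0, 6.0]) == pytest.approx(5.0)
        assert rmse([1, 2, 3], [2, 4, 6]) == pytest.approx(np.sqrt(14.0 / 3.0))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(vectors, st.floats(-100, 100, allow_nan=False))
    def test_symmetry_and_shift_invariance(self, x, c):
        y = x[::-1].copy()
        assert rmse(x, y) == pytest.approx(rmse(y, x), rel=1e-12, abs=1e-12)
        assert rmse(x + c, y + c) == pytest.approx(rmse(x, y), rel=1e-9, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0, 2.0], [1.0])


class TestPcc:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pcc(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pcc(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self, session_rng):
        x = session_rng.normal(size=10)
        y = session_rng.normal(size=10)
        r, _ = pcc(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert r == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(vectors, st.floats(0.1, 50), st.floats(-100, 100))
    def test_invariant_under_positive_affine_maps(self, x, a, b):
        y = np.sin(x) + np.linspace(0, 1, x.size)
        if np.std(x) == 0 or np.std(y) == 0:
            return
        r0, _ = pcc(x, y)
        r1, _ = pcc(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pcc(np.ones(10), np.arange(10.0))


class TestCvPercent:
    def test_closed_forms(self):
        assert cv_percent([10.0, 10.0]) == 0.0
        assert cv_percent([8.0, 12.0]) == pytest.approx(28.2843, abs=1e-4)

    def test_matches_brute_force(self, session_rng):
        v = session_rng.uniform(5, 15, size=5)
        sd = np.sqrt(np.sum((v - v.mean()) ** 2) / (v.size - 1))
        assert cv_percent(v) == pytest.approx(sd / v.mean() * 100.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cv_percent([3.0])
        with pytest.raises(ValueError, match="mean"):
            cv_percent([-1.0, 1.0])


class TestGranger:
    def test_planted_lead_lag_detected(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(2000)
        y = np.zeros(2000)
        y[3:] = 0.9 * x[:-3]
        y += rng.normal(0, 0.1, 2000)
        rep = granger_agreement(x, y, max_lag=10, difference=False)
        assert rep.agree and rep.p_fwd < 0.01
        assert rep.lag_order == 3

    def test_shifted_copy_of_fja_trace_agrees(self, clean_trot_recording):
        v = clean_trot_recording.truth_fja.values
        rng = np.random.default_rng(0)
        x = v + rng.normal(0, 0.3, v.size)
        y = np.roll(v, 4) + rng.normal(0, 0.3, v.size)
        rep = granger_agreement(x[::4], y[::4], max_lag=5)
        assert rep.agree

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            granger_agreement(np.ones(500), np.arange(500.0))

    def test_too_short_for_lag_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            granger_agreement(np.random.default_rng(0).normal(size=100),
                              np.random.default_rng(1).normal(size=100),
                              max_lag=20)

    def test_both_rule_stricter_than_either(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(1500)
        y = np.roll(x, 2) * 0.8 + rng.normal(0, 0.2, 1500)  # x leads y only
        either = granger_agreement(x, y, max_lag=6, difference=False, rule="either")
        both = granger_agreement(x, y, max_lag=6, difference=False, rule="both")
        assert either.agree
        assert both.agree == (both.p_fwd < 0.01 and both.p_rev < 0.01)


class TestBlandAltman:
    def test_identical_methods(self):
        x = np.arange(20.0)
        out = bland_altman_rm(x, x, method="pooled")
        assert out.bias == 0.0 and out.loa_low == 0.0 and out.loa_high == 0.0

    def test_pure_offset(self):
        x = np.arange(20.0)
        out = bland_altman_rm(x + 5.0, x, method="pooled")
        assert out.bias == pytest.approx(5.0)
        assert out.loa_low == pytest.approx(5.0)
        assert out.loa_high == pytest.approx(5.0)

    def test_monte_carlo_recovers_generating_sigma(self):
        """y = x + N(0, 2) over 10 subjects × 500 pairs: bias ≈ 0 and
        rm-corrected LoA ≈ ±1.96·2 = ±3.92."""
        rng = np.random.default_rng(11)
        x = rng.normal(0, 15, 5000)
        y = x + rng.normal(0, 2.0, 5000)
        subj = np.repeat(np.arange(10), 500)
        out = bland_altman_rm(y, x, subject=subj, method="rm_corrected")
        assert out.bias == pytest.approx(0.0, abs=0.15)
        assert out.loa_high == pytest.approx(3.92, abs=0.2)
        assert out.loa_low == pytest.approx(-3.92, abs=0.2)

    def test_rm_with_between_subject_offsets_widens_loa(self):
        rng = np.random.default_rng(5)
        subj = np.repeat(np.arange(8), 100)
        x = rng.normal(0, 10, 800)
        offsets = np.repeat(rng.normal(0, 3.0, 8), 100)  # subject-level bias
        y = x + offsets + rng.normal(0, 1.0, 800)
        pooled = bland_altman_rm(y, x, method="pooled")
        rm = bland_altman_rm(y, x, subject=subj, method="rm_corrected")
        # both must cover the subject-level spread; rm does so via MSB
        assert rm.sd > 2.0
        assert rm.sd == pytest.approx(pooled.sd, rel=0.25)

    def test_single_subject_falls_back_to_pooled(self):
        x = np.arange(10.0)
        y = x + 1.0
        with pytest.warns(UserWarning, match="pooled"):
            out = bland_altman_rm(y, x, subject=np.zeros(10), method="rm_corrected")
        assert out.method == "pooled"


class TestAnovaPartition:
    @staticmethod
    def balanced_table(seed=5, reps=10):
        rng = np.random.default_rng(seed)
        rows = []
        for lame in ("sound", "lame"):
            for gait in ("walk", "trot"):
                for lp in ("front", "hind"):
                    for k in range(reps):
                        rows.append(dict(
                            horse_id=f"{lame}{k}", gait=gait, limb_pair=lp,
                            lameness=lame,
                            cv_percent=10 + 8 * (lame == "lame")
                            + 2 * (gait == "trot") + rng.normal()))
        return pd.DataFrame(rows)

    def test_all_equal_values_give_zero_partition(self):
        df = self.balanced_table()
        df["cv_percent"] = 7.0
        part = anova3_partition(df)
        assert all(part.table["percent_of_total"] == 0.0)

    def test_planted_effects_recovered(self):
        part = anova3_partition(self.balanced_table())
        pct = part.percent_of_total
        assert pct["lameness"] > pct["gait"] > pct["limb_pair"]
        assert part.table.loc["lameness", "p"] < 1e-4
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)

    def test_type1_equals_type2_on_balanced_design(self):
        df = self.balanced_table()
        t1 = anova3_partition(df, typ=1).table
        t2 = anova3_partition(df, typ=2).table
        for f in ("lameness", "gait", "limb_pair"):
            assert t1.loc[f, "sum_sq"] == pytest.approx(t2.loc[f, "sum_sq"], abs=1e-9)

    def test_single_level_factor_dropped_with_warning(self):
        df = self.balanced_table()
        df["gait"] = "walk"
        with pytest.warns(UserWarning, match="gait"):
            part = anova3_partition(df)
        assert "gait" in part.dropped_factors
        assert "gait" not in part.table.index

    def test_shapiro_warning_on_skewed_residuals(self):
        df = self.balanced_table()
        rng = np.random.default_rng(0)
        df["cv_percent"] += rng.exponential(5.0, len(df)) ** 2
        with pytest.warns(UserWarning, match="Shapiro"):
            anova3_partition(df)


class TestModelObjects:
    def test_method_agreement_results_fields_and_summary(self, session_rng):
        t = np.arange(1500) / 200.0
        x = 40 * np.sin(2 * np.pi * 1.4 * t) + session_rng.normal(0, 0.5, t.size)
        y = 40 * np.sin(2 * np.pi * 1.4 * t) + session_rng.normal(0, 0.5, t.size)
        res = MethodAgreement(x, y).fit()
        assert res.rmse_deg < 1.5
        assert res.pcc > 0.99
        assert res.bland_altman.loa_low <= res.bland_altman.bias <= res.bland_altman.loa_high
        text = res.summary()
        assert "RMSE" in text and "Bland-Altman" in text

    def test_rom_variability_model_summary(self):
        res = RomVariabilityAnova.from_dataframe(
            TestAnovaPartition.balanced_table()).fit()
        assert res.dominant_factor == "lameness"
        assert "three-way ANOVA" in res.summary()

    def test_rom_model_rejects_negative_cv(self):
        df = TestAnovaPartition.balanced_table()
        df.loc[0, "cv_percent"] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            RomVariabilityAnova(df)
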