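"""Mixed logistic accuracy model, signal detection, span scoring, correlation."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.special import ndtri

import spabold as sb
from spabold.errors import InputError


@pytest.fixture(scope="module")
def fitted_cohort(protocol):
    design = sb.make_design(protocol, seed=31)
    cohort = sb.make_cohort(40, seed=32)
    records = sb.simulate_behavior(cohort, design, seed=33)
    return cohort, records


class TestFitAccuracyModel:
    def test_matches_plain_logit_when_no_subject_variance(self, protocol):
        # with subject_sd = 0 the ML solution coincides with pooled logistic
        design = sb.make_design(protocol, seed=1)
        cohort = sb.make_cohort(60, seed=2)
        coeffs = sb.BehaviorCoefficients(subject_sd=0.0)
        records = sb.simulate_behavior(cohort, design, coeffs, seed=3)
        res = sb.fit_accuracy_model(records, cohort)

        sent = records[records["stimulus_class"] == "sentence"].merge(
            cohort, on="subject_id")
        pta_c = (sent["pta_db_hl"] - sent["pta_db_hl"].mean()).to_numpy()
        age_c = (sent["age_years"] - sent["age_years"].mean()).to_numpy()
        wm_c = (sent["wm_span"] - sent["wm_span"].mean()).to_numpy()
        is_or = (sent["syntax"] == "object_relative").to_numpy(float)
        is_early = (sent["phrase_position"] == "early").to_numpy(float)
        X = np.column_stack([np.ones(len(sent)), pta_c, age_c, wm_c,
                             is_or, is_early, pta_c * is_or])
        oracle = sm.Logit(sent["is_correct"].to_numpy(bool).astype(float), X).fit(disp=0)
        # tau sits at its boundary; the residual tiny positive tau shifts
        # the intercept by a few thousandths relative to the pooled logit
        np.testing.assert_allclose(res.coefficients["estimate"], oracle.params,
                                   atol=0.02)
        # the residual boundary tau inflates between-subject SEs slightly
        np.testing.assert_allclose(res.coefficients["se"], oracle.bse, rtol=0.15)
        # tau has boundary sampling noise ~n^(-1/4); just check it stays
        # well below the realistic generative value of 0.5
        assert res.random_intercept_sd < 0.2

    def test_matches_lme4_glmer_with_random_intercepts(self, protocol, tmp_path):
        # independent mixed-model oracle: R lme4 (Laplace) on the same data
        design = sb.make_design(protocol, seed=4)
        cohort = sb.make_cohort(30, seed=5)
        records = sb.simulate_behavior(cohort, design, seed=6)
        res = sb.fit_accuracy_model(records, cohort)

        sent = records[records["stimulus_class"] == "sentence"].merge(
            cohort, on="subject_id")
        df = pd.DataFrame({
            "y": sent["is_correct"].to_numpy(bool).astype(int),
            "pta": sent["pta_db_hl"] - sent["pta_db_hl"].mean(),
            "age": sent["age_years"] - sent["age_years"].mean(),
            "wm": sent["wm_span"] - sent["wm_span"].mean(),
            "syntax_or": (sent["syntax"] == "object_relative").astype(int),
            "pos_early": (sent["phrase_position"] == "early").astype(int),
            "subject": sent["subject_id"],
        })
        csv = tmp_path / "trials.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ pta + age + wm + syntax_or + pos_early + pta:syntax_or
                       + (1 | subject), data = d, family = binomial)
            co <- summary(m)$coefficients
            write.csv(co, "{tmp_path}/coefs.csv")
            cat(sqrt(unlist(VarCorr(m))), file = "{tmp_path}/tau.txt")
        """))
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True, timeout=600)
        assert proc.returncode == 0, proc.stderr
        glmer = pd.read_csv(tmp_path / "coefs.csv", index_col=0)
        tau = float((tmp_path / "tau.txt").read_text())
        order = ["(Intercept)", "pta", "age", "wm", "syntax_or", "pos_early",
                 "pta:syntax_or"]
        est_r = glmer.loc[order, "Estimate"].to_numpy()
        se_r = glmer.loc[order, "Std. Error"].to_numpy()
        est = res.coefficients["estimate"].to_numpy()
        se = res.coefficients["se"].to_numpy()
        # Laplace (lme4) vs adaptive quadrature: small approximation gap
        assert np.all(np.abs(est - est_r) <= 0.02 + 0.02 * np.abs(est_r))
        np.testing.assert_allclose(se, se_r, rtol=0.1)
        assert abs(res.random_intercept_sd - tau) < 0.1

    def test_single_subject_rejected(self, protocol):
        design = sb.make_design(protocol, seed=7)
        cohort = sb.make_cohort(1, seed=8)
        records = sb.simulate_behavior(cohort, design, seed=9)
        with pytest.raises(InputError):
            sb.fit_accuracy_model(records, cohort)

    def test_fitted_probabilities_monotone_in_linear_predictor(self, fitted_cohort):
        cohort, records = fitted_cohort
        res = sb.fit_accuracy_model(records, cohort)
        b = res.coefficients["estimate"]
        pta_c = cohort["pta_db_hl"] - cohort["pta_db_hl"].mean()
        eta = b["intercept"] + b["pta"] * pta_c
        p = 1 / (1 + np.exp(-eta))
        assert ((p > 0) & (p < 1)).all()
        order = np.argsort(eta.to_numpy())
        assert np.all(np.diff(p.to_numpy()[order]) >= 0)

    def test_null_slopes_keep_z_small(self, protocol):
        # all generative slopes zero: no term should show a systematic effect
        design = sb.make_design(protocol, seed=10)
        rejections = np.zeros(6)
        n_reps = 12
        for rep in range(n_reps):
            cohort = sb.make_cohort(50, seed=300 + rep)
            coeffs = sb.BehaviorCoefficients(b_pta=0, b_age=0, b_wm=0,
                                             b_syntax=0, b_position=0,
                                             b_pta_x_syntax=0, subject_sd=0.4)
            records = sb.simulate_behavior(cohort, design, coeffs, seed=400 + rep)
            res = sb.fit_accuracy_model(records, cohort)
            slopes = res.coefficients.drop("intercept")
            rejections += (slopes["p"] < 0.05).to_numpy()
        # per-term false positive rate stays near the nominal 5%
        assert rejections.max() <= np.ceil(0.05 * n_reps) + 2


class TestSdt2afc:
    @staticmethod
    def _records(n_hit, n_miss, n_fa, n_cr):
        rows = []
        for resp, truth, n in (("male", "male", n_hit), ("female", "male", n_miss),
                               ("male", "female", n_fa), ("female", "female", n_cr)):
            rows += [{"subject_id": "s", "stimulus_class": "sentence",
                      "correct_answer": truth, "response": resp}] * n
        return pd.DataFrame(rows)

    def test_chance_performance_gives_zero(self):
        res = sb.sdt_2afc(self._records(25, 25, 25, 25))
        assert res.d_prime == 0.0 and res.criterion == 0.0

    def test_h90_fa10_matches_inverse_normal_oracle(self):
        res = sb.sdt_2afc(self._records(45, 5, 5, 45))
        assert res.d_prime == pytest.approx(2 * ndtri(0.9), abs=1e-12)
        assert res.d_prime == pytest.approx(2.5631, abs=1e-4)
        assert res.criterion == pytest.approx(0.0, abs=1e-12)

    def test_perfect_performance_corrected_by_half_count_rule(self):
        res = sb.sdt_2afc(self._records(50, 0, 0, 50))
        assert res.hit_rate == 1 - 1 / 100
        assert res.false_alarm_rate == 1 / 100
        assert res.d_prime == pytest.approx(float(ndtri(0.99) - ndtri(0.01)))
        assert res.correction == "1/(2N)"

    @pytest.mark.parametrize("counts", [(40, 10, 20, 30), (10, 40, 5, 45),
                                        (30, 20, 30, 20)])
    def test_label_swap_symmetry(self, counts):
        rec = self._records(*counts)
        male = sb.sdt_2afc(rec, signal="male")
        female = sb.sdt_2afc(rec, signal="female")
        assert male.d_prime == pytest.approx(female.d_prime, abs=1e-12)
        assert male.criterion == pytest.approx(-female.criterion, abs=1e-12)

    def test_forced_choice_scaling_flag(self):
        rec = self._records(45, 5, 5, 45)
        scaled = sb.sdt_2afc(rec, forced_choice_scaling=True)
        assert scaled.d_prime == pytest.approx(2 * ndtri(0.9) / np.sqrt(2))

    def test_missing_stimulus_class_rejected(self):
        with pytest.raises(InputError):
            sb.sdt_2afc(self._records(10, 5, 0, 0))

    def test_per_subject_table(self, fitted_cohort):
        cohort, records = fitted_cohort
        table = sb.sdt_by_subject(records)
        assert len(table) == len(cohort)
        assert table["d_prime"].notna().all()


class TestWeightedSpanScore:
    @pytest.mark.parametrize("pcs,expected", [
        ([0, 0, 0, 0, 0], 0.0),
        ([1, 1, 1, 1, 1], 3.0),
        ([1, 1, 1, 0, 0], 1.2),
    ])
    def test_documented_rule(self, pcs, expected):
        assert sb.weighted_span_score(pcs).score == pytest.approx(expected)

    def test_missing_set_sizes_listed(self):
        with pytest.raises(InputError, match=r"\[4, 5\]"):
            sb.weighted_span_score({1: 0.5, 2: 0.5, 3: 0.5})

    @given(st.lists(st.floats(0, 1), min_size=5, max_size=5),
           st.integers(0, 4))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_each_proportion(self, pcs, k):
        base = sb.weighted_span_score(pcs).score
        bumped = list(pcs)
        bumped[k] = min(1.0, bumped[k] + 0.25)
        assert sb.weighted_span_score(bumped).score >= base


class TestCorrelate:
    def test_identity_and_negative_linear(self):
        x = np.arange(10.0)
        assert sb.correlate(x, x).r == pytest.approx(1.0)
        assert sb.correlate(x, -2 * x + 3).r == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(InputError):
            sb.correlate(np.ones(5), np.arange(5.0))

    def test_planted_pta_sensitivity_link_is_negative(self, protocol):
        # poorer hearing -> more errors -> lower d'; the sign should
        # reproduce across almost all simulated cohorts of the study size
        design = sb.make_design(protocol, seed=40)
        negative = 0
        n_reps = 10
        for rep in range(n_reps):
            cohort = sb.make_cohort(35, seed=500 + rep)
            records = sb.simulate_behavior(cohort, design, seed=600 + rep)
            table = sb.sdt_by_subject(records).merge(cohort, on="subject_id")
            res = sb.correlate(table["pta_db_hl"], table["d_prime"])
            negative += res.r < 0
        assert negative >= 8
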