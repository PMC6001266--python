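"""Simulator: cohort distributions, design balance, behavior, planted BOLD."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma, truncnorm

import spabold as sb
from spabold.errors import ConfigurationError, InputError

from conftest import mini_design


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

class TestMakeCohort:
    def test_pta_within_stated_range(self):
        cohort = sb.make_cohort(35, seed=0)
        assert cohort["pta_db_hl"].between(-5.0, 23.3).all()
        assert cohort["age_years"].between(18, 41).all()
        assert np.isfinite(cohort["pta_db_hl"]).all()

    def test_empty_cohort(self):
        assert len(sb.make_cohort(0, seed=0)) == 0

    def test_large_sample_matches_truncated_normal_mean(self):
        # closed-form truncated-normal mean as oracle
        cohort = sb.make_cohort(100_000, seed=1)
        a, b = (-5.0 - 3.5) / 5.4, (23.3 - 3.5) / 5.4
        analytic = truncnorm.mean(a, b, loc=3.5, scale=5.4)
        assert abs(cohort["pta_db_hl"].mean() - analytic) < 0.1

    def test_reproducible_under_fixed_seed(self):
        pd.testing.assert_frame_equal(sb.make_cohort(10, seed=7),
                                      sb.make_cohort(10, seed=7))

    @pytest.mark.parametrize("kwargs", [
        {"n": -1}, {"pta_range": (5.0, 5.0)}, {"pta_range": (10.0, -10.0)},
    ])
    def test_invalid_inputs_raise(self, kwargs):
        with pytest.raises(InputError):
            sb.make_cohort(**{"n": 5, **kwargs})


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

class TestMakeDesign:
    def test_per_run_composition(self, protocol, design):
        counts = design.groupby(["run_index", "stimulus_class"]).size().unstack()
        assert (counts["sentence"] == 24).all()
        assert (counts["vocoded_noise"] == 6).all()
        assert (counts["silence"] == 6).all()

    def test_six_sentences_per_cell_per_run(self, design):
        sent = design[design["stimulus_class"] == "sentence"]
        cells = sent.groupby(["run_index", "syntax", "phrase_position"]).size()
        assert (cells == 6).all() and len(cells) == 16

    def test_all_96_stimuli_exactly_once(self, design):
        sent = design[design["stimulus_class"] == "sentence"]
        pairs = list(zip(sent["base_sentence_id"], sent["syntax"],
                         sent["phrase_position"]))
        assert len(pairs) == 96 and len(set(pairs)) == 96

    def test_one_variant_of_each_base_per_run(self, design):
        sent = design[design["stimulus_class"] == "sentence"]
        per_run = sent.groupby("run_index")["base_sentence_id"].nunique()
        assert (per_run == 24).all()

    def test_answer_key_follows_syntax(self, design):
        sent = design[design["stimulus_class"] == "sentence"]
        sr = sent["syntax"] == "subject_relative"
        assert (sent.loc[sr, "correct_answer"] == "male").all()
        assert (sent.loc[~sr, "correct_answer"] == "female").all()

    def test_onsets_are_trial_duration_multiples(self, protocol, design):
        per_run = design.groupby("run_index")["onset_s"]
        for _, onsets in per_run:
            assert np.array_equal(np.sort(onsets),
                                  np.arange(36) * protocol.trial_duration_s)

    def test_same_seed_identical_schedule(self, protocol):
        pd.testing.assert_frame_equal(sb.make_design(protocol, seed=3),
                                      sb.make_design(protocol, seed=3))

    def test_inconsistent_composition_rejected(self):
        bad = sb.AcquisitionProtocol(trials_per_run=30)
        with pytest.raises(ConfigurationError):
            sb.make_design(bad, seed=0)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

class TestSimulateBehavior:
    def test_forced_success_makes_every_sentence_correct(self, protocol, design):
        cohort = sb.make_cohort(5, seed=2)
        coeffs = sb.BehaviorCoefficients(b0=40.0, b_pta=0, b_age=0, b_wm=0,
                                         b_syntax=0, b_position=0,
                                         b_pta_x_syntax=0, subject_sd=0.0)
        rec = sb.simulate_behavior(cohort, design, coeffs, seed=3)
        sent = rec[rec["stimulus_class"] == "sentence"]
        assert sent["is_correct"].all()
        assert (cohort["accuracy"] == 1.0).all()

    def test_silence_has_no_response_or_correctness(self, cohort_with_behavior):
        _, rec = cohort_with_behavior
        sil = rec[rec["stimulus_class"] == "silence"]
        assert sil["response"].isna().all()
        assert sil["is_correct"].isna().all()

    def test_sentence_and_noise_trials_all_answered(self, cohort_with_behavior):
        _, rec = cohort_with_behavior
        answered = rec[rec["stimulus_class"] != "silence"]
        assert answered["response"].isin(["male", "female"]).all()

    def test_accuracy_decreases_across_pta_tertiles(self, protocol, design):
        # Monte-Carlo check against the logistic mean function
        cohort = sb.make_cohort(600, seed=4)
        coeffs = sb.BehaviorCoefficients(b_pta=-0.08, subject_sd=0.0)
        sb.simulate_behavior(cohort, design, coeffs, seed=5)
        tertiles = pd.qcut(cohort["pta_db_hl"], 3, labels=[0, 1, 2])
        means = cohort.groupby(tertiles, observed=True)["accuracy"].mean()
        assert means.iloc[0] > means.iloc[1] > means.iloc[2]

    def test_mismatched_designs_raise(self, protocol, design):
        cohort = sb.make_cohort(3, seed=6)
        with pytest.raises(InputError):
            sb.simulate_behavior(cohort, {"sub-001": design}, seed=7)


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def _hrf_oracle(lags):
    """Independent evaluation of the peak-normalized double-gamma shape."""
    t = np.linspace(0, 50, 5001)
    curve = gamma.pdf(t, 6, scale=1) - gamma.pdf(t, 16, scale=1) / 6.0
    peak = curve.max()
    vals = gamma.pdf(lags, 6, scale=1) - gamma.pdf(lags, 16, scale=1) / 6.0
    return np.where(np.asarray(lags) >= 0, vals / peak, 0.0)


@pytest.fixture(scope="module")
def quiet_spec(small_protocol):
    return sb.default_brainspec(small_protocol, noise_sd=0.0, drift_amplitude=0.0)


def _single_trial(protocol, trial):
    per_run = ["silence"] * (protocol.trials_per_run - 1) + [trial]
    return mini_design(protocol, [per_run] * protocol.n_runs)


class TestSimulateBold:
    def test_single_trial_matches_hrf_oracle(self, small_protocol, quiet_spec):
        design, beh = _single_trial(small_protocol,
                                    ("subject_relative", "early", True))
        subject = {"subject_id": "sub-001", "pta_db_hl": 0.0}
        series, _ = sb.simulate_bold(subject, design, beh, quiet_spec,
                                     small_protocol, seed=0, pta_center=0.0)
        vox = tuple(np.argwhere(quiet_spec.regions["language_core"])[0])
        trial0 = small_protocol.trials_per_run - 1
        vols = slice(trial0 * 5, trial0 * 5 + 5)
        observed = series.data[vox][vols]
        # stimulus starts 1 s into the trial: lags are 3, 5, 7, 9, 11 s
        lags = small_protocol.volume_offsets_s - 1.0
        expected = quiet_spec.baseline + quiet_spec.a_sentence * _hrf_oracle(lags)
        np.testing.assert_allclose(observed, expected, atol=1e-9)

    def test_voxel_outside_masks_is_constant_baseline(self, small_protocol, quiet_spec):
        design, beh = _single_trial(small_protocol,
                                    ("object_relative", "late", True))
        subject = {"subject_id": "sub-001", "pta_db_hl": 10.0}
        series, _ = sb.simulate_bold(subject, design, beh, quiet_spec,
                                     small_protocol, seed=0, pta_center=0.0)
        outside = quiet_spec.brain_mask.copy()
        for m in quiet_spec.regions.values():
            outside &= ~m
        vox = tuple(np.argwhere(outside)[0])
        assert np.ptp(series.data[vox]) == 0.0
        assert series.data[vox][0] == quiet_spec.baseline

    def test_pta_amplitude_is_linear_in_hearing_level(self, small_protocol, quiet_spec):
        design, beh = _single_trial(small_protocol,
                                    ("subject_relative", "early", True))
        out = {}
        for pta in (0.0, 20.0):
            subject = {"subject_id": "sub-001", "pta_db_hl": pta}
            series, _ = sb.simulate_bold(subject, design, beh, quiet_spec,
                                         small_protocol, seed=0, pta_center=0.0)
            vox = tuple(np.argwhere(quiet_spec.regions["pta_sensitive"])[0])
            out[pta] = series.data[vox] - quiet_spec.baseline
        diff = out[20.0] - out[0.0]
        lags = small_protocol.volume_offsets_s - 1.0
        expected = 20.0 * quiet_spec.slope_pta * _hrf_oracle(lags)
        trial0 = small_protocol.trials_per_run - 1
        np.testing.assert_allclose(diff[trial0 * 5: trial0 * 5 + 5], expected,
                                   atol=1e-9)

    def test_error_region_responds_only_to_incorrect(self, small_protocol, quiet_spec):
        design, beh = _single_trial(small_protocol,
                                    ("object_relative", "early", False))
        subject = {"subject_id": "sub-001", "pta_db_hl": 0.0}
        series, _ = sb.simulate_bold(subject, design, beh, quiet_spec,
                                     small_protocol, seed=0, pta_center=0.0)
        err_vox = tuple(np.argwhere(quiet_spec.regions["error_sensitive"])[0])
        pta_vox = tuple(np.argwhere(quiet_spec.regions["pta_sensitive"])[0])
        assert np.ptp(series.data[err_vox]) > 0.0
        assert np.ptp(series.data[pta_vox]) == 0.0   # correct-trial-only region

    def test_superposition_of_trial_mixes(self, small_protocol, quiet_spec):
        # responses add linearly at noise_sd = 0
        base = ["silence"] * small_protocol.trials_per_run
        a = list(base); a[1] = ("subject_relative", "early", True)
        b = list(base); b[3] = ("object_relative", "late", True)
        both = list(base)
        both[1], both[3] = a[1], b[3]
        subject = {"subject_id": "sub-001", "pta_db_hl": 0.0}
        out = {}
        for name, run in (("a", a), ("b", b), ("both", both)):
            design, beh = mini_design(small_protocol, [run] * small_protocol.n_runs)
            series, _ = sb.simulate_bold(subject, design, beh, quiet_spec,
                                         small_protocol, seed=0, pta_center=0.0)
            out[name] = series.data.astype(float) - \
                quiet_spec.baseline * quiet_spec.brain_mask[..., None]
        np.testing.assert_allclose(out["both"], out["a"] + out["b"], atol=1e-9)

    def test_seeded_determinism(self, small_protocol, design, protocol, brainspec):
        full_design = sb.make_design(protocol, seed=1)
        cohort = sb.make_cohort(1, seed=1)
        beh = sb.simulate_behavior(cohort, full_design, seed=2)
        subject = cohort.iloc[0].to_dict()
        s1, m1 = sb.simulate_bold(subject, full_design, beh, brainspec, protocol,
                                  seed=9, pta_center=0.0)
        s2, m2 = sb.simulate_bold(subject, full_design, beh, brainspec, protocol,
                                  seed=9, pta_center=0.0)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(m1, m2)

    def test_missing_behavior_rejected(self, small_protocol, quiet_spec):
        design, beh = _single_trial(small_protocol,
                                    ("subject_relative", "late", True))
        subject = {"subject_id": "sub-001", "pta_db_hl": 0.0}
        with pytest.raises(InputError):
            sb.simulate_bold(subject, design, beh.iloc[:-1], quiet_spec,
                             small_protocol, seed=0)


class TestBrainSpec:
    def test_default_regions_disjoint_and_inside_brain(self, brainspec, protocol):
        brainspec.validate(protocol.grid_shape)
        total = sum(m.astype(int) for m in brainspec.regions.values())
        assert total.max() == 1
        for mask in brainspec.regions.values():
            assert mask.sum() > 0
            assert not (mask & ~brainspec.brain_mask).any()

    def test_overlapping_regions_rejected(self, protocol):
        spec = sb.default_brainspec(protocol)
        spec.regions["language_core"] = spec.regions["pta_sensitive"].copy()
        with pytest.raises(InputError):
            spec.validate(protocol.grid_shape)
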