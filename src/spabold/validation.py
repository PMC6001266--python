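"""Ground-truth validation studies for the whole pipeline.

Each function runs a self-contained study against the simulator — design
arithmetic, OLS oracle equivalence, noise-free FIR/SPA recovery, null
calibration of the random-field cluster test, recovery of the planted
hearing-acuity effect, behavioral coefficient recovery, and signal-
detection identities — and returns plain numbers.  The studies drive both
the acceptance checks and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtri

from .behavior import fit_accuracy_model, sdt_2afc
from .clusters import (estimate_smoothness, permutation_cluster_p,
                       rft_critical_extent, threshold_and_cluster)
from .design import build_design_matrix
from .firstlevel import SpaMap, compute_spa, fit_glm
from .group import regress_covariate
from .hrf import double_gamma_hrf
from .pipeline import cohort_spa_study, covariate_regression_analysis
from .protocol import AcquisitionProtocol
from .synth import (BehaviorCoefficients, VolumeSeries, default_brainspec,
                    make_cohort, make_design, simulate_behavior,
                    simulate_bold, as_rng)


# ---------------------------------------------------------------------------
# design arithmetic
# ---------------------------------------------------------------------------

def design_arithmetic(seed=0) -> dict:
    """Exact design bookkeeping of one generated experiment."""
    protocol = AcquisitionProtocol()
    design = make_design(protocol, seed=seed)
    sent = design[design["stimulus_class"] == "sentence"]
    stimuli = set(zip(sent["base_sentence_id"], sent["syntax"], sent["phrase_position"]))
    per_run = sent.groupby("run_index").size()
    return {
        "n_unique_stimuli": len(stimuli) if len(sent) == len(stimuli) else -1,
        "sentence_trials_per_run": int(per_run.iloc[0]) if per_run.nunique() == 1 else -1,
        "trial_duration_s": protocol.trial_duration_s,
        "run_duration_min": protocol.run_duration_s / 60.0,
    }


# ---------------------------------------------------------------------------
# OLS oracle equivalence
# ---------------------------------------------------------------------------

def _random_mini_design(protocol: AcquisitionProtocol, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random small trial schedule + behavior covering all stimulus classes."""
    rows, brows = [], []
    for run in range(1, protocol.n_runs + 1):
        # at least two baseline (silence) trials per run so the FIR columns
        # can never absorb a run intercept
        classes = ["silence", "silence"] + [
            rng.choice(["sentence", "vocoded_noise", "silence"], p=[0.6, 0.2, 0.2])
            for _ in range(protocol.trials_per_run - 2)]
        rng.shuffle(classes)
        for idx in range(protocol.trials_per_run):
            cls = classes[idx]
            syntax = position = answer = None
            if cls == "sentence":
                syntax = rng.choice(["subject_relative", "object_relative"])
                position = rng.choice(["early", "late"])
                answer = "male" if syntax == "subject_relative" else "female"
            rows.append({"run_index": run, "trial_index": idx,
                         "onset_s": idx * protocol.trial_duration_s,
                         "stimulus_class": cls, "syntax": syntax,
                         "phrase_position": position, "base_sentence_id": None,
                         "correct_answer": answer})
            brows.append({"run_index": run, "trial_index": idx,
                          "stimulus_class": cls, "syntax": syntax,
                          "phrase_position": position, "correct_answer": answer,
                          "response": answer,
                          "is_correct": (bool(rng.random() < 0.8)
                                         if cls != "silence" else pd.NA)})
    beh = pd.DataFrame(brows)
    beh["is_correct"] = beh["is_correct"].astype("boolean")
    return pd.DataFrame(rows), beh


def glm_oracle_study(n_instances: int = 50, seed=0) -> dict:
    """Max relative error of the OLS solver vs an SVD pseudoinverse oracle.

    Each instance is a random small ISSS design (random trial classes and
    accuracies, random motion) with random data on a tiny grid.
    """
    rng = as_rng(seed)
    worst = 0.0
    protocol = AcquisitionProtocol(n_runs=2, trials_per_run=8, grid_shape=(5, 5, 4))
    for _ in range(n_instances):
        design, beh = _random_mini_design(protocol, rng)
        motion = np.cumsum(rng.normal(0, 0.02, size=(protocol.n_volumes, 6)), axis=0)
        dm = build_design_matrix(design, beh, protocol, motion=motion, hp_cutoff_s=128.0)
        data = rng.normal(size=protocol.grid_shape + (protocol.n_volumes,))
        series = VolumeSeries(
            data=data, volume_times_s=np.tile(protocol.run_volume_times(), protocol.n_runs),
            run_of_volume=protocol.series_run_labels(),
            brain_mask=np.ones(protocol.grid_shape, bool), affine=protocol.affine())
        betas = fit_glm(series, dm, keep_residuals=False)
        Y = np.moveaxis(data, -1, 0).reshape(protocol.n_volumes, -1)
        oracle = np.linalg.pinv(dm.matrix) @ Y
        scale = np.abs(oracle).max()
        worst = max(worst, float(np.abs(betas.betas - oracle).max() / scale))
    return {"glm_oracle_max_rel_error": worst, "n_instances": n_instances}


# ---------------------------------------------------------------------------
# noise-free FIR / SPA recovery
# ---------------------------------------------------------------------------

def _isolated_trial_design(protocol: AcquisitionProtocol) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per run: silence trials followed by one final sentence trial.

    With the sentence trial last in each run, its hemodynamic tail falls
    outside every acquisition window, so noise-free OLS recovery of the
    FIR bins is exact rather than approximate.
    """
    rows, brows = [], []
    for run in range(1, protocol.n_runs + 1):
        for idx in range(protocol.trials_per_run):
            last = idx == protocol.trials_per_run - 1
            rows.append({"run_index": run, "trial_index": idx,
                         "onset_s": idx * protocol.trial_duration_s,
                         "stimulus_class": "sentence" if last else "silence",
                         "syntax": "subject_relative" if last else None,
                         "phrase_position": "early" if last else None,
                         "base_sentence_id": None,
                         "correct_answer": "male" if last else None})
            brows.append({"run_index": run, "trial_index": idx,
                          "stimulus_class": rows[-1]["stimulus_class"],
                          "syntax": rows[-1]["syntax"],
                          "phrase_position": rows[-1]["phrase_position"],
                          "correct_answer": rows[-1]["correct_answer"],
                          "response": rows[-1]["correct_answer"],
                          "is_correct": True if last else pd.NA})
    beh = pd.DataFrame(brows)
    beh["is_correct"] = beh["is_correct"].astype("boolean")
    return pd.DataFrame(rows), beh


def fir_recovery_study(seed=0) -> dict:
    """Noise-free FIR profile recovery and the SPA positive-sum identity."""
    protocol = AcquisitionProtocol(trials_per_run=6, grid_shape=(12, 12, 12))
    spec = default_brainspec(protocol, noise_sd=0.0, drift_amplitude=0.0)
    design, beh = _isolated_trial_design(protocol)
    subject = {"subject_id": "sub-001", "pta_db_hl": 0.0}
    series, _ = simulate_bold(subject, design, beh, spec, protocol,
                              seed=seed, pta_center=0.0)
    dm = build_design_matrix(design, beh, protocol, motion=None, hp_cutoff_s=None)
    betas = fit_glm(series, dm, keep_residuals=False)
    profile = betas.fir_profile_matrix("sr_early_correct")

    lags = protocol.volume_offsets_s - protocol.stimulus_delay_s
    expected = spec.a_sentence * double_gamma_hrf(lags)
    core = spec.regions["language_core"][spec.brain_mask]
    err_fir = float(np.abs(profile[:, core] - expected[:, None]).max())

    spa = compute_spa(betas, "sr_early_correct")
    manual = np.clip(profile, 0.0, None).sum(axis=0)
    err_spa = float(np.abs(spa.values - manual).max())
    return {"fir_recovery_max_abs_error": err_fir,
            "spa_positive_sum_max_abs_error": err_spa,
            "n_voxels": int(core.sum())}


# ---------------------------------------------------------------------------
# FWE calibration on null fields
# ---------------------------------------------------------------------------

def _smooth_null_maps(n_subjects, protocol, mask, rng) -> list[SpaMap]:
    sigma = np.full(3, protocol.smoothing_fwhm_mm
                    / (2.0 * np.sqrt(2.0 * np.log(2.0))) / protocol.voxel_size_mm)
    fields = rng.standard_normal((n_subjects,) + tuple(protocol.grid_shape),
                                 dtype=np.float32)
    ndimage.gaussian_filter(fields, sigma=(0.0, *sigma), output=fields, truncate=3.0)
    return [SpaMap(values=f[mask].astype(float), condition="null",
                   subject_id=f"sub-{i:03d}", mask=mask, affine=protocol.affine())
            for i, f in enumerate(fields)]


def fwe_calibration_study(n_datasets: int = 500, n_subjects: int = 35, seed=0,
                          n_perm_datasets: int = 20, n_permutations: int = 499,
                          p_voxel: float = 0.001, alpha: float = 0.05) -> dict:
    """Family-wise error rate of RFT cluster inference on null regressions.

    Each dataset: ``n_subjects`` smooth Gaussian null maps regressed on a
    random covariate; a dataset counts as a family-wise false positive when
    any cluster reaches RFT FWE p < ``alpha``.  On a subset of datasets the
    permutation oracle's max-extent null is computed and its critical
    extent compared with the RFT critical extent.
    """
    rng = as_rng(seed)
    protocol = AcquisitionProtocol()
    spec = default_brainspec(protocol)
    mask = spec.brain_mask
    u = float(ndtri(1.0 - p_voxel))

    positives = 0
    k_rft, k_perm = [], []
    for d in range(n_datasets):
        maps = _smooth_null_maps(n_subjects, protocol, mask, rng)
        covariate = rng.normal(size=n_subjects)
        statmap = regress_covariate(maps, covariate, label="null")
        resid4d = np.zeros(mask.shape + (n_subjects,), np.float32)
        resid4d[mask] = statmap.residuals.T
        sm = estimate_smoothness(resid4d, mask, statmap.df, protocol.voxel_size_mm)
        clusters = threshold_and_cluster(statmap, p_voxel=p_voxel, smoothness=sm)
        if any(c.p_fwe < alpha for c in clusters):
            positives += 1
        if d < n_perm_datasets:
            k_rft.append(rft_critical_extent(sm, u, alpha=alpha))
            arr = np.stack([m.values for m in maps])
            perm = permutation_cluster_p(arr, mask, [1], covariate=covariate,
                                         n_permutations=n_permutations,
                                         seed=rng, p_voxel=p_voxel)
            k_perm.append(perm.critical_extent(alpha=alpha))
    return {
        "fwe_family_wise_rate": positives / n_datasets,
        "n_datasets": n_datasets,
        "rft_critical_extent_mean": float(np.mean(k_rft)),
        "perm_critical_extent_mean": float(np.mean(k_perm)),
        "rft_vs_perm_extent_ratio": float(np.mean(k_rft) / max(np.mean(k_perm), 1e-9)),
    }


# ---------------------------------------------------------------------------
# planted hearing-acuity effect recovery
# ---------------------------------------------------------------------------

def pta_recovery_study(n_seeds: int = 50, n_subjects: int = 35, seed=0,
                       alpha: float = 0.05) -> dict:
    """Detection of the planted correct-trial PTA effect, with null controls.

    Per seed the full pipeline runs at the default study conditions: the
    hit criterion is an FWE-significant cluster of the PTA regression on
    correct-sentence SPA maps overlapping the planted PTA-sensitive region.
    The same regression applied to error-trial and noise-trial SPA maps
    (where no PTA effect is planted) supplies family-wise false-positive
    controls.
    """
    ss = np.random.SeedSequence(seed)
    hits = 0
    fp_error = 0
    fp_noise = 0
    for child in ss.spawn(n_seeds):
        study = cohort_spa_study(n_subjects=n_subjects, seed=child.entropy % (2 ** 31),
                                 groups=("sentence_correct", "noise", "error"))
        target = study.brainspec.regions["pta_sensitive"]
        ga = covariate_regression_analysis(study, "sentence_correct", "pta_db_hl")
        sig = [c for c in ga.table.clusters if c.p_fwe is not None and c.p_fwe < alpha]
        if any((c.voxels & target).any() for c in sig):
            hits += 1
        for group, counter in (("error", "fp_error"), ("noise", "fp_noise")):
            gan = covariate_regression_analysis(study, group, "pta_db_hl")
            any_sig = any(c.p_fwe is not None and c.p_fwe < alpha
                          for c in gan.table.clusters)
            if group == "error":
                fp_error += any_sig
            else:
                fp_noise += any_sig
    return {
        "pta_cluster_recovery_rate": hits / n_seeds,
        "error_trial_false_positive_rate": fp_error / n_seeds,
        "noise_trial_false_positive_rate": fp_noise / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# behavioral coefficient recovery
# ---------------------------------------------------------------------------

def behavior_recovery_study(n_replicates: int = 100, n_subjects: int = 200,
                            seed=0, ci_level: float = 0.95) -> dict:
    """Sign recovery and CI coverage for the planted logistic coefficients."""
    protocol = AcquisitionProtocol()
    coeffs = BehaviorCoefficients()
    ss = np.random.SeedSequence(seed)
    sign_pta = sign_int = cover_pta = cover_int = 0
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        cohort = make_cohort(n_subjects, seed=rng)
        design = make_design(protocol, seed=rng)
        records = simulate_behavior(cohort, design, coeffs, seed=rng)
        res = fit_accuracy_model(records, cohort)
        sign_pta += res["pta"]["estimate"] < 0
        sign_int += res["pta_x_syntax"]["estimate"] > 0
        lo, hi = res.ci("pta", ci_level)
        cover_pta += lo <= coeffs.b_pta <= hi
        lo, hi = res.ci("pta_x_syntax", ci_level)
        cover_int += lo <= coeffs.b_pta_x_syntax <= hi
    return {
        "pta_sign_recovery_rate": sign_pta / n_replicates,
        "interaction_sign_recovery_rate": sign_int / n_replicates,
        "pta_ci_coverage": cover_pta / n_replicates,
        "interaction_ci_coverage": cover_int / n_replicates,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# signal detection identities
# ---------------------------------------------------------------------------

def _records_from_confusion(n_hit, n_miss, n_fa, n_cr) -> pd.DataFrame:
    rows = []
    for resp, truth, n in (("male", "male", n_hit), ("female", "male", n_miss),
                           ("male", "female", n_fa), ("female", "female", n_cr)):
        rows += [{"subject_id": "s", "stimulus_class": "sentence",
                  "correct_answer": truth, "response": resp}] * n
    return pd.DataFrame(rows)


def sdt_oracle_study() -> dict:
    """d'/c on constructed confusion tables, with the label-swap symmetry."""
    rec = _records_from_confusion(45, 5, 5, 45)        # H=0.9, FA=0.1
    res = sdt_2afc(rec)
    oracle_d = float(ndtri(0.9) - ndtri(0.1))
    err = abs(res.d_prime - oracle_d)

    perfect = _records_from_confusion(50, 0, 0, 50)    # corrected to 1 - 1/100
    resp = sdt_2afc(perfect)
    oracle_perfect = float(ndtri(0.99) - ndtri(0.01))
    err = max(err, abs(resp.d_prime - oracle_perfect))

    swapped = sdt_2afc(rec, signal="female")
    sym_d = abs(res.d_prime - swapped.d_prime)
    sym_c = abs(res.criterion + swapped.criterion)
    return {
        "dprime_h90_fa10": res.d_prime,
        "sdt_oracle_max_abs_error": err,
        "label_swap_dprime_error": sym_d,
        "label_swap_criterion_error": sym_c,
    }
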