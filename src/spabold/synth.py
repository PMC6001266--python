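"""Ground-truth simulator: cohorts, trial designs, behavior, and ISSS BOLD.

Everything downstream (FIR estimation, SPA, group inference, cluster-level
FWE) is validated against data produced here, where regional effects,
behavioral coefficients, and noise are all known exactly.

The generator emulates a sentence-comprehension experiment in adults with
audiometrically normal but variable hearing: better-ear pure-tone average
(PTA, mean over 1/2/4 kHz in dB HL) spans roughly -5 to 23 dB HL, and the
planted brain effects mirror the phenomena of interest — a sentence-
responsive perisylvian core, an object-relative syntax increment, a
right-anterior prefrontal region whose correct-trial amplitude scales with
PTA, and error-responsive regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import ConfigurationError, InputError
from .hrf import double_gamma_hrf
from .protocol import AcquisitionProtocol

SENTENCE_CELLS = (
    ("subject_relative", "early"),
    ("subject_relative", "late"),
    ("object_relative", "early"),
    ("object_relative", "late"),
)

#: answer key: the agent is male in subject-relative items, female in
#: object-relative items (word-order rearrangement swaps the agent).
CORRECT_ANSWER = {"subject_relative": "male", "object_relative": "female"}

N_BASE_SENTENCES = 24
N_NOISE_TRIALS = 6
N_SILENCE_TRIALS = 6


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None (fresh entropy)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def make_cohort(n: int = 35,
                pta_mean: float = 3.5, pta_sd: float = 5.4,
                pta_range: tuple[float, float] = (-5.0, 23.3),
                age_mean: float = 25.8, age_sd: float = 4.6,
                age_range: tuple[float, float] = (18.0, 41.0),
                wm_mean: float = 1.76, wm_sd: float = 0.55,
                wm_range: tuple[float, float] = (0.0, 3.0),
                seed=None) -> pd.DataFrame:
    """Draw a cohort with PTA, age, and working-memory span covariates.

    Each covariate follows a truncated normal on its stated range; the
    defaults reproduce the cohort summary statistics of the study this
    simulator emulates.  Returns one row per subject with columns
    ``subject_id, pta_db_hl, age_years, wm_span, accuracy`` (accuracy is
    NaN until behavior has been simulated).
    """
    if n < 0:
        raise InputError(f"cohort size must be non-negative, got {n}")
    for name, (lo, hi) in (("pta_range", pta_range), ("age_range", age_range),
                           ("wm_range", wm_range)):
        if not lo < hi:
            raise InputError(f"{name} must satisfy lo < hi, got {(lo, hi)}")
    rng = as_rng(seed)

    def draw(mean, sd, lo, hi):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)

    return pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "pta_db_hl": draw(pta_mean, pta_sd, *pta_range),
        "age_years": draw(age_mean, age_sd, *age_range),
        "wm_span": draw(wm_mean, wm_sd, *wm_range),
        "accuracy": np.full(n, np.nan),
    })


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def make_design(protocol: AcquisitionProtocol, seed=None) -> pd.DataFrame:
    """Build the per-run trial schedule.

    Each run holds 24 sentence trials (6 per syntax x phrase-position cell),
    6 one-channel vocoded-noise trials, and 6 silence trials in randomized
    order.  Sentence stimuli come from 24 base sentences crossed with the
    four cells (96 stimuli); every run presents exactly one variant of each
    base sentence, and across the four runs each (base, variant) pair occurs
    exactly once (a Latin-square assignment of variants to runs).
    """
    n_sentence = N_BASE_SENTENCES
    expected = n_sentence + N_NOISE_TRIALS + N_SILENCE_TRIALS
    if protocol.trials_per_run != expected:
        raise ConfigurationError(
            f"trials_per_run={protocol.trials_per_run} inconsistent with the "
            f"{n_sentence}+{N_NOISE_TRIALS}+{N_SILENCE_TRIALS} trial composition")
    if protocol.n_runs != len(SENTENCE_CELLS):
        raise ConfigurationError(
            "the Latin-square stimulus rotation requires as many runs as "
            f"sentence cells ({len(SENTENCE_CELLS)}); got n_runs={protocol.n_runs}")
    rng = as_rng(seed)

    base_order = rng.permutation(N_BASE_SENTENCES) + 1
    groups = base_order.reshape(len(SENTENCE_CELLS), -1)  # 4 groups of 6 bases
    cell_perm = rng.permutation(len(SENTENCE_CELLS))

    rows = []
    for run in range(protocol.n_runs):
        trials = []
        for g, bases in enumerate(groups):
            syntax, position = SENTENCE_CELLS[cell_perm[(g + run) % len(SENTENCE_CELLS)]]
            for base in bases:
                trials.append(("sentence", syntax, position, int(base),
                               CORRECT_ANSWER[syntax]))
        trials += [("vocoded_noise", None, None, None, None)] * N_NOISE_TRIALS
        trials += [("silence", None, None, None, None)] * N_SILENCE_TRIALS
        order = rng.permutation(len(trials))
        for idx, j in enumerate(order):
            cls, syntax, position, base, answer = trials[j]
            rows.append({
                "run_index": run + 1,
                "trial_index": idx,
                "onset_s": idx * protocol.trial_duration_s,
                "stimulus_class": cls,
                "syntax": syntax,
                "phrase_position": position,
                "base_sentence_id": base,
                "correct_answer": answer,
            })
    df = pd.DataFrame(rows)
    df["base_sentence_id"] = df["base_sentence_id"].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorCoefficients:
    """Generative logistic model for trial correctness.

    The linear predictor on sentence trials is

        b0 + b_pta*PTAc + b_age*AGEc + b_wm*WMc + b_syntax*[object-relative]
           + b_position*[early] + b_pta_x_syntax*PTAc*[object-relative] + u_subject

    with covariates centered at cohort means and u_subject ~ N(0, subject_sd^2).
    Defaults give ~87% mean accuracy, a negative PTA effect (poorer hearing,
    more errors), a cost for object-relative syntax, and a positive
    PTA x syntax interaction, mirroring the behavioral pattern of interest.
    """

    b0: float = 2.2
    b_pta: float = -0.05
    b_age: float = -0.02
    b_wm: float = 0.3
    b_syntax: float = -0.5
    b_position: float = 0.0
    b_pta_x_syntax: float = 0.02
    subject_sd: float = 0.5

    def validate(self) -> None:
        vals = [self.b0, self.b_pta, self.b_age, self.b_wm, self.b_syntax,
                self.b_position, self.b_pta_x_syntax, self.subject_sd]
        if not all(np.isfinite(vals)):
            raise InputError("behavior coefficients must all be finite")


def simulate_behavior(cohort: pd.DataFrame, design, coeffs: BehaviorCoefficients | None = None,
                      seed=None) -> pd.DataFrame:
    """Draw trialwise responses for every subject.

    ``design`` is either a single schedule shared by all subjects or a
    mapping ``subject_id -> schedule``.  Sentence-trial correctness follows
    the logistic model in :class:`BehaviorCoefficients`; noise trials record
    a random button press (any press counts as compliant, so ``is_correct``
    is True); silence trials carry neither response nor correctness.

    Side effect: ``cohort['accuracy']`` is filled with each subject's
    realized proportion correct over sentence trials.
    """
    coeffs = coeffs or BehaviorCoefficients()
    coeffs.validate()
    rng = as_rng(seed)

    if isinstance(design, pd.DataFrame):
        designs = {sid: design for sid in cohort["subject_id"]}
    else:
        designs = dict(design)
        missing = set(cohort["subject_id"]) - set(designs)
        if missing:
            raise InputError(f"no design for subjects: {sorted(missing)}")

    frames = []
    subject_u = {}
    for sid in cohort["subject_id"]:
        # one random-intercept draw per subject, consumed in cohort order
        subject_u[sid] = rng.normal(0.0, coeffs.subject_sd)
        d = designs[sid]
        sent_rows = d["stimulus_class"] == "sentence"
        if d.loc[sent_rows, ["syntax", "phrase_position"]].isna().any().any():
            raise InputError("every sentence trial must carry a syntax/position cell")
        rec = d[["run_index", "trial_index", "stimulus_class", "syntax",
                 "phrase_position", "correct_answer"]].copy()
        rec.insert(0, "subject_id", sid)
        frames.append(rec)
    records = pd.concat(frames, ignore_index=True)

    centered = pd.DataFrame({
        "subject_id": cohort["subject_id"],
        "pta_c": cohort["pta_db_hl"] - cohort["pta_db_hl"].mean(),
        "age_c": cohort["age_years"] - cohort["age_years"].mean(),
        "wm_c": cohort["wm_span"] - cohort["wm_span"].mean(),
        "u": cohort["subject_id"].map(subject_u),
    })
    cov = records[["subject_id"]].merge(centered, on="subject_id", how="left")

    is_sent = (records["stimulus_class"] == "sentence").to_numpy()
    is_noise = (records["stimulus_class"] == "vocoded_noise").to_numpy()
    is_or = (records["syntax"] == "object_relative").to_numpy(float)
    is_early = (records["phrase_position"] == "early").to_numpy(float)
    lin = (coeffs.b0 + coeffs.b_pta * cov["pta_c"].to_numpy()
           + coeffs.b_age * cov["age_c"].to_numpy()
           + coeffs.b_wm * cov["wm_c"].to_numpy()
           + coeffs.b_syntax * is_or + coeffs.b_position * is_early
           + coeffs.b_pta_x_syntax * cov["pta_c"].to_numpy() * is_or
           + cov["u"].to_numpy())
    correct_draw = rng.random(len(records)) < expit(lin)
    noise_press = rng.random(len(records)) < 0.5

    truth = records["correct_answer"].to_numpy(object)
    other = np.where(truth == "male", "female", "male")
    response = np.full(len(records), None, dtype=object)
    response[is_sent] = np.where(correct_draw, truth, other)[is_sent]
    response[is_noise] = np.where(noise_press, "male", "female")[is_noise]

    is_correct = np.full(len(records), pd.NA, dtype=object)
    is_correct[is_sent] = correct_draw[is_sent]
    is_correct[is_noise] = True  # any button press is acceptable on noise

    records["response"] = response
    records["is_correct"] = pd.array(is_correct, dtype="boolean")

    acc = (records.loc[is_sent].assign(ok=correct_draw[is_sent])
           .groupby("subject_id")["ok"].mean())
    cohort["accuracy"] = cohort["subject_id"].map(acc)
    return records


# ---------------------------------------------------------------------------
# brain specification
# ---------------------------------------------------------------------------

@dataclass
class BrainSpec:
    """Ground-truth regional effects planted in the simulated BOLD data.

    Region rules (per trial, peak-normalized HRF units):
      language_core     +a_sentence on sentence trials
      syntax_sensitive  +a_sentence on sentence trials, plus +a_syntax on
                        object-relative trials (the region sits inside the
                        language network, so it carries the sentence
                        response with an object-relative increment)
      pta_sensitive     +slope_pta * (PTA - cohort mean) on *correct*
                        sentence trials only
      error_sensitive   +a_error on incorrect trials

    Noise is spatially smoothed white Gaussian with marginal SD
    ``noise_sd`` (an optional AR(1) switch adds temporal autocorrelation),
    plus a per-run sinusoidal low-frequency drift.
    """

    brain_mask: np.ndarray
    regions: dict[str, np.ndarray]
    baseline: float = 100.0
    a_sentence: float = 3.0
    a_syntax: float = 1.5
    slope_pta: float = 0.1
    a_error: float = 2.0
    noise_sd: float = 1.0
    drift_amplitude: float = 1.0
    drift_period_s: float = 240.0
    ar_rho: float = 0.0

    REGION_NAMES = ("language_core", "syntax_sensitive", "pta_sensitive", "error_sensitive")

    def validate(self, grid_shape: tuple[int, int, int]) -> None:
        if self.brain_mask.shape != tuple(grid_shape):
            raise InputError(f"brain mask shape {self.brain_mask.shape} does not match grid {grid_shape}")
        for name in self.REGION_NAMES:
            if name not in self.regions:
                raise InputError(f"missing region mask: {name}")
        total = np.zeros(grid_shape, dtype=int)
        for name, mask in self.regions.items():
            if mask.shape != tuple(grid_shape):
                raise InputError(f"region {name} shape {mask.shape} does not match grid")
            if np.any(mask & ~self.brain_mask):
                raise InputError(f"region {name} extends outside the brain mask")
            total += mask.astype(int)
        if np.any(total > 1):
            raise InputError("region masks must be disjoint")
        if not 0 <= self.ar_rho < 1:
            raise InputError("ar_rho must lie in [0, 1)")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise InputError("noise_sd and drift_amplitude must be non-negative")


def _sphere(grid_shape, center, radius) -> np.ndarray:
    idx = np.indices(grid_shape, dtype=float)
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius ** 2


def default_brainspec(protocol: AcquisitionProtocol, **overrides) -> BrainSpec:
    """Ellipsoidal brain with four disjoint spherical effect regions.

    Placement is lateralized the way the emulated phenomena are: the
    sentence and syntax regions sit in the left hemisphere, the
    PTA-sensitive region right-anterior, and the error region medial.
    """
    shape = tuple(protocol.grid_shape)
    center = (np.asarray(shape, float) - 1.0) / 2.0
    semi = np.maximum(np.asarray(shape, float) / 2.0 - 1.5, 1.0)
    idx = np.indices(shape, dtype=float)
    brain = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3)) <= 1.0

    # centers as fractions of the grid so any grid size yields a valid spec
    span = np.asarray(shape, float) - 1.0
    r_big = max(0.125 * min(shape), 1.2)
    r_small = max(0.1 * min(shape), 1.2)
    placements = {
        "language_core": ((0.25, 0.50, 0.45), r_big),       # left perisylvian
        "syntax_sensitive": ((0.25, 0.78, 0.60), r_small),  # left anterior
        "pta_sensitive": ((0.75, 0.72, 0.58), r_big),       # right anterior
        "error_sensitive": ((0.50, 0.22, 0.62), r_small),   # medial
    }
    regions = {
        name: _sphere(shape, np.round(np.asarray(frac) * span), radius)
        for name, (frac, radius) in placements.items()
    }
    regions = {k: (v & brain) for k, v in regions.items()}
    spec = BrainSpec(brain_mask=brain, regions=regions, **overrides)
    spec.validate(shape)
    return spec


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

@dataclass
class VolumeSeries:
    """Discontinuous 4D series: only acquisition-window volumes exist.

    ``data`` is (x, y, z, volume); ``volume_times_s`` is each volume's
    acquisition timestamp measured from its run's start; ``run_of_volume``
    is the 1-based run label per volume.
    """

    data: np.ndarray
    volume_times_s: np.ndarray
    run_of_volume: np.ndarray
    brain_mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        n = self.data.shape[-1]
        if len(self.volume_times_s) != n or len(self.run_of_volume) != n:
            raise InputError("volume_times_s and run_of_volume must match the number of volumes")
        for run in np.unique(self.run_of_volume):
            t = self.volume_times_s[self.run_of_volume == run]
            if np.any(np.diff(t) <= 0):
                raise InputError(f"timestamps must strictly increase within run {run}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


def _smoothed_noise_scale(sigma_vox: np.ndarray, truncate: float = 4.0) -> float:
    """SD of unit white noise after separable Gaussian smoothing.

    Computed from the discrete kernels actually applied, so the rescaling
    to ``noise_sd`` is exact rather than relying on the continuous
    ``(4 pi sigma^2)^(-3/4)`` approximation.
    """
    factor = 1.0
    for s in sigma_vox:
        if s <= 0:
            continue
        r = int(truncate * s + 0.5)
        x = np.arange(-r, r + 1, dtype=float)
        w = np.exp(-0.5 * (x / s) ** 2)
        w /= w.sum()
        factor *= float(np.sum(w ** 2))
    return float(np.sqrt(factor))


def simulate_bold(subject, design: pd.DataFrame, behavior: pd.DataFrame,
                  brainspec: BrainSpec, protocol: AcquisitionProtocol,
                  seed=None, pta_center: float = 0.0):
    """Simulate one subject's ISSS volume series plus motion confounds.

    Every non-silence trial contributes a double-gamma response sampled at
    the acquired volume times (stimulus onset = trial onset +
    ``stimulus_delay_s``), scaled per the :class:`BrainSpec` region rules.
    The HRF tail extending past the 14-s trial window into later
    acquisitions of the same run is simulated truthfully.  Returns
    ``(VolumeSeries, motion)`` where ``motion`` is an (n_volumes, 6) array
    of synthetic head-motion nuisance series.

    ``pta_center`` is the cohort-mean PTA against which the PTA-sensitive
    amplitude is expressed.
    """
    brainspec.validate(protocol.grid_shape)
    rng = as_rng(seed)
    pta = float(subject["pta_db_hl"])
    sid = subject["subject_id"]

    beh = behavior
    if "subject_id" in beh.columns:
        beh = beh[beh["subject_id"] == sid]
    merged = design.merge(
        beh[["run_index", "trial_index", "is_correct"]],
        on=["run_index", "trial_index"], how="left", validate="one_to_one")
    needs = merged["stimulus_class"].isin(["sentence", "vocoded_noise"])
    if merged.loc[needs, "is_correct"].isna().any():
        raise InputError(f"behavior missing for some trials of {sid}")

    shape = tuple(protocol.grid_shape)
    nvol = protocol.n_volumes
    vpr = protocol.volumes_per_run
    vol_times = np.tile(protocol.run_volume_times(), protocol.n_runs)
    run_labels = protocol.series_run_labels()
    run_slices = {run: slice((run - 1) * vpr, run * vpr)
                  for run in range(1, protocol.n_runs + 1)}

    # time-major layout: per-volume smoothing and per-run slicing stay cheap;
    # the noiseless path runs in float64 so analytic recovery is exact
    if brainspec.noise_sd > 0:
        data = rng.standard_normal((nvol,) + shape, dtype=np.float32)
        if brainspec.ar_rho > 0:
            rho = brainspec.ar_rho
            innov = np.sqrt(1.0 - rho ** 2)
            for sl in run_slices.values():
                x = data[sl]
                for t in range(1, x.shape[0]):
                    x[t] = rho * x[t - 1] + innov * x[t]
        sigma_vox = np.full(3, protocol.smoothing_fwhm_mm
                            / (2.0 * np.sqrt(2.0 * np.log(2.0))) / protocol.voxel_size_mm)
        ndimage.gaussian_filter(data, sigma=(0.0, *sigma_vox), output=data, truncate=3.0)
        data *= brainspec.noise_sd / _smoothed_noise_scale(sigma_vox, truncate=3.0)
    else:
        data = np.zeros((nvol,) + shape, dtype=np.float64)

    brain = brainspec.brain_mask
    data[:, brain] += brainspec.baseline

    if brainspec.drift_amplitude > 0:
        for run, sl in run_slices.items():
            phase = rng.uniform(0.0, 2.0 * np.pi)
            drift = brainspec.drift_amplitude * np.sin(
                2.0 * np.pi * vol_times[sl] / brainspec.drift_period_s + phase)
            data[sl.start:sl.stop, brain] += drift[:, None].astype(data.dtype)

    run_times = protocol.run_volume_times()
    for run in range(1, protocol.n_runs + 1):
        rows = merged[merged["run_index"] == run]
        sl = run_slices[run]
        is_sent = (rows["stimulus_class"] == "sentence").to_numpy()
        is_noise_trial = (rows["stimulus_class"] == "vocoded_noise").to_numpy()
        is_event = is_sent | is_noise_trial
        if not is_event.any():
            continue
        stim_t = (rows["onset_s"].to_numpy(float) + protocol.stimulus_delay_s)[is_event]
        is_or = (rows["syntax"] == "object_relative").to_numpy()[is_event]
        correct = rows["is_correct"].fillna(False).to_numpy(bool)[is_event]
        sent = is_sent[is_event]

        amps = {
            "language_core": np.where(sent, brainspec.a_sentence, 0.0),
            "syntax_sensitive": np.where(sent, brainspec.a_sentence, 0.0)
            + np.where(sent & is_or, brainspec.a_syntax, 0.0),
            "pta_sensitive": np.where(sent & correct,
                                      brainspec.slope_pta * (pta - pta_center), 0.0),
            "error_sensitive": np.where(sent & ~correct, brainspec.a_error, 0.0),
        }
        lags = run_times[:, None] - stim_t[None, :]
        H = double_gamma_hrf(lags)
        for name, amp in amps.items():
            if not np.any(amp):
                continue
            series = (H @ amp).astype(data.dtype)
            mask = brainspec.regions[name]
            data[sl, mask] += series[:, None]

    motion = np.cumsum(rng.normal(0.0, 0.02, size=(nvol, 6)), axis=0)

    series = VolumeSeries(
        data=np.moveaxis(data, 0, -1),
        volume_times_s=vol_times,
        run_of_volume=run_labels,
        brain_mask=brain,
        affine=protocol.affine(),
    )
    return series, motion
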