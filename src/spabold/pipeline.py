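"""End-to-end orchestration: cohort simulation through group cluster tables.

This module wires the stages together the way the command-line interface
and the validation studies use them: simulate a cohort subject by subject,
fit the first-level FIR model, form composite SPA maps per analysis group,
and run second-level contrasts/regressions with random-field cluster
inference.  Subjects are processed streaming (one 4D series in memory at a
time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import (ClusterTable, SmoothnessEstimate, cluster_table,
                       estimate_smoothness)
from .design import build_design_matrix
from .errors import ConditionAbsent, InputError
from .firstlevel import BetaMaps, SpaMap, fit_glm, spa_group_average
from .group import StatMap, paired_t, regress_covariate, residualize
from .protocol import AcquisitionProtocol
from .synth import (BehaviorCoefficients, BrainSpec, default_brainspec,
                    make_cohort, make_design, simulate_behavior, simulate_bold)

#: composite analysis conditions -> first-level event types averaged
ANALYSIS_GROUPS = {
    "sentence_correct": ("sr_early_correct", "sr_late_correct",
                         "or_early_correct", "or_late_correct"),
    "sr_correct": ("sr_early_correct", "sr_late_correct"),
    "or_correct": ("or_early_correct", "or_late_correct"),
    "error": ("sr_early_incorrect", "sr_late_incorrect",
              "or_early_incorrect", "or_late_incorrect"),
    "noise": ("noise",),
}


@dataclass
class SpaStudy:
    """Per-subject composite SPA maps plus the cohort covariates."""

    cohort: pd.DataFrame
    maps: dict[str, list[SpaMap]]          # group -> SpaMap per subject (may skip subjects)
    mask: np.ndarray
    affine: np.ndarray
    protocol: AcquisitionProtocol
    brainspec: BrainSpec
    behavior: pd.DataFrame | None = None

    def maps_and_covariate(self, group: str, covariate: str):
        """Maps of one group with the covariate values of their subjects."""
        maps = self.maps[group]
        ids = [m.subject_id for m in maps]
        cov = self.cohort.set_index("subject_id").loc[ids, covariate].to_numpy(float)
        return maps, cov


def subject_first_level(subject, design: pd.DataFrame, behavior: pd.DataFrame,
                        brainspec: BrainSpec, protocol: AcquisitionProtocol,
                        seed=None, pta_center: float = 0.0,
                        hp_cutoff_s: float | None = 128.0,
                        keep_residuals: bool = False) -> BetaMaps:
    """Simulate one subject's BOLD series and fit the first-level model."""
    series, motion = simulate_bold(subject, design, behavior, brainspec,
                                   protocol, seed=seed, pta_center=pta_center)
    dm = build_design_matrix(design, behavior, protocol, motion=motion,
                             hp_cutoff_s=hp_cutoff_s)
    return fit_glm(series, dm, keep_residuals=keep_residuals)


def cohort_spa_study(n_subjects: int = 35, seed=0,
                     protocol: AcquisitionProtocol | None = None,
                     brainspec: BrainSpec | None = None,
                     coeffs: BehaviorCoefficients | None = None,
                     groups=("sentence_correct", "noise", "error"),
                     hp_cutoff_s: float | None = 128.0) -> SpaStudy:
    """Simulate a cohort and return composite SPA maps per analysis group.

    A subject contributes to a group only if at least one of its member
    event types was estimable (e.g. subjects with no errors are absent from
    the ``error`` group); downstream group analyses therefore apply
    listwise exclusion per group.
    """
    protocol = protocol or AcquisitionProtocol()
    brainspec = brainspec or default_brainspec(protocol)
    coeffs = coeffs or BehaviorCoefficients()
    unknown = [g for g in groups if g not in ANALYSIS_GROUPS]
    if unknown:
        raise InputError(f"unknown analysis groups {unknown}; "
                         f"valid: {sorted(ANALYSIS_GROUPS)}")

    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(2 * n_subjects + 2)
    cohort = make_cohort(n_subjects, seed=np.random.default_rng(kids[0]))
    designs = {sid: make_design(protocol, seed=np.random.default_rng(kids[1 + i]))
               for i, sid in enumerate(cohort["subject_id"])}
    behavior = simulate_behavior(cohort, designs, coeffs,
                                 seed=np.random.default_rng(kids[1 + n_subjects]))
    pta_center = float(cohort["pta_db_hl"].mean())

    maps: dict[str, list[SpaMap]] = {g: [] for g in groups}
    for i, subject in enumerate(cohort.to_dict("records")):
        sid = subject["subject_id"]
        beh = behavior[behavior["subject_id"] == sid]
        betas = subject_first_level(
            subject, designs[sid], beh, brainspec, protocol,
            seed=np.random.default_rng(kids[2 + n_subjects + i]),
            pta_center=pta_center, hp_cutoff_s=hp_cutoff_s)
        for g in groups:
            try:
                maps[g].append(spa_group_average(betas, ANALYSIS_GROUPS[g], g,
                                                 subject_id=sid))
            except ConditionAbsent:
                continue

    return SpaStudy(cohort=cohort, maps=maps, mask=brainspec.brain_mask,
                    affine=protocol.affine(), protocol=protocol,
                    brainspec=brainspec, behavior=behavior)


# ---------------------------------------------------------------------------
# group analyses on a study
# ---------------------------------------------------------------------------

@dataclass
class GroupAnalysis:
    statmap: StatMap
    smoothness: SmoothnessEstimate
    table: ClusterTable


def _finish(statmap: StatMap, study: SpaStudy, p_voxel: float,
            fwe_alpha: float, negative: bool) -> GroupAnalysis:
    resid4d = np.zeros(study.mask.shape + (statmap.residuals.shape[0],), np.float32)
    resid4d[study.mask] = statmap.residuals.T
    sm = estimate_smoothness(resid4d, study.mask, statmap.df,
                             study.protocol.voxel_size_mm)
    table = cluster_table(statmap, sm, p_voxel=p_voxel, fwe_alpha=fwe_alpha,
                          negative=negative)
    return GroupAnalysis(statmap=statmap, smoothness=sm, table=table)


def paired_contrast_analysis(study: SpaStudy, a: str, b: str,
                             p_voxel: float = 0.001, fwe_alpha: float = 0.05,
                             negative: bool = False) -> GroupAnalysis:
    """Paired t contrast (a > b) restricted to subjects present in both groups."""
    ids_a = {m.subject_id for m in study.maps[a]}
    ids_b = {m.subject_id for m in study.maps[b]}
    shared = [sid for sid in study.cohort["subject_id"] if sid in ids_a & ids_b]
    sel_a = [m for m in study.maps[a] if m.subject_id in shared]
    sel_b = [m for m in study.maps[b] if m.subject_id in shared]
    statmap = paired_t(sel_a, sel_b, label=f"{a}_gt_{b}")
    return _finish(statmap, study, p_voxel, fwe_alpha, negative)


def covariate_regression_analysis(study: SpaStudy, group: str,
                                  covariate: str = "pta_db_hl",
                                  residualize_on=(),
                                  p_voxel: float = 0.001,
                                  fwe_alpha: float = 0.05,
                                  negative: bool = False) -> GroupAnalysis:
    """Voxelwise covariate regression on one group's SPA maps.

    ``residualize_on`` names cohort columns regressed out of the covariate
    first (the residualized value enters the voxelwise regression), the
    scheme used for the hearing-acuity analyses with age, working memory,
    and accuracy controlled.  Subjects missing any involved covariate are
    excluded listwise.
    """
    maps = study.maps[group]
    ids = [m.subject_id for m in maps]
    cov_frame = study.cohort.set_index("subject_id").loc[
        ids, [covariate, *residualize_on]]
    keep = ~cov_frame.isna().any(axis=1)
    maps = [m for m, k in zip(maps, keep) if k]
    cov_frame = cov_frame[keep.to_numpy()]
    x = cov_frame[covariate].to_numpy(float)
    label = covariate
    if residualize_on:
        others = [cov_frame[c].to_numpy(float) for c in residualize_on]
        x = residualize(x, others)
        label = f"{covariate}_resid_{'_'.join(residualize_on)}"
    statmap = regress_covariate(maps, x, label=f"{label}_on_{group}")
    return _finish(statmap, study, p_voxel, fwe_alpha, negative)
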