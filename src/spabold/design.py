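"""First-level design matrices for the discontinuous ISSS series.

Each non-silence event type receives one finite-impulse-response (FIR)
indicator column per acquired post-trial volume, so the response at each of
the five acquisition lags is estimated freely, with sentence trials split
by behavioral accuracy.  Nuisance structure mirrors the analysis this
package reimplements: six motion regressors, one intercept per run (no
global intercept), and a per-run discrete-cosine drift basis implementing
high-pass filtering with a 128-s cutoff.  Silence trials are never modeled:
they are the implicit baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .protocol import AcquisitionProtocol

_SYNTAX_ABBREV = {"subject_relative": "sr", "object_relative": "or"}

#: canonical event-type order: four sentence cells x accuracy, then noise
EVENT_TYPES = tuple(
    f"{abbrev}_{pos}_{acc}"
    for abbrev in ("sr", "or")
    for pos in ("early", "late")
    for acc in ("correct", "incorrect")
) + ("noise",)

SENTENCE_CORRECT = tuple(e for e in EVENT_TYPES if e.endswith("_correct"))
SENTENCE_INCORRECT = tuple(e for e in EVENT_TYPES if e.endswith("_incorrect"))


def event_type_of(stimulus_class: str, syntax, phrase_position, is_correct) -> str | None:
    """Map a trial to its FIR event family; None for silence (baseline)."""
    if stimulus_class == "silence":
        return None
    if stimulus_class == "vocoded_noise":
        # any button press was acceptable, so noise gets no accuracy split
        return "noise"
    if stimulus_class == "sentence":
        if syntax not in _SYNTAX_ABBREV or phrase_position not in ("early", "late"):
            raise InputError(f"sentence trial with undefined cell: {syntax!r}/{phrase_position!r}")
        if pd.isna(is_correct):
            raise InputError("sentence trial without a behavioral accuracy")
        acc = "correct" if bool(is_correct) else "incorrect"
        return f"{_SYNTAX_ABBREV[syntax]}_{phrase_position}_{acc}"
    raise InputError(f"unknown stimulus class: {stimulus_class!r}")


def dct_basis(timestamps: np.ndarray, cutoff_s: float, run_duration_s: float,
              tr_s: float) -> np.ndarray:
    """Discrete-cosine drift columns evaluated at gapped acquisition times.

    Returns ``floor(2 * run_duration / cutoff)`` columns with periods longer
    than ``cutoff_s``.  Because the ISSS series is sampled on a gapped grid,
    cosines evaluated at the actual timestamps are not exactly zero-mean;
    each column is therefore explicitly demeaned over the run.
    """
    if cutoff_s <= 2.0 * tr_s:
        raise ConfigurationError(
            f"high-pass cutoff {cutoff_s}s must exceed twice the TR ({tr_s}s)")
    timestamps = np.asarray(timestamps, dtype=float)
    n_cols = int(np.floor(2.0 * run_duration_s / cutoff_s))
    if n_cols <= 0:
        return np.empty((len(timestamps), 0))
    x = timestamps / run_duration_s
    cols = np.cos(np.pi * np.outer(x, np.arange(1, n_cols + 1)))
    cols -= cols.mean(axis=0, keepdims=True)
    return cols


@dataclass
class DesignMatrix:
    """Labeled first-level design: rows = acquired volumes, columns = regressors."""

    matrix: np.ndarray
    columns: list[str]
    fir_events: dict[str, int]      # instantiated event type -> trial count
    omitted_events: list[str]       # event types with zero trials
    row_run: np.ndarray
    row_time: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column_index(self, label: str) -> int:
        try:
            return self.columns.index(label)
        except ValueError:
            raise KeyError(label) from None

    def fir_columns(self, event_type: str) -> list[int]:
        prefix = f"{event_type}:fir"
        return [i for i, c in enumerate(self.columns) if c.startswith(prefix)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.columns)
        df.insert(0, "run", self.row_run)
        df.insert(1, "time_s", self.row_time)
        return df


def build_design_matrix(design: pd.DataFrame, behavior: pd.DataFrame,
                        protocol: AcquisitionProtocol,
                        motion: np.ndarray | None = None,
                        hp_cutoff_s: float | None = 128.0) -> DesignMatrix:
    """Assemble the FIR + nuisance design for one subject.

    ``behavior`` supplies trialwise accuracy used to split sentence events
    into correct/incorrect families; event types with zero trials are
    omitted (never emitted as all-zero columns) and recorded in
    ``omitted_events``.  ``motion`` is an (n_volumes, 6) confound array,
    demeaned per run; pass None to build a motion-free design.
    ``hp_cutoff_s=None`` disables the drift basis.
    """
    if "subject_id" in behavior.columns and behavior["subject_id"].nunique() > 1:
        raise InputError("behavior table mixes multiple subjects; filter first")
    beh_cols = behavior[["run_index", "trial_index", "is_correct"]]
    merged = design.merge(beh_cols, on=["run_index", "trial_index"],
                          how="left", validate="one_to_one")

    vpt = protocol.volumes_per_trial
    nvol = protocol.n_volumes
    run_times = protocol.run_volume_times()
    row_time = np.tile(run_times, protocol.n_runs)
    row_run = protocol.series_run_labels()

    trial_rows = {}  # event type -> list of first-volume row indices
    for t in merged.itertuples(index=False):
        etype = event_type_of(t.stimulus_class, t.syntax, t.phrase_position, t.is_correct)
        if etype is None:
            continue
        row0 = (t.run_index - 1) * protocol.volumes_per_run + t.trial_index * vpt
        trial_rows.setdefault(etype, []).append(row0)

    fir_events = {e: len(trial_rows[e]) for e in EVENT_TYPES if e in trial_rows}
    omitted = [e for e in EVENT_TYPES if e not in trial_rows]

    blocks, labels = [], []
    for etype in fir_events:
        cols = np.zeros((nvol, vpt))
        for row0 in trial_rows[etype]:
            for k in range(vpt):
                cols[row0 + k, k] = 1.0
        blocks.append(cols)
        labels += [f"{etype}:fir{k + 1}" for k in range(vpt)]

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (nvol, 6):
            raise InputError(f"motion series must be ({nvol}, 6), got {motion.shape}")
        motion = motion.copy()
        for run in range(1, protocol.n_runs + 1):
            sl = row_run == run
            motion[sl] -= motion[sl].mean(axis=0, keepdims=True)
        blocks.append(motion)
        labels += [f"motion{j + 1}" for j in range(6)]

    for run in range(1, protocol.n_runs + 1):
        col = (row_run == run).astype(float)[:, None]
        blocks.append(col)
        labels.append(f"run{run}:intercept")

    if hp_cutoff_s is not None:
        for run in range(1, protocol.n_runs + 1):
            sl = row_run == run
            drift = dct_basis(row_time[sl], hp_cutoff_s, protocol.run_duration_s,
                              protocol.tr_s)
            cols = np.zeros((nvol, drift.shape[1]))
            cols[sl] = drift
            blocks.append(cols)
            labels += [f"run{run}:dct{k + 1}" for k in range(drift.shape[1])]

    matrix = np.concatenate(blocks, axis=1)
    return DesignMatrix(matrix=matrix, columns=labels, fir_events=fir_events,
                        omitted_events=omitted, row_run=row_run, row_time=row_time)
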