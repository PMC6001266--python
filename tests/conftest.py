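import pandas as pd
import pytest

from spabold import (AcquisitionProtocol, BehaviorCoefficients,
                     default_brainspec, make_cohort, make_design,
                     simulate_behavior)


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def small_protocol():
    """Few trials on a small grid: fast full-pipeline unit tests."""
    return AcquisitionProtocol(n_runs=2, trials_per_run=6, grid_shape=(10, 12, 10))


@pytest.fixture(scope="session")
def brainspec(protocol):
    return default_brainspec(protocol)


@pytest.fixture(scope="session")
def design(protocol):
    return make_design(protocol, seed=11)


@pytest.fixture(scope="session")
def cohort_with_behavior(protocol, design):
    cohort = make_cohort(8, seed=21)
    records = simulate_behavior(cohort, design, BehaviorCoefficients(), seed=22)
    return cohort, records


def mini_design(protocol, classes_per_run):
    """Hand-built schedule from explicit per-run trial class tuples.

    Each class is either ``"silence"``, ``"vocoded_noise"``, or a
    ``(syntax, position, is_correct)`` triple for a sentence trial.
    Returns (design, behavior) frames for one subject.
    """
    rows, brows = [], []
    for run, classes in enumerate(classes_per_run, start=1):
        assert len(classes) == protocol.trials_per_run
        for idx, cls in enumerate(classes):
            onset = idx * protocol.trial_duration_s
            if cls in ("silence", "vocoded_noise"):
                rows.append(dict(run_index=run, trial_index=idx, onset_s=onset,
                                 stimulus_class=cls, syntax=None,
                                 phrase_position=None, base_sentence_id=None,
                                 correct_answer=None))
                brows.append(dict(run_index=run, trial_index=idx,
                                  stimulus_class=cls, syntax=None,
                                  phrase_position=None, correct_answer=None,
                                  response="male" if cls == "vocoded_noise" else None,
                                  is_correct=True if cls == "vocoded_noise" else pd.NA))
            else:
                syntax, position, ok = cls
                answer = "male" if syntax == "subject_relative" else "female"
                rows.append(dict(run_index=run, trial_index=idx, onset_s=onset,
                                 stimulus_class="sentence", syntax=syntax,
                                 phrase_position=position, base_sentence_id=1,
                                 correct_answer=answer))
                brows.append(dict(run_index=run, trial_index=idx,
                                  stimulus_class="sentence", syntax=syntax,
                                  phrase_position=position, correct_answer=answer,
                                  response=answer if ok else
                                  ("female" if answer == "male" else "male"),
                                  is_correct=ok))
    design = pd.DataFrame(rows)
    behavior = pd.DataFrame(brows)
    behavior["is_correct"] = behavior["is_correct"].astype("boolean")
    return design, behavior
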