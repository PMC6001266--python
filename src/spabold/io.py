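"""Readers, writers, and configuration for the on-disk pipeline layout.

Volumes are NIfTI-1; tabular data are tab-separated with header rows
(events tables follow the BIDS convention of onset / duration / trial_type
leading columns); configuration is YAML validated against the schema of
:class:`PipelineConfig`.  Every stage writes a provenance sidecar carrying
the resolved seed and a hash of the resolved configuration, so any output
is reproducible from its sidecar alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .protocol import AcquisitionProtocol
from .synth import BehaviorCoefficients


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BrainSpecParams:
    """Scalar knobs of the simulator's ground truth (masks are generated)."""

    baseline: float = 100.0
    a_sentence: float = 3.0
    a_syntax: float = 1.5
    slope_pta: float = 0.1
    a_error: float = 2.0
    noise_sd: float = 1.0
    drift_amplitude: float = 1.0
    drift_period_s: float = 240.0
    ar_rho: float = 0.0


@dataclass(frozen=True)
class Thresholds:
    p_voxel: float = 0.001
    fwe_alpha: float = 0.05


@dataclass(frozen=True)
class PipelineConfig:
    n_subjects: int = 35
    seed: int = 0
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    brainspec: BrainSpecParams = field(default_factory=BrainSpecParams)
    behavior: BehaviorCoefficients = field(default_factory=BehaviorCoefficients)
    thresholds: Thresholds = field(default_factory=Thresholds)

    _SECTIONS = {"protocol": AcquisitionProtocol, "brainspec": BrainSpecParams,
                 "behavior": BehaviorCoefficients, "thresholds": Thresholds}

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs = {}
        for section, typ in cls._SECTIONS.items():
            if section not in raw:
                raise ConfigurationError(f"config missing required field: {section}")
            body = raw.pop(section)
            valid = {f.name for f in dataclasses.fields(typ)}
            unknown = set(body) - valid
            if unknown:
                raise ConfigurationError(
                    f"unknown keys in {section}: {sorted(unknown)}")
            if "grid_shape" in body:
                body["grid_shape"] = tuple(body["grid_shape"])
            kwargs[section] = typ(**body)
        for scalar in ("n_subjects", "seed"):
            if scalar not in raw:
                raise ConfigurationError(f"config missing required field: {scalar}")
            kwargs[scalar] = raw.pop(scalar)
        if raw:
            raise ConfigurationError(f"unknown top-level config keys: {sorted(raw)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {"n_subjects": self.n_subjects, "seed": self.seed}
        for section in self._SECTIONS:
            body = dataclasses.asdict(getattr(self, section))
            if "grid_shape" in body:
                body["grid_shape"] = list(body["grid_shape"])
            out[section] = body
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} does not hold a mapping")
    return PipelineConfig.from_dict(raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_provenance(path, config: PipelineConfig, stage: str, **extra) -> None:
    payload = {"stage": stage, "seed": config.seed,
               "config_hash": config.config_hash(), **extra}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# volumes and tables
# ---------------------------------------------------------------------------

def write_nifti(path, data: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float32), img.affine


def write_mask(path, mask: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def events_frame(design: pd.DataFrame, behavior: pd.DataFrame,
                 protocol: AcquisitionProtocol) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type first) for one subject."""
    merged = design.merge(
        behavior[["run_index", "trial_index", "response", "is_correct"]],
        on=["run_index", "trial_index"], how="left", validate="one_to_one")
    trial_type = merged["stimulus_class"].copy()
    sent = merged["stimulus_class"] == "sentence"
    abbrev = merged["syntax"].map({"subject_relative": "sr", "object_relative": "or"})
    trial_type[sent] = abbrev[sent] + "_" + merged.loc[sent, "phrase_position"]
    out = pd.DataFrame({
        "onset": merged["onset_s"],
        "duration": protocol.trial_duration_s,
        "trial_type": trial_type,
    })
    keep = ["run_index", "trial_index", "stimulus_class", "syntax",
            "phrase_position", "base_sentence_id", "correct_answer",
            "response", "is_correct"]
    return pd.concat([out, merged[keep]], axis=1)


def events_to_design_behavior(events: pd.DataFrame,
                              protocol: AcquisitionProtocol
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Invert :func:`events_frame` into design and behavior tables."""
    design = events[["run_index", "trial_index", "stimulus_class", "syntax",
                     "phrase_position", "base_sentence_id", "correct_answer"]].copy()
    design["onset_s"] = events["onset"]
    behavior = events[["run_index", "trial_index", "stimulus_class", "syntax",
                       "phrase_position", "correct_answer", "response",
                       "is_correct"]].copy()
    behavior["is_correct"] = behavior["is_correct"].map(
        {True: True, False: False, "True": True, "False": False}).astype("boolean")
    return design, behavior
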