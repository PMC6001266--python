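"""Acquisition timing for interleaved silent steady-state (ISSS) fMRI.

ISSS inserts a silent gap into each trial so auditory stimuli can be
presented without scanner noise, then collects a burst of volumes.  The
resulting time series is *discontinuous*: only the volumes collected during
acquisition windows exist, and trials are spaced so that one trial's burst
ends before the next trial begins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and geometry of one ISSS experiment.

    Defaults describe a 14-s trial: a 4-s silent gap (stimulus presented
    1 s after trial onset) followed by five volumes at TR = 2 s, with
    four runs of 36 trials on a 3-mm isotropic working grid.
    """

    tr_s: float = 2.0
    volumes_per_trial: int = 5
    silent_gap_s: float = 4.0
    n_runs: int = 4
    trials_per_run: int = 36
    voxel_size_mm: float = 3.0
    grid_shape: tuple[int, int, int] = (20, 24, 20)
    smoothing_fwhm_mm: float = 9.0
    stimulus_delay_s: float = 1.0

    def __post_init__(self) -> None:
        scalars = {
            "tr_s": self.tr_s,
            "volumes_per_trial": self.volumes_per_trial,
            "silent_gap_s": self.silent_gap_s,
            "n_runs": self.n_runs,
            "trials_per_run": self.trials_per_run,
            "voxel_size_mm": self.voxel_size_mm,
            "smoothing_fwhm_mm": self.smoothing_fwhm_mm,
        }
        for name, value in scalars.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {value!r}")
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3 positive integers, got {self.grid_shape!r}")
        if not 0 <= self.stimulus_delay_s < self.silent_gap_s:
            raise ConfigurationError("stimulus_delay_s must fall inside the silent gap")

    # ---- derived timing -------------------------------------------------

    @property
    def trial_duration_s(self) -> float:
        return self.silent_gap_s + self.volumes_per_trial * self.tr_s

    @property
    def run_duration_s(self) -> float:
        return self.trials_per_run * self.trial_duration_s

    @property
    def volumes_per_run(self) -> int:
        return self.trials_per_run * self.volumes_per_trial

    @property
    def n_volumes(self) -> int:
        return self.n_runs * self.volumes_per_run

    @property
    def volume_offsets_s(self) -> np.ndarray:
        """Acquisition start times of each volume relative to trial onset."""
        return self.silent_gap_s + self.tr_s * np.arange(self.volumes_per_trial)

    def run_volume_times(self) -> np.ndarray:
        """Timestamps of all volumes in one run, measured from run start."""
        onsets = self.trial_duration_s * np.arange(self.trials_per_run)
        return (onsets[:, None] + self.volume_offsets_s[None, :]).ravel()

    def series_run_labels(self) -> np.ndarray:
        """1-based run label of every volume in the concatenated series."""
        return np.repeat(np.arange(1, self.n_runs + 1), self.volumes_per_run)

    # ---- geometry -------------------------------------------------------

    def affine(self) -> np.ndarray:
        """Voxel-to-mm affine placing the grid center at the MNI-like origin."""
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        center = (np.asarray(self.grid_shape, float) - 1.0) / 2.0
        aff[:3, 3] = -self.voxel_size_mm * center
        return aff
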