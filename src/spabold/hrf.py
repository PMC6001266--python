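"""Canonical hemodynamic response shape used by the simulator.

The FIR estimator downstream is deliberately shape-free; the simulator
nevertheless needs a ground-truth response to plant, and a double-gamma
(positive gamma peak plus a delayed undershoot) is the field-standard
choice.  The shape is normalized so its peak equals 1, making planted
amplitudes interpretable as peak signal change.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.stats import gamma


@lru_cache(maxsize=8)
def _peak_value(peak_delay: float, peak_disp: float, undershoot_delay: float,
                undershoot_disp: float, undershoot_ratio: float) -> float:
    t = np.linspace(0.0, 50.0, 5001)
    h = (gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
         - undershoot_ratio * gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp))
    return float(h.max())


def double_gamma_hrf(t, peak_delay: float = 6.0, peak_disp: float = 1.0,
                     undershoot_delay: float = 16.0, undershoot_disp: float = 1.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Evaluate the peak-normalized double-gamma response at lags ``t`` (s).

    Zero for negative lags.  With the default parameters the positive lobe
    peaks near 5 s and the undershoot bottoms out around 15 s, decaying to
    ~0 by 30 s.
    """
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t >= 0
    h[pos] = (gamma.pdf(t[pos], peak_delay / peak_disp, scale=peak_disp)
              - undershoot_ratio * gamma.pdf(t[pos], undershoot_delay / undershoot_disp,
                                             scale=undershoot_disp))
    return h / _peak_value(peak_delay, peak_disp, undershoot_delay,
                           undershoot_disp, undershoot_ratio)
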