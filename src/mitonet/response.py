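"""Logistic (sigmoidal) dose-response used across the bioenergetic models."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SigmoidResponse"]


@dataclass(frozen=True)
class SigmoidResponse:
    """Strictly increasing logistic response r(x) = r_max / (1 + e^-((x-x_half)/slope)).

    Used with membrane potential (mV) on the x-axis for the ATP-synthesis
    rate, and with matrix calcium (uM) for TCA-cycle enzyme activation.
    ``slope`` sets the width of the rising region; the response is convex
    ("exponential regime") well below ``x_half`` and saturates ("plateau")
    well above it.
    """

    r_max: float = 1.0
    x_half: float = 150.0
    slope: float = 10.0

    def __post_init__(self):
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def __call__(self, x):
        z = (np.asarray(x, dtype=float) - self.x_half) / self.slope
        out = np.where(
            z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z))
        )
        out = self.r_max * out
        return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out
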