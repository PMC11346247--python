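"""Linear stimulus-to-drive rescaling s~ = alpha + beta * s.

Maps container fill fractions in [0, 1] onto the ~1e-2 ms^-1 drive scale of
the mean-field layer. beta >= 0 preserves stimulus order; drives are floored
at 0 (with the study's alpha = -0.018 a strictly positive drive for every
s in [0, 1] is impossible, so dim stimuli simply contribute no drive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class RescaleParams:
    alpha: float = -0.018
    beta: float = 0.05

    def __post_init__(self):
        if self.beta < 0:
            raise ConfigurationError("beta must be >= 0 (order preservation)")

    def apply(self, s):
        """Drive(s) = max(alpha + beta * s, 0)."""
        return np.maximum(self.alpha + self.beta * np.asarray(s, dtype=float), 0.0)
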