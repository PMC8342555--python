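"""Multiple-testing adjustment."""

from __future__ import annotations

import numpy as np


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Boolean significance mask at the Bonferroni-adjusted threshold.

    A test is significant when p < alpha / m with m the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p < alpha / p.size
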