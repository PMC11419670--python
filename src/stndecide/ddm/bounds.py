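"""Decision-bound profile: plateau followed by exponential collapse.

B(t) = a                                   for t <= b_t
B(t) = a * exp(-b_collapse * (t - b_t))    for t >  b_t

The bound is symmetric about zero (+B for the contralateral choice, -B
for the ipsilateral choice); a starting-point offset z plays the role of
asymmetric bound offsets of equal magnitude.
"""

from __future__ import annotations

import numpy as np

from stndecide.ddm.params import DDMParams

__all__ = ["bound_height"]


def bound_height(t, params: DDMParams):
    """Bound height B(t) at time ``t`` (s, scalar or array) since motion onset.

    Raises ``ValueError`` for negative times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("bound_height requires t >= 0")
    b = params.a * np.exp(-params.b_collapse * np.maximum(0.0, t - params.b_t))
    if b.ndim == 0:
        return float(b)
    return b
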