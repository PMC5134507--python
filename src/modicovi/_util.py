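"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np


def wrap_angle(a):
    """Wrap angles (scalar or array, radians) into the half-open interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped
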