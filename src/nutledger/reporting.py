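"""Reporting-layer rounding conventions.

Headline numbers follow the usual convention for national availability
estimates: energies to the nearest 5 kcal, energy shares to one decimal of a
percent.  Rounding happens only here — internal pipeline values stay at full
precision.
"""

from __future__ import annotations

import numpy as np


def round_kcal(value):
    """Round an energy value to the nearest 5 kcal (halves round up)."""
    arr = np.floor(np.asarray(value, dtype=float) / 5.0 + 0.5) * 5.0
    return float(arr) if arr.ndim == 0 else arr


def round_share(value):
    """Round a percentage share to one decimal (halves round up)."""
    arr = np.floor(np.asarray(value, dtype=float) * 10.0 + 0.5) / 10.0
    return float(arr) if arr.ndim == 0 else arr
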