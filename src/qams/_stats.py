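"""Small shared statistics helpers (public surface re-exported elsewhere)."""
from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .errors import InvalidInputError, UndefinedStatisticError


def rsd(values: Sequence[float] | np.ndarray) -> float:
    """Relative standard deviation in percent: 100 * sample SD / mean.

    The sample standard deviation uses n-1 degrees of freedom. The mean is
    taken with its sign; for the signed retention-time offsets used in peak
    location the caller divides by ``abs(mean)`` instead.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidInputError("RSD requires at least 2 values")
    mean = arr.mean()
    if mean == 0.0:
        raise UndefinedStatisticError("RSD undefined for zero-mean values")
    return float(100.0 * arr.std(ddof=1) / mean)


def rsd_abs(values: Sequence[float] | np.ndarray) -> float:
    """RSD relative to the magnitude of the mean (always >= 0)."""
    return abs(rsd(values))
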