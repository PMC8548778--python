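"""Linear scaling of ages and thickness values onto [-1, 1].

The trajectory networks are all-tanh, so both the input (age in years) and
the target (regional thickness in mm) must be mapped into the open working
range of the activation.  The map is the affine min-max transform: the
fitted minimum goes to -1, the fitted maximum to +1, and the inverse is
exact.  Values outside the fitted range extrapolate the same affine map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class DegenerateRangeError(ValueError):
    """All fitted values are identical; a [-1, 1] scaling is undefined."""


@dataclass(frozen=True)
class ScalingTransform:
    """Affine map sending ``lo`` to -1 and ``hi`` to +1."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lo) or not np.isfinite(self.hi):
            raise ValueError("scaler bounds must be finite")
        if self.hi <= self.lo:
            raise DegenerateRangeError(
                f"cannot scale a degenerate range [{self.lo}, {self.hi}]"
            )

    def apply(self, x):
        x = np.asarray(x, dtype=float)
        out = 2.0 * (x - self.lo) / (self.hi - self.lo) - 1.0
        return float(out) if out.ndim == 0 else out

    def invert(self, y):
        y = np.asarray(y, dtype=float)
        out = self.lo + (y + 1.0) * (self.hi - self.lo) / 2.0
        return float(out) if out.ndim == 0 else out

    def contains(self, x) -> np.ndarray:
        """Whether values lie inside the fitted range (False = extrapolation)."""
        x = np.asarray(x, dtype=float)
        return (x >= self.lo) & (x <= self.hi)

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingTransform":
        return cls(lo=float(d["lo"]), hi=float(d["hi"]))


def fit_scaler(values: Sequence[float]) -> ScalingTransform:
    """Fit a [-1, 1] min-max scaler to observed values.

    Raises
    ------
    DegenerateRangeError
        If fewer than two distinct values are present.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateRangeError("need at least two values to fit a scaler")
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        raise DegenerateRangeError("all values identical; range is degenerate")
    return ScalingTransform(lo=lo, hi=hi)
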