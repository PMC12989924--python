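"""Right-continuous nonincreasing step functions on [0, domain_max].

Survival-type estimators (Kaplan-Meier, copula-graphic, the naive pooled
survival fraction) are all step functions equal to 1 at t=0 with downward
jumps at observed times.  ``StepCurve`` is the shared value type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StepCurve"]


@dataclass(frozen=True)
class StepCurve:
    """A right-continuous, nonincreasing step function with S(0) = 1.

    Parameters
    ----------
    breakpoints : array of strictly increasing times > 0 where the curve jumps.
    values : curve value on ``[breakpoints[k], breakpoints[k+1])``; the value
        on ``[0, breakpoints[0])`` is 1.
    domain_max : largest observed time; the curve is only defined on
        ``[0, domain_max]``.
    """

    breakpoints: np.ndarray
    values: np.ndarray
    domain_max: float

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if bp.shape != vals.shape or bp.ndim != 1:
            raise ValueError("breakpoints and values must be equal-length 1-d")
        if bp.size and (np.any(bp <= 0) or np.any(np.diff(bp) <= 0)):
            raise ValueError("breakpoints must be strictly increasing and > 0")
        if np.any(vals < -1e-12) or np.any(vals > 1.0 + 1e-12):
            raise ValueError("step curve values must lie in [0, 1]")
        if np.any(np.diff(vals) > 1e-12) or (vals.size and vals[0] > 1.0 + 1e-12):
            raise ValueError("step curve must be nonincreasing from 1")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", np.clip(vals, 0.0, 1.0))
        object.__setattr__(self, "domain_max", float(self.domain_max))

    def __call__(self, t, clip: bool = False):
        """Evaluate the curve (right-continuously) at time(s) ``t``.

        Raises for t outside [0, domain_max] unless ``clip`` is set, in
        which case the curve is extrapolated as constant beyond domain_max.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("curve is only defined for t >= 0")
        if clip:
            t_arr = np.minimum(t_arr, self.domain_max)
        elif np.any(t_arr > self.domain_max + 1e-12):
            raise ValueError(
                f"curve is only defined on [0, {self.domain_max}]"
            )
        idx = np.searchsorted(self.breakpoints, t_arr, side="right")
        padded = np.concatenate(([1.0], self.values))
        out = padded[idx]
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def left_limit(self, t, clip: bool = False):
        """Evaluate the left limit S(t-); S(0-) is defined as 1."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("curve is only defined for t >= 0")
        if clip:
            t_arr = np.minimum(t_arr, self.domain_max)
        elif np.any(t_arr > self.domain_max + 1e-12):
            raise ValueError(f"curve is only defined on [0, {self.domain_max}]")
        idx = np.searchsorted(self.breakpoints, t_arr, side="left")
        padded = np.concatenate(([1.0], self.values))
        out = padded[idx]
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def sup_distance(self, other: "StepCurve", t_max: float | None = None) -> float:
        """Supremum distance to another step curve on [0, t_max]."""
        if t_max is None:
            t_max = min(self.domain_max, other.domain_max)
        grid = np.unique(
            np.concatenate(
                [[0.0], self.breakpoints, other.breakpoints, [t_max]]
            )
        )
        grid = grid[grid <= t_max + 1e-15]
        return float(np.max(np.abs(self(grid, clip=True) - other(grid, clip=True))))
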