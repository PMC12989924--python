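"""Tree evaluation: covariate-selection precision, Harrell's C on terminal-
node ranks, and the censoring-weighted (integrated) Brier score.

Harrell's C here compares the *terminal-node numbering* against observed
survival: node numbers increase with risk (node 1 = best prognosis), so a
pair is concordant when the longer-lived subject sits in a lower-numbered
node.  Pairs are comparable only when one subject certainly failed before
the other, i.e. the earlier observed time is an event.

The integrated Brier score follows the inverse-probability-of-censoring
weighting of Graf et al.: before a subject's observed time the squared
error (1 - S_hat)^2 is weighted by 1/C_hat(t); after an observed *event*
the squared error S_hat^2 is weighted by 1/C_hat(x_i); censored subjects
contribute nothing past their censoring time.  The time integral is the
exact rectangle sum over a grid containing every jump of the step-function
estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .copulas import ArchimedeanCopula, IndependenceCopula
from .estimators import SurvivalSample, censoring_curve
from .stepcurve import StepCurve

__all__ = [
    "ConcordanceCounts",
    "selection_precision",
    "harrells_c",
    "concordance_counts",
    "integrated_brier",
    "km_censoring_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceCounts:
    """Concordant / discordant / tied-rank pair counts over comparable pairs."""

    CC: int
    DC: int
    TR: int

    @property
    def harrells_c(self) -> Optional[float]:
        total = self.CC + self.DC + self.TR
        if total == 0:
            return None
        return (self.CC + 0.5 * self.TR) / total


def selection_precision(tree, informative: Sequence[int]) -> Optional[float]:
    """Fraction of internal nodes splitting on an informative covariate.

    Returns None for a depth-0 tree (no internal nodes), so that callers
    can exclude such trees from averages rather than diluting them.
    """
    features = getattr(tree, "split_features_", None)
    if features is None:
        raise ValueError("tree must be fitted")
    if not features:
        return None
    informative = set(informative)
    return sum(1 for f in features if f in informative) / len(features)


def concordance_counts(node_numbers, s: SurvivalSample) -> ConcordanceCounts:
    """Count pairs over ordered (i, j) with x_i > x_j and delta_j = 1.

    The strict time inequality plus the event requirement on the earlier
    subject make the pair's survival ordering certain despite censoring.
    """
    node_numbers = np.asarray(node_numbers)
    x, delta = s.x, s.delta
    if node_numbers.shape != x.shape:
        raise ValueError("node_numbers must match the sample size")
    later = x[:, None] > x[None, :]  # (i, j): i outlived j
    comparable = later & (delta[None, :] == 1)
    lower = node_numbers[:, None] < node_numbers[None, :]
    higher = node_numbers[:, None] > node_numbers[None, :]
    cc = int(np.count_nonzero(comparable & lower))
    dc = int(np.count_nonzero(comparable & higher))
    tr = int(np.count_nonzero(comparable & ~lower & ~higher))
    return ConcordanceCounts(cc, dc, tr)


def harrells_c(node_numbers, s: SurvivalSample) -> Optional[float]:
    """HC = (CC + 0.5 TR) / (CC + DC + TR); None when no pair is comparable."""
    return concordance_counts(node_numbers, s).harrells_c


def km_censoring_curve(s: SurvivalSample) -> StepCurve:
    """Kaplan-Meier estimate of the censoring distribution (default IPCW)."""
    return censoring_curve(s, IndependenceCopula())


def cge_censoring_curve(s: SurvivalSample, copula: ArchimedeanCopula) -> StepCurve:
    """CGE estimate of the censoring distribution under an assumed copula."""
    return censoring_curve(s, copula)


def integrated_brier(
    predictions: Sequence[StepCurve],
    test: SurvivalSample,
    weight_curve: StepCurve,
    grid: np.ndarray,
    left_limit_weights: bool = True,
) -> float:
    """Discretized integrated Brier score with censoring weights.

    IB_hat = (1/max x) * sum_j (t_{j+1} - t_j) * (1/n) * sum_i [
                 (1 - S_hat(t_j | z_i))^2 / C_hat(t_j) * 1{x_i > t_j}
               + S_hat(t_j | z_i)^2 / C_hat(x_i) * 1{x_i <= t_j} * delta_i ]

    ``grid`` should contain the jump times of the prediction and weight
    curves (the observed train/test times suffice); the rectangle sum is
    then exact.  The grid weight C_hat(t_j) is evaluated right-
    continuously (the almost-everywhere value of the integrand on
    [t_j, t_{j+1}), which keeps the sum grid-refinement invariant); the
    per-subject weight C_hat(x_i) is evaluated as the left limit
    C_hat(x_i-) by default (the usual IPCW convention; set
    ``left_limit_weights=False`` for the right-continuous reading).
    Terms whose weight is zero are dropped and counted in a debug log.
    """
    x, delta = test.x, test.delta
    n = x.size
    if len(predictions) != n:
        raise ValueError("one predicted curve per test subject is required")
    grid = np.unique(np.asarray(grid, dtype=float))
    grid = grid[grid >= 0]
    if grid.size < 2:
        raise ValueError("grid must contain at least two timepoints")
    t = grid[:-1]
    dt = np.diff(grid)

    S = np.vstack([curve(t, clip=True) for curve in predictions])  # (n, m)
    C_t = weight_curve(t, clip=True)  # (m,) a.e. value on [t_j, t_{j+1})
    eval_w = weight_curve.left_limit if left_limit_weights else weight_curve
    C_x = eval_w(x, clip=True)  # (n,)

    # segment [t_j, t_{j+1}) lies inside [0, x_i) iff x_i > t_j when the
    # grid contains x_i; this makes the rectangle sum equal the continuous
    # integral exactly (a perfect predictor scores exactly 0)
    before = x[:, None] > t[None, :]
    after_event = (~before) & (delta[:, None] == 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        term_before = np.where(before, (1.0 - S) ** 2 / C_t[None, :], 0.0)
        term_after = np.where(after_event, S ** 2 / C_x[:, None], 0.0)
    dropped = int(np.count_nonzero(~np.isfinite(term_before))) + int(
        np.count_nonzero(~np.isfinite(term_after))
    )
    if dropped:
        logger.debug("integrated_brier: dropped %d zero-weight terms", dropped)
    term_before = np.where(np.isfinite(term_before), term_before, 0.0)
    term_after = np.where(np.isfinite(term_after), term_after, 0.0)

    inner = (term_before + term_after).mean(axis=0)  # (m,)
    return float(np.sum(dt * inner) / x.max())
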