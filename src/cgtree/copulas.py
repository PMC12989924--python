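"""Archimedean copulas for modelling dependence between event and censoring times.

An Archimedean copula is built from a generator function phi via
``C(u, v) = phi_inv(phi(u) + phi(v))`` where ``phi: (0, 1] -> [0, inf)`` is
continuous, convex and strictly decreasing with ``phi(1) = 0``.  The joint
*survival* function of event time T and censoring time C is modelled as
``P(T > t, C > s) = C(S_T(t), S_C(s))``, so the copula fully specifies how
censoring is informative about survival.

Three families are provided:

* Clayton: ``phi(u) = (u**-theta - 1) / theta`` with Kendall's
  ``tau = theta / (theta + 2)`` (lower-tail dependence),
* Frank:   ``phi(u) = -log((exp(-theta*u) - 1) / (exp(-theta) - 1))``
  (no tail dependence),
* independence: ``phi(u) = -log(u)``, the ``theta -> 0`` limit of both.

Dependent uniform pairs are sampled with the conditional-distribution
method, which has a closed-form conditional inverse for both families.
"""

from __future__ import annotations

import warnings
from typing import Union

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "ArchimedeanCopula",
    "ClaytonCopula",
    "FrankCopula",
    "IndependenceCopula",
    "archimedean_copula",
    "kendall_tau_from_generator",
]

_FAMILIES = ("clayton", "frank", "independence")


class ArchimedeanCopula:
    """Base class: generator, pseudo-inverse, Kendall's tau and sampling.

    Subclasses implement the vectorized generator pair (``_phi`` /
    ``_phi_inv``) and the conditional inverse used for sampling.
    """

    family: str = ""
    theta: float = 0.0
    tau: float = 0.0

    # -- generator pair ---------------------------------------------------

    def generator(self, u):
        """Evaluate phi(u) for u in (0, 1].  Raises outside the domain."""
        u_arr = np.asarray(u, dtype=float)
        if np.any(u_arr <= 0.0) or np.any(u_arr > 1.0):
            raise ValueError("generator argument must lie in (0, 1]")
        out = self._phi(u_arr)
        return float(out) if np.isscalar(u) or u_arr.ndim == 0 else out

    def inverse_generator(self, w):
        """Pseudo-inverse: phi_inv(phi(u)) = u, and 0 for w >= phi(0+)."""
        w_arr = np.asarray(w, dtype=float)
        if np.any(w_arr < 0.0):
            raise ValueError("inverse generator argument must be >= 0")
        out = self._phi_inv(w_arr)
        return float(out) if np.isscalar(w) or w_arr.ndim == 0 else out

    def _phi(self, u: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _phi_inv(self, w: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    # -- copula function ---------------------------------------------------

    def cdf(self, u, v):
        """C(u, v) = phi_inv(phi(u) + phi(v)), with boundary conventions."""
        u_arr = np.asarray(u, dtype=float)
        v_arr = np.asarray(v, dtype=float)
        u_c = np.clip(u_arr, 0.0, 1.0)
        v_c = np.clip(v_arr, 0.0, 1.0)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            w = self._phi(u_c) + self._phi(v_c)
            out = self._phi_inv(w)
        out = np.where((u_c == 0.0) | (v_c == 0.0), 0.0, out)
        if np.isscalar(u) and np.isscalar(v):
            return float(out)
        return out

    # -- sampling ----------------------------------------------------------

    def sample(self, n: int, seed: Union[int, np.random.Generator, None] = None):
        """Draw ``n`` dependent pairs (U, V) with uniform marginals.

        Uses the conditional-distribution method: U ~ Unif(0,1), then V is
        the conditional inverse of dC/du at an independent uniform draw.
        Deterministic for a given seed.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=n)
        w = rng.uniform(size=n)
        v = self._conditional_inverse(u, w)
        return u, v

    def _conditional_inverse(self, u: np.ndarray, w: np.ndarray) -> np.ndarray:
        raise NotImplementedError  # pragma: no cover

    def __repr__(self) -> str:
        return (
            f"{type(self).__name__}(theta={self.theta:.6g}, tau={self.tau:.6g})"
        )


class IndependenceCopula(ArchimedeanCopula):
    """phi(u) = -log(u); C(u, v) = u*v.  Kendall's tau = 0."""

    family = "independence"
    theta = 0.0
    tau = 0.0

    def _phi(self, u):
        with np.errstate(divide="ignore"):
            return -np.log(u)

    def _phi_inv(self, w):
        return np.exp(-w)

    def _conditional_inverse(self, u, w):
        return w


class ClaytonCopula(ArchimedeanCopula):
    """Clayton copula, generated by phi(u) = (u**-theta - 1)/theta.

    ``theta > 0`` gives positive dependence with lower-tail clustering and
    Kendall's tau = theta/(theta+2); theta in [-1, 0) gives negative
    dependence (supported with a warning, outside the usual use case).
    """

    family = "clayton"

    def __init__(self, theta: float):
        if theta == 0.0:
            raise ValueError(
                "theta=0 is the independence limit; use IndependenceCopula"
            )
        if theta < -1.0:
            raise ValueError("Clayton theta must be in [-1, inf) \\ {0}")
        if theta < 0.0:
            warnings.warn(
                "negative Clayton dependence requested; all standard "
                "settings use tau >= 0",
                stacklevel=2,
            )
        self.theta = float(theta)
        self.tau = self.theta / (self.theta + 2.0)

    @classmethod
    def from_tau(cls, tau: float) -> "ClaytonCopula":
        if not -1.0 < tau < 1.0 or tau == 0.0:
            raise ValueError("Clayton tau must be in (-1, 1) \\ {0}")
        return cls(2.0 * tau / (1.0 - tau))

    def _phi(self, u):
        th = self.theta
        with np.errstate(divide="ignore"):
            return (u ** -th - 1.0) / th

    def _phi_inv(self, w):
        th = self.theta
        base = 1.0 + th * w
        if th > 0:
            with np.errstate(over="ignore"):
                out = base ** (-1.0 / th)
            return np.where(np.isinf(w), 0.0, out)
        # theta < 0: phi(0) = -1/theta is finite; truncate beyond it
        return np.where(base > 0.0, np.maximum(base, 0.0) ** (-1.0 / th), 0.0)

    def _conditional_inverse(self, u, w):
        th = self.theta
        base = (w ** (-th / (1.0 + th)) - 1.0) * u ** -th + 1.0
        return np.maximum(base, 1e-300) ** (-1.0 / th)


class FrankCopula(ArchimedeanCopula):
    """Frank copula, generated by
    phi(u) = -log((exp(-theta*u) - 1)/(exp(-theta) - 1)).

    Radially symmetric, no tail dependence.  theta is solved from Kendall's
    tau by root-finding on the generator integral (no series expansion).
    """

    family = "frank"

    def __init__(self, theta: float):
        if theta == 0.0:
            raise ValueError(
                "theta=0 is the independence limit; use IndependenceCopula"
            )
        self.theta = float(theta)
        self.tau = kendall_tau_from_generator(self)

    @classmethod
    def from_tau(cls, tau: float) -> "FrankCopula":
        if not -1.0 < tau < 1.0 or tau == 0.0:
            raise ValueError("Frank tau must be in (-1, 1) \\ {0}")

        def objective(theta: float) -> float:
            return kendall_tau_from_generator(cls(theta)) - tau

        # tau(theta) is increasing and odd in theta; bracket then refine
        lo, hi = (1e-6, 1.0) if tau > 0 else (-1.0, -1e-6)
        if tau > 0:
            while objective(hi) < 0.0:
                hi *= 2.0
                if hi > 1e6:  # pragma: no cover
                    raise RuntimeError("Frank theta bracketing failed")
            theta = optimize.brentq(objective, lo, hi, xtol=1e-10, rtol=1e-12)
        else:
            while objective(lo) > 0.0:
                lo *= 2.0
                if lo < -1e6:  # pragma: no cover
                    raise RuntimeError("Frank theta bracketing failed")
            theta = optimize.brentq(objective, lo, hi, xtol=1e-10, rtol=1e-12)
        return cls(theta)

    def _phi(self, u):
        th = self.theta
        with np.errstate(divide="ignore"):
            return -np.log(np.expm1(-th * u) / np.expm1(-th))

    def _phi_inv(self, w):
        th = self.theta
        # u = -log(1 + exp(-w) * (exp(-theta) - 1)) / theta
        with np.errstate(divide="ignore", invalid="ignore"):
            out = -np.log1p(np.exp(-w) * np.expm1(-th)) / th
        return np.where(np.isinf(w), 0.0, out)

    def _conditional_inverse(self, u, w):
        th = self.theta
        a = np.exp(-th * u)
        d = np.expm1(-th)
        b = w * d / (a - w * (a - 1.0))
        return -np.log1p(b) / th


def kendall_tau_from_generator(copula: ArchimedeanCopula) -> float:
    """Kendall's tau as ``1 + 4 * int_0^1 phi(t)/phi'(t) dt`` (numeric).

    phi' is taken by central differences inside quad-friendly closed forms:
    each family exposes phi analytically, so phi/phi' is computed from the
    analytic derivative per family to keep the quadrature well conditioned.
    """
    th = copula.theta
    fam = copula.family
    if fam == "independence":
        return 0.0
    if fam == "clayton":
        def ratio(t):
            # phi/phi' = -(t - t**(theta+1))/theta
            return -(t - t ** (th + 1.0)) / th
    elif fam == "frank":
        def ratio(t):
            # phi'(t) = theta*exp(-theta t)/expm1(-theta t)
            num = -np.log(np.expm1(-th * t) / np.expm1(-th))
            den = th * np.exp(-th * t) / np.expm1(-th * t)
            return num / den
    else:  # pragma: no cover
        raise ValueError(f"unknown family {fam!r}")
    val, _ = integrate.quad(ratio, 0.0, 1.0, limit=200, epsabs=1e-12)
    return 1.0 + 4.0 * val


def archimedean_copula(family: str, tau: float) -> ArchimedeanCopula:
    """Build a copula of the given family with Kendall's tau.

    ``tau`` must lie in (-1, 1).  ``tau == 0`` returns the independence
    copula for any family (the theta -> 0 limit of Clayton and Frank).
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}, got {family!r}")
    if not -1.0 < tau < 1.0:
        raise ValueError(f"tau must be in (-1, 1), got {tau}")
    if tau == 0.0 or family == "independence":
        if family == "independence" and tau != 0.0:
            raise ValueError("independence copula requires tau=0")
        return IndependenceCopula()
    if family == "clayton":
        return ClaytonCopula.from_tau(tau)
    return FrankCopula.from_tau(tau)
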