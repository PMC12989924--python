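"""Synthetic right-censored survival data with dependent censoring.

All generators follow the same recipe: draw a dependent uniform pair
(U, V) from a chosen Archimedean copula, invert the cumulative hazard of
the event-time model at U, and turn V into an exponential censoring time
whose rate ``lambda_C = r/(1-r)`` is calibrated so that, under the null
(no covariate effect) with unit-exponential event times, exactly 100r% of
observations are censored in expectation.  Because Kendall's tau is
invariant under the monotone maps u -> -log(u), the (T, C) pair inherits
the copula's tau exactly.

Generators:

* :func:`simulate_ph` - proportional hazards, T = -log(U) * exp(-beta*z),
  with a binary group covariate or one of three alternative covariate
  mechanisms (normal mean shift, normal scale change, Poisson rate shift).
* :func:`simulate_nph` - Gompertz hazard h(t) = exp(gamma*t + b1*z + b2*z*t),
  giving time-dependent (non-proportional) group effects.
* :func:`simulate_pathway` - block-correlated "gene pathway" covariates:
  p covariates in blocks of q, within-block correlation rho, the first 2q
  informative with effects (+beta, -beta), half of each block median-
  binarized, everything rounded to one decimal.
* :func:`simulate_unequal_censoring` - sensitivity arms that break the
  equal-censoring-distributions assumption.

Datasets are pandas DataFrames with columns ``time``, ``event``, covariate
columns, and (for two-group designs) ``group``; the generating
configuration and the latent (T, C) are kept in ``DataFrame.attrs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .copulas import ArchimedeanCopula, IndependenceCopula

__all__ = [
    "PHConfig",
    "NPHConfig",
    "PathwayConfig",
    "censoring_rate",
    "simulate_ph",
    "simulate_nph",
    "simulate_pathway",
    "simulate_unequal_censoring",
]

SQRT3 = np.sqrt(3.0)


def censoring_rate(r: float) -> float:
    """Exponential censoring rate lambda_C with P(C < T) = r at the null.

    With T ~ Exp(1) independent of C ~ Exp(lambda_C),
    P(C < T) = lambda_C / (1 + lambda_C) = r  =>  lambda_C = r/(1-r).
    """
    if not 0.0 <= r < 1.0:
        raise ValueError("censoring parameter r must lie in [0, 1)")
    return r / (1.0 - r)


@dataclass(frozen=True)
class PHConfig:
    """Proportional-hazards design: unit-exponential baseline, effect beta."""

    n1: int
    n2: int
    beta: float = 0.0
    r: float = 0.5
    copula: ArchimedeanCopula = field(default_factory=IndependenceCopula)
    covariate_setting: str = "binary"  # binary|normal_mean|normal_scale|poisson
    gamma: float = 0.0  # parameter of the alternative covariate mechanisms
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be >= 1")
        censoring_rate(self.r)  # validates r


@dataclass(frozen=True)
class NPHConfig:
    """Gompertz non-proportional-hazards design."""

    n1: int
    n2: int
    beta1: float = 0.0
    beta2: float = 0.0
    gamma: float = 1.0
    r: float = 0.5
    copula: ArchimedeanCopula = field(default_factory=IndependenceCopula)
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be >= 1")
        censoring_rate(self.r)
        if self.gamma + self.beta2 <= 0 or self.gamma <= 0:
            # needed for the cumulative-hazard inversion on z in {0, 1}
            raise ValueError("gamma and gamma + beta2 must be positive")


@dataclass(frozen=True)
class PathwayConfig:
    """Block "pathway" covariates: p columns, two informative blocks of q."""

    n: int
    p: int = 50
    q: int = 5
    rho: float = 0.5
    beta: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self):
        if self.p <= 2 * self.q:
            raise ValueError("pathway design requires p > 2q")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _draw_uv(copula, n, rng):
    return copula.sample(n, rng)


def _censoring_times(v: np.ndarray, r: float) -> np.ndarray:
    lam = censoring_rate(r)
    if lam == 0.0:
        return np.full(v.shape, np.inf)
    return -np.log(v) / lam


def _covariates(cfg: PHConfig, rng: np.random.Generator) -> np.ndarray:
    n1, n2, g = cfg.n1, cfg.n2, cfg.gamma
    if cfg.covariate_setting == "binary":
        return np.concatenate([np.zeros(n1), np.ones(n2)])
    if cfg.covariate_setting == "normal_mean":
        return np.concatenate(
            [rng.normal(0.0, 1.0, n1), rng.normal(g, 1.0, n2)]
        )
    if cfg.covariate_setting == "normal_scale":
        if g <= 0:
            raise ValueError("normal_scale setting requires gamma > 0")
        return np.concatenate(
            [rng.normal(0.0, 1.0, n1), rng.normal(0.0, g, n2)]
        )
    if cfg.covariate_setting == "poisson":
        if 1.0 + g <= 0:
            raise ValueError("poisson setting requires 1 + gamma > 0")
        return np.concatenate(
            [rng.poisson(1.0, n1), rng.poisson(1.0 + g, n2)]
        ).astype(float)
    raise ValueError(f"unknown covariate setting {cfg.covariate_setting!r}")


def _assemble(x, delta, z, group, t, c, config) -> pd.DataFrame:
    df = pd.DataFrame({"time": x, "event": delta.astype(int)})
    if z.ndim == 1:
        df["z1"] = z
    else:
        for j in range(z.shape[1]):
            df[f"z{j + 1}"] = z[:, j]
    if group is not None:
        df["group"] = group
    df.attrs["latent"] = {"T": t, "C": c}
    df.attrs["config"] = config
    return df


def simulate_ph(cfg: PHConfig) -> pd.DataFrame:
    """Proportional-hazards data with copula-dependent censoring.

    T = -log(U) * exp(-beta * z); C = -log(V) / lambda_C with
    lambda_C = r/(1-r); x = min(T, C), delta = 1(T <= C).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n1 + cfg.n2
    z = _covariates(cfg, rng)
    u, v = _draw_uv(cfg.copula, n, rng)
    t = -np.log(u) * np.exp(-cfg.beta * z)
    c = _censoring_times(v, cfg.r)
    x = np.minimum(t, c)
    delta = (t <= c).astype(int)
    group = np.concatenate(
        [np.ones(cfg.n1, dtype=int), np.full(cfg.n2, 2, dtype=int)]
    )
    return _assemble(x, delta, z, group, t, c, cfg)


def simulate_nph(cfg: NPHConfig) -> pd.DataFrame:
    """Gompertz non-proportional-hazards data.

    Inverting the cumulative hazard of h(t) = exp(gamma*t + b1*z + b2*z*t)
    gives T = log(1 - (gamma + b2*z) * exp(-b1*z) * log(U)) / (gamma + b2*z);
    the argument of the log is >= 1 since log(U) < 0, so the inversion is
    always defined.  Censoring is generated exactly as in the PH design.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n1 + cfg.n2
    z = np.concatenate([np.zeros(cfg.n1), np.ones(cfg.n2)])
    u, v = _draw_uv(cfg.copula, n, rng)
    a = cfg.gamma + cfg.beta2 * z
    small = np.abs(a) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.log1p(-a * np.exp(-cfg.beta1 * z) * np.log(u)) / a
    t = np.where(small, -np.exp(-cfg.beta1 * z) * np.log(u), t)
    c = _censoring_times(v, cfg.r)
    x = np.minimum(t, c)
    delta = (t <= c).astype(int)
    group = np.concatenate(
        [np.ones(cfg.n1, dtype=int), np.full(cfg.n2, 2, dtype=int)]
    )
    return _assemble(x, delta, z, group, t, c, cfg)


def _pathway_covariates(cfg: PathwayConfig, rng: np.random.Generator):
    """Uniform(-sqrt3, sqrt3) covariates with within-block correlation rho.

    A Gaussian copula with normal correlation 2*sin(pi*rho/6) produces
    uniform margins whose Pearson correlation equals rho; correlation is
    confined to the two leading blocks of q columns.
    """
    n, p, q, rho = cfg.n, cfg.p, cfg.q, cfg.rho
    rho_n = 2.0 * np.sin(np.pi * rho / 6.0)
    normal = rng.standard_normal((n, p))
    for block in range(2):
        cols = slice(block * q, (block + 1) * q)
        cov = np.full((q, q), rho_n) + (1.0 - rho_n) * np.eye(q)
        chol = np.linalg.cholesky(cov)
        normal[:, cols] = normal[:, cols] @ chol.T
    # map to uniform with mean 0, sd 1: Unif(-sqrt3, sqrt3)
    from scipy.stats import norm

    unif = norm.cdf(normal)
    return (2.0 * unif - 1.0) * SQRT3


def simulate_pathway(
    cfg: PathwayConfig,
    r: float = 0.5,
    copula: Optional[ArchimedeanCopula] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Block "pathway" covariate data with dependent censoring.

    The first ceil(q/2) columns of each of the two informative blocks are
    binarized at the column median (clinical-style categorical markers);
    all columns are then rounded to one decimal, which keeps the set of
    candidate tree cutoffs small.  Effects are +beta on block 1, -beta on
    block 2, 0 elsewhere; columns 0..2q-1 are the informative set.
    """
    if copula is None:
        copula = IndependenceCopula()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    z = _pathway_covariates(cfg, rng)
    q = cfg.q
    n_bin = int(np.ceil(q / 2))
    for block in range(2):
        for j in range(block * q, block * q + n_bin):
            z[:, j] = (z[:, j] >= np.median(z[:, j])).astype(float)
    z = np.round(z, 1)
    beta_vec = np.concatenate(
        [
            np.full(q, cfg.beta),
            np.full(q, -cfg.beta),
            np.zeros(cfg.p - 2 * q),
        ]
    )
    u, v = _draw_uv(copula, cfg.n, rng)
    t = -np.log(u) * np.exp(-z @ beta_vec)
    c = _censoring_times(v, r)
    x = np.minimum(t, c)
    delta = (t <= c).astype(int)
    df = _assemble(x, delta, z, None, t, c, cfg)
    df.attrs["informative"] = list(range(2 * q))
    return df


def simulate_unequal_censoring(
    variant: str,
    cfg: PHConfig,
    r1: float = 0.5,
    r2: float = 0.25,
) -> pd.DataFrame:
    """Sensitivity arms violating the equal-censoring assumption.

    ``variant="group_r"``: censoring rates calibrated per group to r1 / r2.
    ``variant="censoring_equals_survival"``: censoring times are generated
    by the same covariate-dependent mechanism as the event times,
    C = -log(V) * exp(-beta * z).
    """
    if variant not in ("group_r", "censoring_equals_survival"):
        raise ValueError(
            "variant must be 'group_r' or 'censoring_equals_survival'"
        )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n1 + cfg.n2
    z = _covariates(cfg, rng)
    u, v = _draw_uv(cfg.copula, n, rng)
    t = -np.log(u) * np.exp(-cfg.beta * z)
    if variant == "group_r":
        rates = np.concatenate(
            [
                np.full(cfg.n1, censoring_rate(r1)),
                np.full(cfg.n2, censoring_rate(r2)),
            ]
        )
        with np.errstate(divide="ignore"):
            c = np.where(rates > 0.0, -np.log(v) / rates, np.inf)
    else:
        c = -np.log(v) * np.exp(-cfg.beta * z)
    x = np.minimum(t, c)
    delta = (t <= c).astype(int)
    group = np.concatenate(
        [np.ones(cfg.n1, dtype=int), np.full(cfg.n2, 2, dtype=int)]
    )
    df = _assemble(x, delta, z, group, t, c, cfg)
    df.attrs["unequal_censoring"] = {
        "variant": variant,
        "r1": r1,
        "r2": r2,
    }
    return df
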