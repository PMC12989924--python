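"""Simulation harness reproducing the two simulation studies at any scale.

The *power study* runs the CGE permutation tests (an assumed-tau grid) and
the logrank / Peto-Peto comparators on proportional-hazards data with
copula-dependent censoring, per scenario cell, and tabulates rejection
rates with their Monte-Carlo standard errors.  The *tree study* grows CGE
trees (and the logrank comparator tree) on block "pathway" covariate data
and scores selection precision, Harrell's C and the integrated Brier score
on an independent test set per round.

Per-cell seeds are derived from the study seed and the cell index through
``numpy`` seed sequences, so every cell - and every simulation round
inside it - is reproducible in isolation and independent of evaluation
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .copulas import archimedean_copula
from .estimators import SurvivalSample
from .metrics import (
    cge_censoring_curve,
    harrells_c,
    integrated_brier,
    km_censoring_curve,
    selection_precision,
)
from .simulate import PathwayConfig, PHConfig, simulate_ph, simulate_pathway
from .tree import CGESurvivalTree
from .twosample import TwoSampleData, permutation_test_multi, weighted_logrank

__all__ = [
    "ScenarioCell",
    "monte_carlo_se",
    "monte_carlo_se_bound",
    "run_power_study",
    "run_tree_study",
    "DESK_POWER_GRID",
    "PAPER_TYPE1_GRID",
]

DEFAULT_TAU_GRID = (0.0, 0.25, 0.5, 0.75)


def monte_carlo_se(power_hat: float, nsim: int) -> float:
    """Binomial Monte-Carlo standard error sqrt(p(1-p)/nsim)."""
    return float(np.sqrt(power_hat * (1.0 - power_hat) / nsim))


def monte_carlo_se_bound(nsim: int) -> float:
    """Worst-case Monte-Carlo SE, 0.5/sqrt(nsim) (at power 1/2)."""
    return float(0.5 / np.sqrt(nsim))


@dataclass(frozen=True)
class ScenarioCell:
    """One cell of the test simulation grid."""

    n1: int
    n2: int
    beta: float = 0.0
    r: float = 0.5
    copula_family: str = "clayton"
    tau_theor: float = 0.0
    covariate_setting: str = "binary"
    gamma: float = 0.0

    def label(self) -> str:
        return (
            f"n=({self.n1},{self.n2}) beta={self.beta} r={self.r} "
            f"{self.copula_family} tau={self.tau_theor}"
        )


def _cell_rng_seeds(seed: int, cell_index: int, nsim: int):
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(cell_index,))
    return ss.spawn(nsim)


def run_power_study(
    cells: Sequence[ScenarioCell],
    nsim: int = 1000,
    nperm: int = 1000,
    alpha: float = 0.05,
    tau_assumed: Sequence[float] = DEFAULT_TAU_GRID,
    include_comparators: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Rejection rates of all tests per scenario cell.

    Returns a tidy frame with one row per (cell, test): the rejection rate
    (type-I error when beta encodes the null, power otherwise), its
    Monte-Carlo SE, and the mean per-group censored fractions.
    """
    assumed_copulas = [archimedean_copula("clayton", t) for t in tau_assumed]
    rows = []
    for ci, cell in enumerate(cells):
        theor = archimedean_copula(cell.copula_family, cell.tau_theor)
        test_names = [f"cge_tau_{t:g}" for t in tau_assumed]
        if include_comparators:
            test_names += ["logrank", "peto_peto"]
        rejections = {name: 0 for name in test_names}
        cens1 = np.empty(nsim)
        cens2 = np.empty(nsim)
        for i, sub in enumerate(_cell_rng_seeds(seed, ci, nsim)):
            rng = np.random.default_rng(sub)
            cfg = PHConfig(
                n1=cell.n1,
                n2=cell.n2,
                beta=cell.beta,
                r=cell.r,
                copula=theor,
                covariate_setting=cell.covariate_setting,
                gamma=cell.gamma,
                seed=rng.integers(2**31),
            )
            df = simulate_ph(cfg)
            g1 = df[df["group"] == 1]
            g2 = df[df["group"] == 2]
            cens1[i] = 1.0 - g1["event"].mean()
            cens2[i] = 1.0 - g2["event"].mean()
            data = TwoSampleData(
                SurvivalSample(g1["time"].to_numpy(), g1["event"].to_numpy()),
                SurvivalSample(g2["time"].to_numpy(), g2["event"].to_numpy()),
            )
            results = permutation_test_multi(
                data, assumed_copulas, nperm, rng, alpha
            )
            for name, res in zip(test_names, results):
                rejections[name] += res.p_value <= alpha
            if include_comparators:
                for wname, key in (("logrank", "logrank"), ("peto_peto", "peto_peto")):
                    try:
                        _, p = weighted_logrank(data, key)
                    except ValueError:
                        p = 1.0
                    rejections[wname] += p <= alpha
        for name in test_names:
            rate = rejections[name] / nsim
            rows.append(
                {
                    "scenario": cell.label(),
                    "n1": cell.n1,
                    "n2": cell.n2,
                    "beta": cell.beta,
                    "r": cell.r,
                    "copula_family": cell.copula_family,
                    "tau_theor": cell.tau_theor,
                    "test": name,
                    "rejection_rate": rate,
                    "monte_carlo_se": monte_carlo_se(rate, nsim),
                    "nsim": nsim,
                    "nperm": nperm,
                    "mean_censoring_group1": float(cens1.mean()),
                    "mean_censoring_group2": float(cens2.mean()),
                }
            )
    return pd.DataFrame(rows)


def run_tree_study(
    cfg: PathwayConfig,
    r: float = 0.5,
    tau_theor: float = 0.25,
    nsim: int = 100,
    nperm: int = 1000,
    p_threshold: float = 0.01,
    min_child: int = 2,
    tau_assumed: Sequence[float] = DEFAULT_TAU_GRID,
    include_logrank: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-round tree metrics on matched train/test pathway datasets.

    Each round simulates an independent training and testing dataset of
    ``cfg.n`` subjects, grows one tree per assumed tau (plus the logrank
    comparator tree), and evaluates on the test data: number of terminal
    nodes, selection precision, Harrell's C on terminal-node ranks, and
    the IBS with Kaplan-Meier and with CGE (tau = tau_theor) censoring
    weights.
    """
    theor = archimedean_copula("clayton", tau_theor)
    rows = []
    tree_specs = [("cge", t) for t in tau_assumed]
    if include_logrank:
        tree_specs.append(("logrank", 0.0))
    for i, sub in enumerate(
        np.random.SeedSequence(entropy=seed, spawn_key=(0,)).spawn(nsim)
    ):
        rng = np.random.default_rng(sub)
        train = simulate_pathway(cfg, r, theor, seed=rng.integers(2**31))
        test = simulate_pathway(cfg, r, theor, seed=rng.integers(2**31))
        zcols = [c for c in train.columns if c.startswith("z")]
        Xtr = train[zcols].to_numpy()
        Xte = test[zcols].to_numpy()
        ytr = (train["time"].to_numpy(), train["event"].to_numpy())
        test_sample = SurvivalSample(
            test["time"].to_numpy(), test["event"].to_numpy()
        )
        grid = np.unique(
            np.concatenate([train["time"].to_numpy(), test["time"].to_numpy()])
        )
        km_weights = km_censoring_curve(test_sample)
        cge_weights = cge_censoring_curve(test_sample, theor)
        tree_seed = int(rng.integers(2**31))
        for kind, tau in tree_specs:
            tree = CGESurvivalTree(
                family="clayton",
                tau=tau,
                p_threshold=p_threshold,
                nperm=nperm,
                min_child=min_child,
                split_test="cge_l1" if kind == "cge" else "logrank",
                random_state=tree_seed,
            ).fit(Xtr, ytr)
            node_numbers = tree.predict(Xte)
            curves = tree.predict_survival_function(Xte)
            rows.append(
                {
                    "round": i,
                    "tree": f"{kind}_tau_{tau:g}" if kind == "cge" else "logrank",
                    "n_terminal_nodes": tree.n_terminal_nodes_,
                    "precision": selection_precision(
                        tree, train.attrs["informative"]
                    ),
                    "harrells_c": harrells_c(node_numbers, test_sample),
                    "ibs_km": integrated_brier(
                        curves, test_sample, km_weights, grid
                    ),
                    "ibs_cge": integrated_brier(
                        curves, test_sample, cge_weights, grid
                    ),
                    "censoring_train": 1.0 - train["event"].mean(),
                    "censoring_test": 1.0 - test["event"].mean(),
                }
            )
    return pd.DataFrame(rows)


# Preset grids -----------------------------------------------------------

#: Reduced "desk" power grid: the printed headline settings only.
DESK_POWER_GRID = tuple(
    ScenarioCell(n1=n1, n2=n2, beta=beta, r=0.5, tau_theor=tau)
    for (n1, n2) in ((150, 150), (20, 50))
    for beta in (-0.4, 0.0, 0.4)
    for tau in (0.0001, 0.5)
)

#: Null-hypothesis grid at moderate sample size for type-I-error checks.
PAPER_TYPE1_GRID = tuple(
    ScenarioCell(n1=50, n2=50, beta=0.0, r=r, copula_family=fam, tau_theor=tau)
    for fam in ("clayton", "frank")
    for r in (0.1, 0.25, 0.5)
    for tau in (0.0001, 0.25, 0.5, 0.75)
)
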