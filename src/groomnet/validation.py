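"""Self-contained validation studies: property checks, null calibrations and
planted-effect recovery.

These routines exercise the whole pipeline on randomly generated inputs with
known structure -- random weighted networks for the metric invariants,
binomial/random-tournament nulls for the randomization tests, and fully
synthetic multi-group datasets with planted effects for the mixed-model
stage.  They are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .dominance import (WinMatrix, hierarchy_steepness, landau_linearity,
                        normalized_davids_scores)
from .mixed_models import (MAIN_TERMS, aic_backward_reduction, fit_lmm,
                           prepare_design)
from .network_build import GroomingNetwork, build_networks
from .network_metrics import (compute_metrics_table, disparity,
                              eigenvector_centrality, symmetrize)
from .synthetic_data import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


def random_network(rng: np.random.Generator, n_min: int = 3,
                   n_max: int = 15) -> GroomingNetwork:
    """A random directed weighted network with a connected symmetrization."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        W = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
        np.fill_diagonal(W, 0.0)
        if (W + W.T).sum(axis=1).min() > 0:  # no isolated nodes
            return GroomingNetwork(group_id="R", nodes=[f"n{i}" for i in
                                                        range(n)], W=W)


def disparity_bounds_violations(n_networks: int = 200, seed: int = 0) -> int:
    """Count violations of 1/k <= Y <= 1 (and of dY >= 0) on random nets."""
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_networks):
        net = random_network(rng)
        Y = disparity(net)
        k = (net.W > 0).sum(axis=1)
        for yi, ki in zip(Y, k):
            if ki == 0:
                if np.isfinite(yi):
                    violations += 1
                continue
            if not (1.0 / ki - 1e-12 <= yi <= 1.0 + 1e-12):
                violations += 1
    return violations


def eigenvector_power_vs_dense(n_networks: int = 200, seed: int = 0) -> float:
    """Max |power iteration - dense eigendecomposition| after max-scaling."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_networks):
        net = random_network(rng)
        M = symmetrize(net)
        e_power = eigenvector_centrality(net)
        evals, evecs = np.linalg.eigh(M)
        v = np.abs(evecs[:, int(np.argmax(evals))])
        e_dense = v / v.max()
        worst = max(worst, float(np.nanmax(np.abs(e_power - e_dense))))
    return worst


def normds_conservation_error(n_matrices: int = 200, seed: int = 0) -> float:
    """Max |sum(normDS) - N(N-1)/2| over random win matrices."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(3, 13))
        X = rng.poisson(1.2, size=(n, n))
        np.fill_diagonal(X, 0)
        for method in ("Dij", "Pij"):
            nds = normalized_davids_scores(X, method=method)
            worst = max(worst, float(abs(nds.sum() - n * (n - 1) / 2.0)))
    return worst


def steepness_null_rejection_rate(n_reps: int = 500, n_rand: int = 199,
                                  seed: int = 0, alpha: float = 0.10,
                                  n_individuals: int = 6,
                                  mean_dyad_events: float = 4.0) -> float:
    """Type-I rate of the steepness randomization test under its own null.

    Data are generated exactly under the null: dyadic interaction counts are
    Poisson, win splits are fair binomials.  The rejection rate at ``alpha``
    should match ``alpha`` up to Monte Carlo error.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    nodes = [f"n{i}" for i in range(n_individuals)]
    for rep in range(n_reps):
        n_mat = rng.poisson(mean_dyad_events,
                            size=(n_individuals, n_individuals))
        n_mat = np.triu(n_mat, k=1)
        wins = rng.binomial(n_mat, 0.5)
        X = wins + (n_mat - wins).T
        win = WinMatrix(group_id="null", nodes=nodes, X=X)
        _, p = hierarchy_steepness(win, n_rand=n_rand,
                                   seed=int(rng.integers(2 ** 31)))
        if p <= alpha:
            rejections += 1
    return rejections / n_reps


def linearity_null_rejection_rate(n_reps: int = 500, n_rand: int = 199,
                                  seed: int = 0, alpha: float = 0.10,
                                  n_individuals: int = 8) -> float:
    """Type-I rate of the linearity test on random complete tournaments.

    Landau's h takes few distinct values in very small groups, so the
    achievable rejection rates are coarse there; the default group size of 8
    gives the null distribution enough support for a nominal-level check.
    """
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_individuals)]
    rejections = 0
    for rep in range(n_reps):
        direction = rng.random((n_individuals, n_individuals)) < 0.5
        X = np.triu(direction, k=1).astype(int)
        X += np.tril(1 - direction.T, k=-1).astype(int)
        np.fill_diagonal(X, 0)
        win = WinMatrix(group_id="null", nodes=nodes, X=X)
        _, _, _, p = landau_linearity(win, n_rand=n_rand,
                                      seed=int(rng.integers(2 ** 31)))
        if p <= alpha:
            rejections += 1
    return rejections / n_reps


@dataclass
class RecoveryReport:
    n_sims: int
    n_records_mean: float
    quad_age_negative_rate: float
    rearing_negative_rate: float
    sex_ratio_eliminated_rate: float


def recovery_study(n_sims: int = 100, seed: int = 0,
                   config: SimulationConfig | None = None,
                   n_groups: int = 34,
                   run_elimination: bool = True) -> RecoveryReport:
    """Planted-effect recovery across simulated multi-group datasets.

    Each replicate simulates a full multi-group dataset (~300 records with
    the default 34 groups), runs networks -> metrics -> design preparation,
    fits the main-effects mixed model for out-strength and records

    * whether the planted negative quadratic age effect is recovered with
      the correct (negative) sign,
    * whether the planted atypical-rearing deficit comes out negative,
    * whether backward AIC reduction eliminates sex ratio, which has no
      planted effect on grooming given.

    The sex-composition pathways (female-female assortment, sex- and
    rearing-dependent receiver attractiveness) are switched off so that sex
    ratio is a genuine null predictor of out-strength; the planted age and
    rearing effects on giving are kept at their defaults.
    """
    config = replace(config or SimulationConfig(), n_groups=n_groups,
                     sex_assortment=0.0, receiver_female_effect=0.0,
                     receiver_atypical_male_effect=0.0)
    rng = np.random.default_rng(seed)
    quad_neg = rear_neg = sexratio_out = 0
    n_records = []
    for i in range(n_sims):
        sim_seed = int(rng.integers(2 ** 31 - 10))
        obs, _ = simulate_dataset(config, seed=sim_seed, with_agonistic=False)
        table = compute_metrics_table(build_networks(obs), obs)
        design = prepare_design(table, "out_strength")
        n_records.append(len(design.df))
        fit = fit_lmm(design, MAIN_TERMS, reml=False)
        quad_neg += fit.params["age_sq"] < 0
        rear_neg += fit.params["atypical"] < 0
        if run_elimination:
            final, _ = aic_backward_reduction(design, MAIN_TERMS)
            sexratio_out += "sex_ratio" not in final.terms
    return RecoveryReport(
        n_sims=n_sims, n_records_mean=float(np.mean(n_records)),
        quad_age_negative_rate=quad_neg / n_sims,
        rearing_negative_rate=rear_neg / n_sims,
        sex_ratio_eliminated_rate=(sexratio_out / n_sims
                                   if run_elimination else float("nan")))
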