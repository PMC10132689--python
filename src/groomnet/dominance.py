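"""Dominance hierarchy analytics from flee-upon-aggression matrices.

A win is recorded for the aggressor whenever the opponent flees.  From the
dyadic win matrix the module computes

* normalized David's scores (cardinal rank), by default from the
  chance-corrected dyadic index D_ij = P_ij - (P_ij - 0.5) / (n_ij + 1),
  optionally from the raw win proportions P_ij;
* hierarchy steepness: the absolute slope of the normalized scores regressed
  on descending rank (1 = despotic, 0 = egalitarian), with a randomization
  test that redraws each dyad's wins as Binomial(n_ij, 1/2);
* Landau's linearity h and the h' correction for unknown or tied dyads,
  with a randomization test against random complete dominance orders.

Randomization p-values carry the small-sample +1 correction,
p = (1 + #{null >= observed}) / (1 + n_rand), so p is never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd

from .data_model import ObservationSet, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_RAND = 10_000
PASS_ALPHA = 0.10  # group-inclusion criterion for a resolved hierarchy


@dataclass
class WinMatrix:
    """Dyadic win counts; ``X[i, j]`` = number of times i made j flee."""

    group_id: str
    nodes: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.X.shape != (n, n):
            raise ValidationError("win matrix does not match node list")
        if (self.X < 0).any() or np.diagonal(self.X).any():
            raise ValidationError("invalid win matrix")

    @property
    def n(self) -> np.ndarray:
        """Symmetric dyadic interaction counts n_ij = X_ij + X_ji."""
        return self.X + self.X.T

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class DominanceResult:
    group_id: str
    nodes: list[str]
    norm_ds: np.ndarray
    centered_ds: np.ndarray
    steepness: float
    p_steepness: float
    h: float
    h_prime: float
    n_unknown_dyads: int
    p_linearity: float
    n_randomizations: int
    seed: int
    method: str = "Dij"
    passes: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passes = (self.p_steepness <= PASS_ALPHA
                       and self.p_linearity <= PASS_ALPHA)


def build_win_matrix(obs: ObservationSet, group_id: str) -> WinMatrix:
    """Tally the flee-upon-aggression matrix from (winner, loser) events."""
    nodes = list(obs.members(group_id))
    index = {iid: k for k, iid in enumerate(nodes)}
    X = np.zeros((len(nodes), len(nodes)), dtype=int)
    events = obs.events_for(group_id)
    if not events:
        logger.warning("group %s: no agonistic events; win matrix is empty",
                       group_id)
    for winner, loser in events:
        if winner not in index or loser not in index:
            raise ValidationError(
                f"group {group_id}: agonistic event ({winner}, {loser}) "
                f"references a non-member")
        X[index[winner], index[loser]] += 1
    return WinMatrix(group_id=group_id, nodes=nodes, X=X)


def dyadic_indices(win: WinMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(P, D): win proportions and chance-corrected dyadic dominance indices.

    P_ij = X_ij / n_ij; D_ij = P_ij - (P_ij - 0.5) / (n_ij + 1).  Dyads that
    never interacted are NaN in both.
    """
    return _dyadic_indices_from_X(win.X.astype(float))


def _dyadic_indices_from_X(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = X + np.swapaxes(X, -1, -2)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(n > 0, X / np.where(n > 0, n, 1.0), np.nan)
        D = P - (P - 0.5) / (n + 1.0)
    eye = np.eye(X.shape[-1], dtype=bool)
    P[..., eye] = np.nan
    D[..., eye] = np.nan
    return P, D


def normalized_davids_scores(win_or_X, method: str = "Dij") -> np.ndarray:
    """Normalized David's scores, normDS = (DS + N(N-1)/2) / N.

    DS_i = w_i + w2_i - l_i - l2_i with w_i = sum_j d_ij,
    w2_i = sum_j d_ij * w_j, l_i = sum_j d_ji, l2_i = sum_j d_ji * l_j,
    where d is the chosen dyadic index (Dij default, Pij optional) and
    unknown dyads contribute zero.
    """
    X = win_or_X.X if isinstance(win_or_X, WinMatrix) else np.asarray(win_or_X)
    if X.shape[-1] < 2:
        raise ValidationError("David's scores need at least 2 individuals")
    P, D = _dyadic_indices_from_X(X.astype(float))
    d = {"Dij": D, "Pij": P}[method]
    d = np.nan_to_num(d, nan=0.0)
    return _norm_ds_from_index(d)


def _norm_ds_from_index(d: np.ndarray) -> np.ndarray:
    """normDS from a (possibly batched) dyadic index array (NaN-free)."""
    N = d.shape[-1]
    w = d.sum(axis=-1)
    l = d.sum(axis=-2)
    w2 = np.einsum("...ij,...j->...i", d, w)
    l2 = np.einsum("...ji,...j->...i", d, l)
    ds = w + w2 - l - l2
    return (ds + N * (N - 1) / 2.0) / N


def center_scores(norm_ds: np.ndarray) -> np.ndarray:
    """Mean-center normalized David's scores within a group.

    Because normDS sums to N(N-1)/2, this subtracts (N-1)/2 and makes scores
    comparable across groups of different size.
    """
    norm_ds = np.asarray(norm_ds, dtype=float)
    return norm_ds - norm_ds.mean(axis=-1, keepdims=True)


def steepness_from_scores(norm_ds: np.ndarray) -> np.ndarray:
    """|slope| of descending-sorted normDS regressed on ranks 1..N."""
    norm_ds = np.asarray(norm_ds, dtype=float)
    N = norm_ds.shape[-1]
    y = -np.sort(-norm_ds, axis=-1)  # descending
    ranks = np.arange(1, N + 1, dtype=float)
    rc = ranks - ranks.mean()
    slope = (y * rc).sum(axis=-1) / (rc ** 2).sum()
    return np.abs(slope)


def _binomial_null_scores(n_dyads: np.ndarray, n_rand: int,
                          rng: np.random.Generator,
                          method: str) -> np.ndarray:
    """normDS under the null: per dyad, wins ~ Binomial(n_ij, 1/2)."""
    N = n_dyads.shape[0]
    iu = np.triu_indices(N, k=1)
    n_flat = n_dyads[iu]
    wins = rng.binomial(n_flat[None, :], 0.5, size=(n_rand, n_flat.size))
    X = np.zeros((n_rand, N, N))
    X[:, iu[0], iu[1]] = wins
    X[:, iu[1], iu[0]] = n_flat[None, :] - wins
    P, D = _dyadic_indices_from_X(X)
    d = np.nan_to_num({"Dij": D, "Pij": P}[method], nan=0.0)
    return _norm_ds_from_index(d)


def hierarchy_steepness(win: WinMatrix, n_rand: int = DEFAULT_N_RAND,
                        seed: int = 0, method: str = "Dij",
                        ) -> tuple[float, float]:
    """Observed steepness and its randomization p-value.

    The null keeps each dyad's interaction count n_ij and redraws the win
    split as Binomial(n_ij, 1/2); p is the +1-corrected fraction of null
    steepness values at least as large as the observed one.
    """
    if n_rand < 1:
        raise ValidationError("need at least one randomization")
    observed = float(steepness_from_scores(
        normalized_davids_scores(win, method=method)))
    n_dyads = win.n
    if n_dyads.sum() == 0:
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    null_scores = _binomial_null_scores(n_dyads, n_rand, rng, method)
    null_steep = steepness_from_scores(null_scores)
    p = (1 + int((null_steep >= observed - 1e-12).sum())) / (1 + n_rand)
    return observed, float(p)


def landau_h(X: np.ndarray) -> tuple[float, float, int]:
    """(h, h', u) for a win matrix.

    Dominance per dyad: i dominates j if X_ij > X_ji; tied if equal and
    positive; unknown if the dyad never interacted.  V_i counts dominated
    partners (ties and unknowns count 1/2).  h = 12/(N^3-N) * sum
    (V_i - (N-1)/2)^2 and h' = h + 6u/(N^3-N) where u is the number of
    unknown dyads.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    if N < 3:
        raise ValidationError("Landau's h needs at least 3 individuals")
    n = X + X.T
    dominates = (X > X.T).astype(float)
    undecided = (n == 0) | ((X == X.T) & (n > 0))  # unknown or tied
    np.fill_diagonal(undecided, False)
    V = dominates.sum(axis=1) + 0.5 * undecided.sum(axis=1)
    h = 12.0 / (N ** 3 - N) * ((V - (N - 1) / 2.0) ** 2).sum()
    iu = np.triu_indices(N, k=1)
    u = int((n[iu] == 0).sum())
    h_prime = h + 6.0 * u / (N ** 3 - N)
    return float(h), float(h_prime), u


def _random_tournament_h(N: int, n_rand: int,
                         rng: np.random.Generator) -> np.ndarray:
    """h of random complete dominance matrices (each dyad a fair coin)."""
    iu = np.triu_indices(N, k=1)
    wins = rng.random((n_rand, iu[0].size)) < 0.5
    V = np.zeros((n_rand, N))
    np.add.at(V, (slice(None), iu[0]), wins)          # i beats j
    # add upper-triangle losses to the j side
    for k in range(iu[0].size):  # N <= 15, cheap
        V[:, iu[1][k]] += ~wins[:, k]
    return 12.0 / (N ** 3 - N) * ((V - (N - 1) / 2.0) ** 2).sum(axis=1)


def landau_linearity(win: WinMatrix, n_rand: int = DEFAULT_N_RAND,
                     seed: int = 0, fill_unknowns: bool = False,
                     ) -> tuple[float, float, int, float]:
    """(h, h', u, p): linearity indices and randomization significance.

    The default null compares h' with the h of random complete dominance
    matrices (every dyad decided by a fair coin).  With
    ``fill_unknowns=True`` the observed statistic is instead the Monte Carlo
    mean h over random completions of the unknown/tied dyads (a variant of
    the two-step procedure used by some dominance software), tested against
    the same null.
    """
    if n_rand < 1:
        raise ValidationError("need at least one randomization")
    h, h_prime, u = landau_h(win.X)
    rng = np.random.default_rng(seed)
    N = win.n_nodes
    if fill_unknowns:
        n = win.n
        undecided = (n == 0) | ((win.X == win.X.T) & (n > 0))
        np.fill_diagonal(undecided, False)
        iu = np.triu_indices(N, k=1)
        und = undecided[iu]
        base_dom = (win.X > win.X.T).astype(float)
        fills = rng.random((256, int(und.sum()))) < 0.5
        hs = []
        for f in fills:
            X_fill = base_dom.copy()
            X_fill[iu[0][und], iu[1][und]] = f
            X_fill[iu[1][und], iu[0][und]] = ~f
            hs.append(landau_h(X_fill)[0])
        statistic = float(np.mean(hs))
    else:
        statistic = h_prime
    null_h = _random_tournament_h(N, n_rand, rng)
    p = (1 + int((null_h >= statistic - 1e-12).sum())) / (1 + n_rand)
    return h, h_prime, u, float(p)


def plot_rank_age_trends(scores: "pd.DataFrame", path,
                         age_col: str = "age", sex_col: str = "sex",
                         score_col: str = "centered_ds") -> None:
    """Visual aid: centered David's scores against age, by sex.

    Draws a quadratic least-squares trend per sex.  No inferential claim is
    attached; the plot mirrors how rank-age patterns are usually inspected
    alongside grooming-age effects.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"female": "tab:red", "male": "tab:blue"}
    for sex, sub in scores.groupby(sex_col):
        ax.scatter(sub[age_col], sub[score_col], s=14,
                   color=colors.get(sex, "k"), label=sex, alpha=0.7)
        if len(sub) >= 3:
            coeffs = np.polyfit(sub[age_col], sub[score_col], 2)
            grid = np.linspace(sub[age_col].min(), sub[age_col].max(), 100)
            ax.plot(grid, np.polyval(coeffs, grid),
                    color=colors.get(sex, "k"))
    ax.set_xlabel("age (years)")
    ax.set_ylabel("centered normalized David's score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def analyze_group(obs: ObservationSet, group_id: str,
                  n_rand: int = DEFAULT_N_RAND, seed: int = 0,
                  method: str = "Dij") -> DominanceResult:
    """Full dominance report for one group (scores, steepness, linearity)."""
    win = build_win_matrix(obs, group_id)
    norm_ds = normalized_davids_scores(win, method=method)
    steep, p_steep = hierarchy_steepness(win, n_rand=n_rand, seed=seed,
                                         method=method)
    h, h_prime, u, p_lin = landau_linearity(win, n_rand=n_rand, seed=seed + 1)
    return DominanceResult(
        group_id=group_id, nodes=list(win.nodes), norm_ds=norm_ds,
        centered_ds=center_scores(norm_ds), steepness=steep,
        p_steepness=p_steep, h=h, h_prime=h_prime, n_unknown_dyads=u,
        p_linearity=p_lin, n_randomizations=n_rand, seed=seed, method=method)
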