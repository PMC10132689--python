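"""Node-level grooming network metrics and their group-size standardizations.

Five metrics per individual-in-group:

* out-strength / in-strength -- total frequency of grooming given / received
  (row / column sums of the weighted adjacency).
* disparity  Y_i = sum_j (w_ij / s_out_i)^2 -- heterogeneity of an
  individual's given-grooming relationships (1/k for k equally strong
  partners, 1 for a single partner).
* affinity -- the edge-weight-weighted mean strength of a node's partners on
  the symmetrized network (preference for high-strength partners).
* eigenvector centrality -- leading eigenvector of the symmetrized network,
  scaled to max 1 per group; computed by power iteration.

Indirect metrics (affinity, eigenvector centrality) are only biologically
meaningful in reasonably sized networks and are reported as missing for
groups with fewer than ``MIN_INDIRECT_GROUP_SIZE`` adults.  Nodes with zero
grooming activity get missing (never silently zero) metrics where the metric
is undefined for them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ObservationSet, ValidationError
from .network_build import GroomingNetwork, symmetrize

logger = logging.getLogger(__name__)

MIN_INDIRECT_GROUP_SIZE = 5
CORRELATION_THRESHOLD = 0.70

RAW_METRICS = ["out_strength", "in_strength", "disparity", "affinity",
               "eigenvector"]
STANDARDIZED = {"out_strength": "out_strength_std",
                "in_strength": "in_strength_std",
                "disparity": "disparity_dev",
                "affinity": "affinity_scaled",
                "eigenvector": "eigenvector_scaled"}


def strengths(net: GroomingNetwork) -> tuple[np.ndarray, np.ndarray]:
    """(out-strength, in-strength): row and column sums of W."""
    return net.W.sum(axis=1), net.W.sum(axis=0)


def degree(net: GroomingNetwork) -> np.ndarray:
    """Number of distinct partners groomed (positive out-going weight)."""
    return (net.W > 0).sum(axis=1)


def disparity(net: GroomingNetwork, use_symmetrized: bool = False) -> np.ndarray:
    """Y_i = sum_j (w_ij / s_i)^2 over out-going edges (NaN when s_i = 0)."""
    W = symmetrize(net) if use_symmetrized else net.W
    s = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = W / s[:, None]
        Y = np.where(s > 0, (shares ** 2).sum(axis=1), np.nan)
    if np.isnan(Y).any():
        logger.info("group %s: %d node(s) with zero out-strength; disparity "
                    "missing", net.group_id, int(np.isnan(Y).sum()))
    return Y


def affinity(net: GroomingNetwork, weighted: bool = True) -> np.ndarray:
    """Weighted mean strength of a node's partners on M = W + W^T.

    With ``weighted=False`` the plain mean of the partners' strengths is used
    instead of weighting by edge weight.  Isolated nodes get NaN.
    """
    M = symmetrize(net)
    s = M.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if weighted:
            a = np.where(s > 0, (M @ s) / s, np.nan)
        else:
            k = (M > 0).sum(axis=1)
            a = np.where(k > 0, ((M > 0) @ s) / k, np.nan)
    return a


def _power_iteration(M: np.ndarray, tol: float = 1e-10,
                     max_iter: int = 100_000) -> np.ndarray:
    """Leading eigenvector of a symmetric non-negative matrix.

    A diagonal shift by the maximum row sum guarantees the dominant
    eigenvalue is unique in modulus (the shift leaves eigenvectors
    unchanged), so the iteration cannot oscillate on bipartite structures.
    """
    n = M.shape[0]
    shift = float(M.sum(axis=1).max())
    A = M + shift * np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = A @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValidationError("no edges: zero matrix in power iteration")
        w /= norm
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    return v


def eigenvector_centrality(net: GroomingNetwork, tol: float = 1e-10,
                           ) -> np.ndarray:
    """Leading-eigenvector scores on M = W + W^T, scaled to max 1.

    Computed per connected component (a disconnected network is flagged with
    a warning and each non-trivial component is scaled to its own maximum).
    Nodes with no edges at all get NaN.
    """
    M = symmetrize(net)
    if not (M > 0).any():
        raise ValidationError(f"group {net.group_id}: no edges")
    graph = nx.from_numpy_array(M)
    components = [sorted(c) for c in nx.connected_components(graph)]
    nontrivial = [c for c in components if len(c) > 1]
    if len(nontrivial) > 1:
        logger.warning("group %s: grooming network is disconnected "
                       "(%d components); eigenvector centrality computed per "
                       "component", net.group_id, len(nontrivial))
    e = np.full(net.n_nodes, np.nan)
    for comp in components:
        if len(comp) == 1:
            continue  # isolated node: centrality undefined, stays NaN
        idx = np.asarray(comp)
        sub = M[np.ix_(idx, idx)]
        v = _power_iteration(sub, tol=tol)
        e[idx] = v / v.max()
    return e


@dataclass
class MetricsOptions:
    """Switches for the metric definitions (defaults match the main text)."""

    disparity_symmetrized: bool = False
    affinity_weighted: bool = True
    min_indirect_group_size: int = MIN_INDIRECT_GROUP_SIZE


def compute_metrics_table(networks: list[GroomingNetwork],
                          obs: ObservationSet,
                          options: MetricsOptions | None = None,
                          ) -> pd.DataFrame:
    """Tidy per-individual-in-group table of metrics, traits and covariates."""
    options = options or MetricsOptions()
    frames = []
    for net in networks:
        s_out, s_in = strengths(net)
        Y = disparity(net, use_symmetrized=options.disparity_symmetrized)
        a = affinity(net, weighted=options.affinity_weighted)
        try:
            e = eigenvector_centrality(net)
        except ValidationError:
            e = np.full(net.n_nodes, np.nan)
        if net.n_nodes < options.min_indirect_group_size:
            a = np.full(net.n_nodes, np.nan)
            e = np.full(net.n_nodes, np.nan)
        recs = [obs.record(net.group_id, iid) for iid in net.nodes]
        frames.append(pd.DataFrame({
            "group_id": net.group_id,
            "individual_id": net.nodes,
            "sex": [r.sex for r in recs],
            "age": [r.age for r in recs],
            "rearing": [r.rearing for r in recs],
            "group_size": net.n_nodes,
            "sex_ratio": obs.sex_ratio(net.group_id),
            "degree": degree(net),
            "out_strength": s_out,
            "in_strength": s_in,
            "disparity": Y,
            "affinity": a,
            "eigenvector": e,
        }))
    return pd.concat(frames, ignore_index=True)


def metrics_from_published(individuals: pd.DataFrame,
                           groups: pd.DataFrame) -> pd.DataFrame:
    """Metrics table from workbook-published values (no recomputation)."""
    table = individuals.merge(groups[["group_id", "group_size", "sex_ratio"]],
                              on="group_id", how="left", validate="m:1")
    return table


def standardize_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Add group-size-standardized metric variants.

    * strengths divided by the number of available partners (N - 1);
    * disparity as the deviation from edge-weight disparity, Y - 1/k
      (observed minus the equal-weights expectation for the same number of
      partners);
    * affinity and eigenvector centrality scaled to the maximum value within
      the individual's network.
    """
    if (table["group_size"] < 2).any():
        raise ValidationError("cannot standardize metrics for a group of 1")
    out = table.copy()
    out["out_strength_std"] = out["out_strength"] / (out["group_size"] - 1)
    out["in_strength_std"] = out["in_strength"] / (out["group_size"] - 1)
    if "degree" in out:
        k = out["degree"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            baseline = np.where(k > 0, 1.0 / np.where(k > 0, k, 1.0), np.nan)
        out["disparity_dev"] = out["disparity"] - baseline
    else:  # published tables without partner counts
        out["disparity_dev"] = np.nan
    grp = out.groupby("group_id")
    out["affinity_scaled"] = out["affinity"] / grp["affinity"].transform("max")
    out["eigenvector_scaled"] = (out["eigenvector"]
                                 / grp["eigenvector"].transform("max"))
    return out


def metric_correlation_screen(table: pd.DataFrame,
                              metrics: list[str] | None = None,
                              threshold: float = CORRELATION_THRESHOLD,
                              ) -> pd.DataFrame:
    """Pearson correlations for all metric pairs, with exclusion flags.

    Pairs exceeding ``|r| > threshold`` are flagged (the a-priori rule for
    dropping redundant measures).  Pairs are evaluated on pairwise-complete
    records; a constant column yields a missing correlation.
    """
    metrics = metrics or RAW_METRICS
    rows = []
    for m1, m2 in itertools.combinations(metrics, 2):
        sub = table[[m1, m2]].dropna()
        n = len(sub)
        if n < 3 or sub[m1].nunique() < 2 or sub[m2].nunique() < 2:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(sub[m1], sub[m2])
        flagged = bool(abs(r) > threshold) if np.isfinite(r) else False
        rows.append({"metric_a": m1, "metric_b": m2, "r": r, "p": p,
                     "n": n, "flagged": flagged})
    screen = pd.DataFrame(rows)
    for row in screen.itertuples(index=False):
        if row.flagged:
            logger.warning("correlation screen: |r(%s, %s)| = %.3f exceeds "
                           "%.2f", row.metric_a, row.metric_b, abs(row.r),
                           threshold)
    return screen
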