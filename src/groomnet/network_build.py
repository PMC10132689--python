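"""Directed, weighted grooming networks from scan records.

Edge weights use the *index of interactions*: the number of scans in which
actor i groomed receiver j, divided by the number of scans in which the dyad
(i, j) was jointly observable.  A scan counts toward the denominator unless
*both* i and j were out of sight (when only one is invisible the dyad's
grooming state is still knowable, so the scan is kept).  The denominator is
therefore per-dyad; a group-level shared denominator (total scans) is
available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import ObservationSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GroomingCounts:
    """Raw scan tallies for one group.

    ``C[i, j]`` is the number of scans where i groomed j; ``D[i, j]`` the
    number of scans where the dyad was jointly observable (total scans minus
    scans with both i and j out of sight).
    """

    group_id: str
    nodes: list[str]
    C: np.ndarray
    D: np.ndarray
    total_scans: int

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.C.shape != (n, n) or self.D.shape != (n, n):
            raise ValidationError("count matrices do not match node list")
        if np.diagonal(self.C).any():
            raise ValidationError("grooming counts on the diagonal")
        if not np.array_equal(self.D, self.D.T):
            raise ValidationError("dyad denominator is not symmetric")
        if (self.D < 0).any() or (self.D > self.total_scans).any():
            raise ValidationError("dyad denominator outside [0, total scans]")
        if (self.C > self.D).any():
            raise ValidationError("grooming count exceeds observable scans")


@dataclass
class GroomingNetwork:
    """Directed weighted grooming network (index-of-interactions weights)."""

    group_id: str
    nodes: list[str]
    W: np.ndarray
    counts: GroomingCounts | None = None

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.W.shape != (n, n):
            raise ValidationError("weight matrix does not match node list")
        if np.diagonal(self.W).any():
            raise ValidationError("self-loop weights are not allowed")
        if not np.isfinite(self.W).all():
            raise ValidationError("non-finite edge weights")
        if (self.W < 0).any() or (self.W > 1).any():
            raise ValidationError("edge weights outside [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def tally_grooming(obs: ObservationSet, group_id: str) -> GroomingCounts:
    """Tally grooming counts and per-dyad observable-scan denominators."""
    nodes = list(obs.members(group_id))  # raises KeyError for unknown group
    scans = obs.scans_for(group_id)
    if not scans:
        raise ValidationError(f"group {group_id!r} has no scans")
    index = {iid: k for k, iid in enumerate(nodes)}
    n = len(nodes)
    C = np.zeros((n, n), dtype=int)
    out_flags = np.zeros((len(scans), n), dtype=bool)
    for s, scan in enumerate(scans):
        actors_seen: set[str] = set()
        for actor, receiver in scan.grooming_pairs:
            if actor in actors_seen:
                logger.warning("group %s scan %d: actor %s grooms more than "
                               "one receiver in a single scan", group_id,
                               scan.scan_index, actor)
            actors_seen.add(actor)
            C[index[actor], index[receiver]] += 1
        for iid in scan.out_of_sight:
            out_flags[s, index[iid]] = True
    # scans where both members of a dyad were out of sight
    joint_out = out_flags.astype(int).T @ out_flags.astype(int)
    D = len(scans) - joint_out
    np.fill_diagonal(D, len(scans))
    return GroomingCounts(group_id=group_id, nodes=nodes, C=C, D=D,
                          total_scans=len(scans))


def index_of_interactions(counts: GroomingCounts,
                          shared_denominator: bool = False) -> GroomingNetwork:
    """Standardize counts into edge weights w_ij = C_ij / D_ij.

    With ``shared_denominator=True`` every dyad is divided by the total scan
    count instead of its own observable-scan count.
    """
    C = counts.C.astype(float)
    if shared_denominator:
        D = np.full_like(C, float(counts.total_scans))
    else:
        D = counts.D.astype(float)
    bad = (D == 0) & (C > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"group {counts.group_id}: dyad ({counts.nodes[i]}, "
            f"{counts.nodes[j]}) has grooming but zero observable scans")
    never_observable = (D == 0) & (C == 0)
    np.fill_diagonal(never_observable, False)
    if never_observable.any():
        logger.warning("group %s: %d dyad(s) never jointly observable; "
                       "weight set to 0", counts.group_id,
                       int(never_observable.sum()) // 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(D > 0, C / np.where(D > 0, D, 1.0), 0.0)
    np.fill_diagonal(W, 0.0)
    return GroomingNetwork(group_id=counts.group_id, nodes=list(counts.nodes),
                           W=W, counts=counts)


def symmetrize(net: GroomingNetwork) -> np.ndarray:
    """Total dyadic grooming rate M = W + W^T (symmetric, zero diagonal)."""
    return net.W + net.W.T


def build_networks(obs: ObservationSet,
                   shared_denominator: bool = False) -> list[GroomingNetwork]:
    """Tally and standardize every group with scans, in group order."""
    nets = []
    for gid in obs.group_ids:
        if obs.scans_for(gid):
            nets.append(index_of_interactions(
                tally_grooming(obs, gid),
                shared_denominator=shared_denominator))
    return nets
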