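import logging

import numpy as np
import pytest

from groomnet.data_model import (GroupRecord, IndividualRecord,
                                 ObservationSet, ScanEvent)
from groomnet.network_build import GroomingNetwork, build_networks
from groomnet.network_metrics import compute_metrics_table, standardize_metrics
from groomnet.reference import make_reference_observations

logging.getLogger("groomnet").setLevel(logging.ERROR)


def make_obs(groups, scans=(), agonistic=(), traits=None):
    """Small hand-built ObservationSet.

    ``groups`` maps group_id -> member ids; ``traits`` optionally maps
    (group_id, individual_id) -> (sex, age, rearing).
    """
    traits = traits or {}
    individuals, group_records = [], []
    for gid, members in groups.items():
        group_records.append(GroupRecord(group_id=gid, members=tuple(members)))
        for k, iid in enumerate(members):
            sex, age, rearing = traits.get(
                (gid, iid), ("female" if k % 2 else "male", 15.0 + k,
                             "mother_reared"))
            individuals.append(IndividualRecord(
                individual_id=iid, group_id=gid, sex=sex, age=age,
                rearing=rearing))
    return ObservationSet(individuals=individuals, groups=group_records,
                          scans=list(scans), agonistic_events=list(agonistic))


def net_from_W(W, group_id="G"):
    W = np.asarray(W, dtype=float)
    nodes = [f"n{i}" for i in range(W.shape[0])]
    return GroomingNetwork(group_id=group_id, nodes=nodes, W=W)


@pytest.fixture(scope="session")
def reference_obs():
    """Synthetic reference dataset on the published composition (seed 1)."""
    obs, gt = make_reference_observations(seed=1)
    return obs, gt


@pytest.fixture(scope="session")
def reference_table(reference_obs):
    obs, _ = reference_obs
    return standardize_metrics(
        compute_metrics_table(build_networks(obs), obs))


@pytest.fixture(scope="session")
def reference_workbook(tmp_path_factory):
    from groomnet.reference import make_reference_workbook
    path = tmp_path_factory.mktemp("wb") / "reference.xlsx"
    make_reference_workbook(path, seed=1)
    return path


__all__ = ["make_obs", "net_from_W"]
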