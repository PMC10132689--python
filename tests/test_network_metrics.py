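import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from groomnet.data_model import ValidationError
from groomnet.network_metrics import (affinity, disparity,
                                      eigenvector_centrality,
                                      metric_correlation_screen,
                                      standardize_metrics, strengths)
from groomnet.validation import random_network

from conftest import make_obs, net_from_W


def test_strengths_are_row_and_column_sums():
    net = net_from_W([[0.0, 0.1, 0.2], [0.0, 0.0, 0.0], [0.3, 0.0, 0.0]])
    s_out, s_in = strengths(net)
    assert s_out == pytest.approx([0.3, 0.0, 0.3])
    assert s_in == pytest.approx([0.3, 0.1, 0.2])
    assert s_out.sum() == pytest.approx(s_in.sum())


@pytest.mark.parametrize("weights,expected", [
    ([0.2, 0.2, 0.2, 0.2], 0.25),   # equal shares to k=4 partners -> 1/k
    ([0.7, 0.0, 0.0, 0.0], 1.0),    # single partner
    ([0.1, 0.3, 0.0, 0.0], 0.625),  # 0.25^2 + 0.75^2
])
def test_disparity_hand_values(weights, expected):
    W = np.zeros((5, 5))
    W[0, 1:] = weights
    assert disparity(net_from_W(W))[0] == pytest.approx(expected)


def test_disparity_missing_for_inactive_node():
    W = np.zeros((3, 3))
    W[0, 1] = 0.5
    Y = disparity(net_from_W(W))
    assert np.isnan(Y[2])


def test_affinity_two_node_and_regular_networks():
    net = net_from_W([[0.0, 0.2], [0.1, 0.0]])
    a = affinity(net)
    # each node's only partner: affinity equals the partner's strength
    assert a[0] == pytest.approx(0.3)
    assert a[1] == pytest.approx(0.3)
    # all-equal complete network: affinity equals the common strength
    W = np.full((4, 4), 0.1)
    np.fill_diagonal(W, 0)
    a = affinity(net_from_W(W))
    assert a == pytest.approx([0.6] * 4)


def test_affinity_three_node_line_hand_value():
    """Line a-b-c with symmetrized weights 0.2 and 0.4: center's affinity is
    the edge-weighted mean of its partners' strengths."""
    W = np.zeros((3, 3))
    W[0, 1] = 0.2
    W[1, 2] = 0.4
    net = net_from_W(W)
    a = affinity(net)
    # m = W + W^T; strengths s = (0.2, 0.6, 0.4)
    expected_center = (0.2 * 0.2 + 0.4 * 0.4) / 0.6
    assert a[1] == pytest.approx(expected_center)
    # unweighted variant: plain mean of partner strengths
    a_unw = affinity(net, weighted=False)
    assert a_unw[1] == pytest.approx((0.2 + 0.4) / 2)


def test_eigenvector_complete_path_and_scale_invariance():
    W = np.full((4, 4), 0.2)
    np.fill_diagonal(W, 0)
    assert eigenvector_centrality(net_from_W(W)) == pytest.approx([1.0] * 4)

    path = np.zeros((3, 3))
    path[0, 1] = path[1, 2] = 0.3
    e = eigenvector_centrality(net_from_W(path))
    assert e == pytest.approx([1 / np.sqrt(2), 1.0, 1 / np.sqrt(2)],
                              abs=1e-9)
    e2 = eigenvector_centrality(net_from_W(2 * path / 3))
    assert e2 == pytest.approx(e, abs=1e-9)

    with pytest.raises(ValidationError, match="no edges"):
        eigenvector_centrality(net_from_W(np.zeros((3, 3))))


def test_eigenvector_matches_dense_eigendecomposition():
    rng = np.random.default_rng(7)
    worst = 0.0
    for _ in range(50):
        net = random_network(rng)
        e = eigenvector_centrality(net)
        M = net.W + net.W.T
        evals, evecs = np.linalg.eigh(M)
        v = np.abs(evecs[:, np.argmax(evals)])
        worst = max(worst, float(np.max(np.abs(e - v / v.max()))))
    assert worst < 1e-8


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_disparity_bounds_property(seed):
    """1/k <= Y <= 1 for active nodes, for arbitrary weighted networks."""
    net = random_network(np.random.default_rng(seed))
    Y = disparity(net)
    k = (net.W > 0).sum(axis=1)
    for yi, ki in zip(Y, k):
        if ki == 0:
            assert np.isnan(yi)
        else:
            assert 1.0 / ki - 1e-12 <= yi <= 1.0 + 1e-12


def _metrics_table_for(W_by_group, sizes):
    from groomnet.network_build import build_networks
    from groomnet.network_metrics import compute_metrics_table
    import pandas as pd
    rows = []
    for gid, W in W_by_group.items():
        n = W.shape[0]
        s_out = W.sum(axis=1)
        rows.append(pd.DataFrame({
            "group_id": gid,
            "individual_id": [f"{gid}{i}" for i in range(n)],
            "sex": "female", "age": 20.0, "rearing": "mother_reared",
            "group_size": n, "sex_ratio": 1.0,
            "degree": (W > 0).sum(axis=1),
            "out_strength": s_out, "in_strength": W.sum(axis=0),
            "disparity": disparity(net_from_W(W)),
            "affinity": affinity(net_from_W(W)),
            "eigenvector": eigenvector_centrality(net_from_W(W)),
        }))
    return pd.concat(rows, ignore_index=True)


def test_standardize_metrics_definitions():
    W = np.zeros((6, 6))
    W[0, 1:] = 0.06          # equal weights: disparity = 1/5, deviation 0
    W[1, 0] = 0.3
    W[2, 0] = 0.1
    W[3, 0] = W[4, 0] = W[5, 0] = 0.05
    table = _metrics_table_for({"G": W}, [6])
    out = standardize_metrics(table)
    assert out.loc[0, "out_strength_std"] == pytest.approx(0.3 / 5)  # 0.06
    assert out.loc[0, "disparity_dev"] == pytest.approx(0.0, abs=1e-12)
    assert out.loc[1, "disparity_dev"] == pytest.approx(1.0 - 1.0)
    assert (out["disparity_dev"].dropna() >= -1e-12).all()
    # within-group max scaling
    assert out["affinity_scaled"].max() == pytest.approx(1.0)
    assert out["eigenvector_scaled"].max() == pytest.approx(1.0)


def test_indirect_metrics_missing_below_group_size_threshold():
    from groomnet.data_model import ScanEvent
    from groomnet.network_build import build_networks
    from groomnet.network_metrics import compute_metrics_table
    scans = [ScanEvent("S", 0, frozenset({("a", "b"), ("b", "c")})),
             ScanEvent("S", 1, frozenset({("c", "a")}))]
    obs = make_obs({"S": ["a", "b", "c", "d"]}, scans=scans)
    table = compute_metrics_table(build_networks(obs), obs)
    assert table["affinity"].isna().all()
    assert table["eigenvector"].isna().all()
    assert table["out_strength"].notna().all()


def test_correlation_screen_flags_and_missing():
    import pandas as pd
    rng = np.random.default_rng(0)
    x = rng.random(30)
    table = pd.DataFrame({"out_strength": x, "in_strength": -x,
                          "disparity": rng.random(30),
                          "affinity": np.ones(30),
                          "eigenvector": rng.random(30)})
    screen = metric_correlation_screen(table)
    row = screen[(screen.metric_a == "out_strength")
                 & (screen.metric_b == "in_strength")].iloc[0]
    assert row.r == pytest.approx(-1.0)
    assert bool(row.flagged)
    const = screen[screen.metric_b == "affinity"]
    assert const["r"].isna().all()
    assert not const["flagged"].any()
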