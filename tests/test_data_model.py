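import numpy as np
import pandas as pd
import pytest

from groomnet.data_model import (FormatError, ParseError, ScanEvent,
                                 ValidationError, read_adjacency,
                                 read_scan_table,
                                 read_supplementary_workbook, write_adjacency,
                                 write_scan_table,
                                 write_supplementary_workbook)
from groomnet.synthetic_data import SimulationConfig, simulate_dataset

from conftest import make_obs


@pytest.fixture()
def three_group_obs():
    config = SimulationConfig(n_groups=3, n_scans_range=(30, 40))
    obs, _ = simulate_dataset(config, seed=42)
    return obs


def test_scan_table_round_trip_is_identity(tmp_path, three_group_obs):
    """Writing and re-reading a scan table preserves every observation."""
    path = tmp_path / "scans.csv"
    write_scan_table(three_group_obs, path)
    back = read_scan_table(path)
    assert back.group_ids == three_group_obs.group_ids
    assert {(r.group_id, r.individual_id, r.sex, r.rearing, r.age)
            for r in back.individuals} \
        == {(r.group_id, r.individual_id, r.sex, r.rearing, r.age)
            for r in three_group_obs.individuals}
    orig = {(s.group_id, s.scan_index): (s.grooming_pairs, s.out_of_sight)
            for s in three_group_obs.scans}
    got = {(s.group_id, s.scan_index): (s.grooming_pairs, s.out_of_sight)
           for s in back.scans}
    assert got == orig


def test_mutual_bout_reads_as_two_ordered_pairs(tmp_path):
    """A mutual grooming bout is stored as A->B plus B->A in one scan."""
    obs = make_obs({"G": ["a", "b", "c"]},
                   scans=[ScanEvent("G", 0,
                                    frozenset({("a", "b"), ("b", "a")}))])
    path = tmp_path / "scans.csv"
    write_scan_table(obs, path)
    back = read_scan_table(path)
    (scan,) = back.scans
    assert scan.grooming_pairs == frozenset({("a", "b"), ("b", "a")})


def test_scan_table_rejects_self_grooming_and_duplicates(tmp_path):
    header = ("group_id,scan_index,individual_id,sex,age,rearing,"
              "visible,behavior,partner_id\n")
    base = "G,0,a,male,12,mother_reared,1,grooming,{p}\n"
    path = tmp_path / "bad.csv"
    path.write_text(header + base.format(p="a"))
    with pytest.raises(ValidationError, match="actor equals receiver"):
        read_scan_table(path)
    rows = (header
            + "G,0,a,male,12,mother_reared,1,,\n"
            + "G,0,a,male,12,mother_reared,1,,\n")
    path.write_text(rows)
    with pytest.raises(ValidationError, match="duplicate"):
        read_scan_table(path)


def test_scan_table_malformed_row_names_row_number(tmp_path):
    header = ("group_id,scan_index,individual_id,sex,age,rearing,"
              "visible,behavior,partner_id\n")
    path = tmp_path / "bad.csv"
    path.write_text(header + "G,zero,a,male,12,mother_reared,1,,\n")
    with pytest.raises(ParseError, match="row 2"):
        read_scan_table(path)


def test_scan_table_unknown_partner_rejected_with_report(tmp_path, caplog):
    header = ("group_id,scan_index,individual_id,sex,age,rearing,"
              "visible,behavior,partner_id\n")
    rows = (header
            + "G,0,a,male,12,mother_reared,1,grooming,zz\n"
            + "G,0,b,female,14,mother_reared,1,,\n")
    path = tmp_path / "scan.csv"
    path.write_text(rows)
    with caplog.at_level("WARNING", logger="groomnet.data_model"):
        obs = read_scan_table(path)
    assert "rejected 1 row" in caplog.text
    assert obs.scans[0].grooming_pairs == frozenset()


@pytest.mark.parametrize("W", [
    np.zeros((3, 3)),
    np.array([[0.0, 0.125, 0.0], [0.0, 0.0, 0.5], [0.25, 0.0, 0.0]]),
])
def test_adjacency_round_trip_exact(tmp_path, W):
    """Labeled adjacency CSV round-trips labels and weights exactly."""
    path = tmp_path / "adj.csv"
    nodes = ["x", "y", "z"]
    write_adjacency(nodes, W, path)
    back_nodes, back_W = read_adjacency(path)
    assert back_nodes == nodes
    assert np.array_equal(back_W, W)
    if W.any():
        assert "0.125" in path.read_text()


def test_adjacency_label_mismatch_is_format_error(tmp_path):
    path = tmp_path / "adj.csv"
    path.write_text(",x,y\na,0,1\nb,0,0\n")
    with pytest.raises(FormatError, match="labels"):
        read_adjacency(path)


def test_workbook_round_trip(tmp_path):
    individuals = pd.DataFrame({
        "group_id": ["G", "G"], "individual_id": ["a", "b"],
        "sex": ["male", "female"], "age": [10.0, 20.0],
        "rearing": ["mother_reared", "atypically_reared"],
        "out_strength": [0.1, 0.2], "in_strength": [0.2, 0.1],
        "disparity": [1.0, 1.0], "affinity": [np.nan, np.nan],
        "eigenvector": [np.nan, np.nan]})
    groups = pd.DataFrame({"group_id": ["G"], "group_size": [2],
                           "sex_ratio": [1.0], "n_scans": [100]})
    W = np.array([[0.0, 0.1], [0.2, 0.0]])
    path = tmp_path / "wb.xlsx"
    write_supplementary_workbook(path, individuals, groups, {"G": (["a", "b"],
                                                                   W)})
    data = read_supplementary_workbook(path)
    assert list(data.matrices) == ["G"]
    nodes, back = data.matrices["G"]
    assert nodes == ["a", "b"]
    assert np.array_equal(back, W)
    pd.testing.assert_frame_equal(data.individuals, individuals)


def test_workbook_accepts_decimal_commas(tmp_path):
    """European exports with comma decimal separators parse correctly."""
    import openpyxl

    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "groups"
    ws.append(["group_id", "group_size", "sex_ratio", "n_scans"])
    ws.append(["G", 2, "0,5", 100])
    ws = wb.create_sheet("individuals")
    ws.append(["group_id", "individual_id", "sex", "age", "rearing",
               "out_strength"])
    ws.append(["G", "a", "male", "10,5", "mother_reared", "0,125"])
    ws.append(["G", "b", "female", 20, "mother_reared", "0,25"])
    ws = wb.create_sheet("matrix_G")
    ws.append(["", "a", "b"])
    ws.append(["a", 0, "0,125"])
    ws.append(["b", "0,25", 0])
    path = tmp_path / "comma.xlsx"
    wb.save(path)
    data = read_supplementary_workbook(path)
    assert data.groups.loc[0, "sex_ratio"] == 0.5
    assert data.individuals.loc[0, "age"] == 10.5
    _, W = data.matrices["G"]
    assert W[0, 1] == 0.125 and W[1, 0] == 0.25


def test_observation_set_referential_integrity():
    with pytest.raises(ValidationError):
        make_obs({"G": ["a", "b"]},
                 scans=[ScanEvent("G", 0, frozenset({("a", "zz")}))])
    with pytest.raises(ValidationError):
        make_obs({"G": ["a", "b"]}, agonistic=[("G", "a", "zz")])
    with pytest.raises(ValidationError, match="self-grooming"):
        ScanEvent("G", 0, frozenset({("a", "a")}))
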