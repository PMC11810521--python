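import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from richsrm.network_data import (
    AllocationRecord,
    AllocationSet,
    BinaryLayer,
    Individual,
    Roster,
    ValidationError,
    build_dyad_table,
    load_allocations,
    load_dyads,
    load_layer,
    load_roster,
    merge_transfer_reports,
)
from richsrm.synthetic import coastal_like, generate_roster

from conftest import make_roster


# ---------------------------------------------------------------- roster

def test_load_roster_preserves_order(tmp_path):
    p = tmp_path / "roster.csv"
    p.write_text(
        "id,site,group,wealth,income,food_insecurity\n"
        "a,coastal,afro,1000,50,0\n"
        "b,coastal,embera,2000,60,1\n"
        "c,coastal,afro,1500,70,2\n"
    )
    roster = load_roster(p)
    assert len(roster) == 3
    assert roster.ids == ["a", "b", "c"]
    assert roster.groups == ["afro", "embera", "afro"]


def test_duplicate_id_rejected():
    inds = [
        Individual("a", "coastal", "afro", 1000, 1, 0),
        Individual("a", "coastal", "afro", 2000, 1, 0),
    ]
    with pytest.raises(ValidationError, match="a"):
        Roster(inds)


def test_nonpositive_wealth_rejected():
    with pytest.raises(ValidationError):
        Individual("a", "coastal", "afro", 0.0, 1, 0).validate()


def test_unknown_site_rejected():
    with pytest.raises(ValidationError):
        Individual("a", "mars", "afro", 1000, 1, 0).validate()


def test_roster_roundtrip(tmp_path):
    roster = generate_roster(coastal_like(), seed=5)
    p = tmp_path / "roster.csv"
    roster.save(p)
    back = load_roster(p)
    assert back.ids == roster.ids
    assert back.groups == roster.groups
    for a, b in zip(roster, back):
        assert a.site == b.site
        assert a.wealth == pytest.approx(b.wealth)
        assert a.income == pytest.approx(b.income)
        assert a.food_insecurity == b.food_insecurity


def test_log_wealth_derived_covariate(toy_roster):
    lw = toy_roster.covariate("log_wealth")
    assert np.allclose(lw, np.log(toy_roster.covariate("wealth")))


# ---------------------------------------------------------------- layers

def test_empty_edge_file_gives_zero_layer(tmp_path, toy_roster):
    p = tmp_path / "layer.csv"
    p.write_text("focal_id,alter_id,value\n")
    layer = load_layer(p, toy_roster, "friendship")
    assert layer.adjacency.sum() == 0


def test_self_edge_rejected(tmp_path, toy_roster):
    p = tmp_path / "layer.csv"
    p.write_text("focal_id,alter_id,value\np0,p0,1\n")
    with pytest.raises(ValidationError, match="self-edge"):
        load_layer(p, toy_roster, "friendship")


def test_unknown_id_rejected(tmp_path, toy_roster):
    p = tmp_path / "layer.csv"
    p.write_text("focal_id,alter_id,value\np0,zzz,1\n")
    with pytest.raises(ValidationError, match="zzz"):
        load_layer(p, toy_roster, "friendship")


def test_bad_value_rejected(tmp_path, toy_roster):
    p = tmp_path / "layer.csv"
    p.write_text("focal_id,alter_id,value\np0,p1,2\n")
    with pytest.raises(ValidationError):
        load_layer(p, toy_roster, "friendship")


def test_layer_roundtrip(tmp_path, coastal_site):
    layer = coastal_site.layers["friendship"]
    p = tmp_path / "layer.csv"
    layer.save(p)
    back = load_layer(p, coastal_site.roster, "friendship")
    assert np.array_equal(back.adjacency, layer.adjacency)
    assert back.edge_count() == layer.edge_count()


def test_graphml_export(tmp_path, toy_roster):
    adj = np.zeros((6, 6), dtype=int)
    adj[0, 1] = adj[2, 3] = 1
    layer = BinaryLayer("friendship", toy_roster, adj)
    out = tmp_path / "g.graphml"
    layer.to_graphml(out)
    import networkx as nx

    g = nx.read_graphml(out)
    assert g.number_of_edges() == 2
    assert g.nodes["p0"]["group"] == "afro"


# ---------------------------------------------------------------- merging

def _layer_from_pairs(roster, pairs):
    n = len(roster)
    adj = np.zeros((n, n), dtype=int)
    for i, j in pairs:
        adj[i, j] = 1
    return BinaryLayer("transfer", roster, adj)


def test_union_keeps_single_report(toy_roster):
    give = _layer_from_pairs(toy_roster, [(0, 1)])
    recv = _layer_from_pairs(toy_roster, [])
    merged = merge_transfer_reports(give, recv, rule="union")
    assert merged.adjacency[0, 1] == 1


def test_intersection_drops_single_report(toy_roster):
    give = _layer_from_pairs(toy_roster, [(0, 1)])
    recv = _layer_from_pairs(toy_roster, [])
    merged = merge_transfer_reports(give, recv, rule="intersection")
    assert merged.adjacency[0, 1] == 0


def test_merge_provenance_codes(toy_roster):
    give = _layer_from_pairs(toy_roster, [(0, 1), (1, 2)])
    recv = _layer_from_pairs(toy_roster, [(1, 2), (2, 3)])
    merged = merge_transfer_reports(give, recv, rule="union")
    assert merged.provenance[0, 1] == 1  # giver only
    assert merged.provenance[2, 3] == 2  # receiver only
    assert merged.provenance[1, 2] == 3  # both


@settings(max_examples=50, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)), max_size=12),
       st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)), max_size=12))
def test_union_superset_of_intersection(g_pairs, r_pairs):
    roster = make_roster(6)
    give = _layer_from_pairs(roster, [(i, j) for i, j in g_pairs if i != j])
    recv = _layer_from_pairs(roster, [(i, j) for i, j in r_pairs if i != j])
    union = merge_transfer_reports(give, recv, "union").adjacency
    inter = merge_transfer_reports(give, recv, "intersection").adjacency
    assert (union >= inter).all()
    assert union.sum() >= inter.sum()


# ---------------------------------------------------------------- dyads

def test_dyad_table_pair_count():
    roster = make_roster(3)
    table = build_dyad_table(roster)
    assert len(table) == 3 * 2
    assert len(table.to_frame()) == 6


def test_marriage_symmetric(toy_dyads, toy_roster):
    i, j = toy_roster.index["p0"], toy_roster.index["p1"]
    assert toy_dyads.marriage[i, j] == 1
    assert toy_dyads.marriage[j, i] == 1


def test_asymmetric_kin_rejected(toy_roster):
    with pytest.raises(ValidationError, match="asymmetric"):
        build_dyad_table(toy_roster, kin={("p0", "p1"): 0.5, ("p1", "p0"): 0.25})


def test_relatedness_range_enforced(toy_roster):
    with pytest.raises(ValidationError):
        build_dyad_table(toy_roster, kin={("p0", "p1"): 1.5})


def test_same_group_derived(toy_dyads, toy_roster):
    g = toy_roster.group_array()
    same = toy_dyads.same_group
    for i in range(len(toy_roster)):
        for j in range(len(toy_roster)):
            if i == j:
                assert same[i, j] == 0
            else:
                assert same[i, j] == float(g[i] == g[j])


def test_dyads_roundtrip(tmp_path, toy_dyads, toy_roster):
    p = tmp_path / "dyads.csv"
    toy_dyads.save(p)
    back = load_dyads(p, toy_roster)
    assert np.allclose(back.relatedness, toy_dyads.relatedness)
    assert np.array_equal(back.marriage, toy_dyads.marriage)


# ---------------------------------------------------------------- allocations

def test_allocation_must_sum_to_budget(toy_roster):
    rec = AllocationRecord("giving", "p0", {"p0": 3, "p1": 2}, budget=6,
                           coin_value=1000)
    with pytest.raises(ValidationError, match="sums to 5"):
        rec.validate(toy_roster)


def test_allocation_roundtrip(tmp_path, coastal_site):
    alloc = coastal_site.allocations["giving"]
    p = tmp_path / "alloc.csv"
    alloc.save(p)
    cfg = coastal_site.game_config
    back = load_allocations(p, coastal_site.roster, "giving",
                            budget=cfg.giving_coins, coin_value=cfg.giving_coin,
                            focal_ids=alloc.focal_ids)
    assert np.array_equal(back.count_matrix(), alloc.count_matrix())


def test_allocation_shortfall_fills_self(tmp_path, toy_roster):
    p = tmp_path / "alloc.csv"
    p.write_text("focal_id,target_id,count\np0,p1,4\n")
    alloc = load_allocations(p, toy_roster, "giving", budget=10, coin_value=1000,
                             focal_ids=["p0"])
    assert alloc.records[0].self_count() == 6
    assert alloc.records[0].counts["p1"] == 4
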