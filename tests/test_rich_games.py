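import numpy as np
import pytest

from richsrm.network_data import BinaryLayer, ValidationError
from richsrm.rich_games import (
    COASTAL_CONFIG,
    INLAND_CONFIG,
    compute_payouts,
    ingroup_outgroup_rates,
    percent_of_stake,
    population_identity_residual,
    summarize_game,
    taking_stake,
    total_stake_per_person,
)
from richsrm.synthetic import coastal_like, generate_site

from conftest import make_roster


# ------------------------------------------------------------- stakes

def test_taking_stakes_match_printed_values():
    assert taking_stake(115, 500) == 57_500
    assert taking_stake(151, 500) == 75_500
    assert taking_stake(0, 500) == 0


def test_taking_stake_rejects_negative():
    with pytest.raises(ValidationError):
        taking_stake(-1, 500)


def test_inland_total_stake():
    assert total_stake_per_person(INLAND_CONFIG, 151) == 110_500


def test_coastal_total_stake_computed_from_components():
    # printed total is 83,000; the sum of printed stakes is 82,500 — the
    # function computes from components and surfaces the 500-peso gap
    total = total_stake_per_person(COASTAL_CONFIG, 115)
    assert total == 82_500
    assert total != 83_000


# ------------------------------------------------------------- summaries

@pytest.mark.parametrize(
    "mean, stake, printed, decimals",
    [
        (11_760, 15_000, 78.4, 1),  # coastal giving mean
        (39_800, 57_500, 69.2, 1),  # coastal taking mean
        (36_300, 75_500, 48, 0),    # inland taking mean (printed as 48%)
        (1_600, 10_000, 16, 0),     # coastal reduction mean (printed as 16%)
        (47_000, 57_500, 81.7, 1),  # coastal taking median
    ],
)
def test_printed_percentages(mean, stake, printed, decimals):
    pct = percent_of_stake(mean, stake)
    # compare at the precision the value was printed with
    assert round(pct, decimals) == printed


def test_summarize_full_stake_degenerate():
    s = summarize_game([10_000, 10_000, 10_000], stake=10_000)
    assert s.mean_percent == 100.0
    assert s.sd == 0.0


def test_summarize_symmetric():
    s = summarize_game([0, 5_000, 10_000], stake=10_000)
    assert s.mean == 5_000
    assert s.median == 5_000
    assert s.mean_percent == 50.0


def test_summarize_rejects_amount_over_stake():
    with pytest.raises(ValidationError):
        summarize_game([11_000], stake=10_000)


def test_summarize_order_invariant():
    a = summarize_game([100, 900, 500], stake=1000)
    b = summarize_game([500, 100, 900], stake=1000)
    assert a == b


def test_percent_scale_invariant():
    assert percent_of_stake(4_000, 10_000) == percent_of_stake(8_000, 20_000)


# ------------------------------------------------------------- payouts

def _random_play(site, seed):
    """Random valid allocations/taking over the site's completers."""
    rng = np.random.default_rng(seed)
    from richsrm.network_data import AllocationRecord, AllocationSet

    roster = site.roster
    cfg = site.game_config
    n = len(roster)
    completers = site.completers

    def random_alloc(game, budget, coin):
        records = []
        for fid in completers:
            shares = rng.multinomial(budget, np.ones(n) / n)
            counts = {roster.ids[j]: int(c) for j, c in enumerate(shares) if c}
            counts.setdefault(fid, 0)
            records.append(AllocationRecord(game, fid, counts, budget, coin))
        return AllocationSet(game, roster, records)

    giving = random_alloc("giving", cfg.giving_coins, cfg.giving_coin)
    reduction = random_alloc("reduction", cfg.reduction_tokens, cfg.token_cost)
    adj = np.zeros((n, n), dtype=int)
    fidx = [roster.index[i] for i in completers]
    for i in fidx:
        row = rng.integers(0, 2, size=n)
        row[i] = 0
        adj[i] = row
    taking = BinaryLayer("taking_leave", roster, adj, focal_ids=completers)
    return giving, taking, reduction


def test_single_token_example():
    roster = make_roster(4)
    from richsrm.network_data import AllocationRecord, AllocationSet

    cfg = COASTAL_CONFIG
    keep_all = lambda fid, game, budget, coin: AllocationRecord(
        game, fid, {fid: budget}, budget, coin
    )
    giving = AllocationSet(
        "giving", roster,
        [keep_all(f, "giving", cfg.giving_coins, cfg.giving_coin)
         for f in roster.ids],
    )
    # p0 spends exactly one token on p1; everyone else keeps their budget
    red_records = []
    for fid in roster.ids:
        counts = {fid: cfg.reduction_tokens}
        if fid == "p0":
            counts = {fid: cfg.reduction_tokens - 1, "p1": 1}
        red_records.append(
            AllocationRecord("reduction", fid, counts, cfg.reduction_tokens,
                             cfg.token_cost)
        )
    reduction = AllocationSet("reduction", roster, red_records)
    n = len(roster)
    taking = BinaryLayer("taking_leave", roster, np.zeros((n, n), dtype=int))

    ledger = compute_payouts(roster, giving, taking, reduction, cfg)
    f = ledger.frame.set_index("id")
    assert f.loc["p1", "reduction_received"] == 4_000
    assert f.loc["p0", "reduction_spent"] == 1_000
    # identity still holds
    res = population_identity_residual(ledger, roster, giving, taking,
                                       reduction, cfg)
    assert res == 0


def test_no_tokens_conserves_stakes():
    site = generate_site(coastal_like(), seed=9)
    giving, taking, _ = _random_play(site, 1)
    from richsrm.network_data import AllocationRecord, AllocationSet

    cfg = site.game_config
    keep = AllocationSet(
        "reduction", site.roster,
        [AllocationRecord("reduction", fid, {fid: cfg.reduction_tokens},
                          cfg.reduction_tokens, cfg.token_cost)
         for fid in site.completers],
    )
    ledger = compute_payouts(site.roster, giving, taking, keep, cfg)
    n_targets = len(site.roster) - 1
    stakes = len(site.completers) * (
        cfg.giving_stake + taking_stake(n_targets, cfg.taking_coin)
        + cfg.reduction_budget
    )
    assert ledger.total_payout() == stakes


def test_payout_identity_random_plays(coastal_site):
    cfg = coastal_site.game_config
    for seed in range(20):
        giving, taking, reduction = _random_play(coastal_site, seed)
        ledger = compute_payouts(coastal_site.roster, giving, taking,
                                 reduction, cfg)
        res = population_identity_residual(ledger, coastal_site.roster, giving,
                                           taking, reduction, cfg)
        assert res == 0


# ------------------------------------------------------------- in/out rates

def test_rates_hand_example():
    roster = make_roster(5)  # groups alternate afro/embera: a e a e a
    n = len(roster)
    adj = np.zeros((n, n), dtype=int)
    # p0 (afro) leaves all in-group coins (p2, p4), takes out-group (p1, p3)
    adj[0, 2] = adj[0, 4] = 1
    layer = BinaryLayer("taking_leave", roster, adj, focal_ids=["p0"])
    rates = ingroup_outgroup_rates(layer, roster).set_index("id")
    assert rates.loc["p0", "in_rate"] == 1.0
    assert rates.loc["p0", "out_rate"] == 0.0
    assert rates.loc["p0", "side"] == "in_group_favouring"


def test_rates_indiscriminate_charity():
    roster = make_roster(5)
    n = len(roster)
    adj = np.ones((n, n), dtype=int)
    np.fill_diagonal(adj, 0)
    layer = BinaryLayer("taking_leave", roster, adj, focal_ids=["p0"])
    rates = ingroup_outgroup_rates(layer, roster).set_index("id")
    assert rates.loc["p0", "in_rate"] == 1.0
    assert rates.loc["p0", "out_rate"] == 1.0
    assert rates.loc["p0", "side"] == "indiscriminate"


def test_rates_undefined_reported_missing():
    roster = make_roster(4, groups=("afro",))  # single group: no out-group
    n = len(roster)
    layer = BinaryLayer("taking_leave", roster, np.zeros((n, n), dtype=int))
    rates = ingroup_outgroup_rates(layer, roster)
    assert rates["out_rate"].isna().all()
    assert (rates["side"] == "undefined").all()


def test_rates_label_swap(coastal_site):
    from richsrm.network_data import Individual, Roster

    roster = coastal_site.roster
    layer = coastal_site.layers["taking_leave"]
    swap = {"afro": "embera", "embera": "afro"}
    swapped = Roster(
        [
            Individual(i.id, i.site, swap[i.group], i.wealth, i.income,
                       i.food_insecurity)
            for i in roster
        ]
    )
    layer_sw = BinaryLayer("taking_leave", swapped, layer.adjacency,
                           focal_ids=layer.focal_ids)
    a = ingroup_outgroup_rates(layer, roster).set_index("id")
    b = ingroup_outgroup_rates(layer_sw, swapped).set_index("id")
    # relabelling every individual preserves the same-group relation, so the
    # rates are invariant; only the group column flips
    assert np.allclose(a["in_rate"], b["in_rate"], equal_nan=True)
    assert np.allclose(a["out_rate"], b["out_rate"], equal_nan=True)
    assert (a["side"] == b["side"]).all()
    assert (b["group"] == a["group"].map(swap)).all()


def test_rates_unit_square(coastal_site):
    rates = ingroup_outgroup_rates(coastal_site.layers["taking_leave"],
                                   coastal_site.roster)
    ok = rates[["in_rate", "out_rate"]].dropna()
    assert ((ok >= 0) & (ok <= 1)).all().all()
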