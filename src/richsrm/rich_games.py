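"""Stake and payout accounting for the three RICH economic games.

The games are played over a photo roster of all community adults:

* **giving** — the focal splits a stack of 1,000-peso coins between their
  own cell and any alters' cells;
* **taking** — a single 500-peso coin is pre-allocated to every photo and
  the focal may take or leave each one (1 = left);
* **costly reduction** — the focal may convert 1,000-peso coins into tokens,
  each of which removes ``multiplier`` x 1,000 pesos (default 4,000) from a
  target's earnings.

The ledger obeys an exact population accounting identity: the grand total
paid out equals the total stakes minus ``token_cost * (multiplier + 1)``
pesos per reduction token spent (the purchase price plus the destroyed
value).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .network_data import AllocationSet, BinaryLayer, Roster, ValidationError


@dataclasses.dataclass
class GameConfig:
    """Per-site stakes, coin values and the reduction multiplier (pesos)."""

    giving_stake: int
    giving_coin: int = 1_000
    taking_coin: int = 500
    reduction_budget: int = 10_000
    token_cost: int = 1_000
    reduction_multiplier: int = 4

    def __post_init__(self) -> None:
        for name in (
            "giving_stake", "giving_coin", "taking_coin",
            "reduction_budget", "token_cost", "reduction_multiplier",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.giving_coin and self.giving_stake % self.giving_coin:
            raise ValidationError("giving_stake must be divisible by giving_coin")
        if self.token_cost and self.reduction_budget % self.token_cost:
            raise ValidationError("reduction_budget must be divisible by token_cost")

    @property
    def giving_coins(self) -> int:
        return self.giving_stake // self.giving_coin

    @property
    def reduction_tokens(self) -> int:
        return self.reduction_budget // self.token_cost


#: Printed per-site configurations.
COASTAL_CONFIG = GameConfig(giving_stake=15_000, reduction_budget=10_000)
INLAND_CONFIG = GameConfig(giving_stake=20_000, reduction_budget=15_000)


def taking_stake(n_targets: int, coin: int = 500) -> int:
    """Total pre-allocated taking-game endowment: one coin per target photo."""
    if n_targets < 0 or coin < 0:
        raise ValidationError("n_targets and coin must be non-negative")
    return n_targets * coin


def total_stake_per_person(config: GameConfig, n_targets: int) -> int:
    """Sum of the three per-person game stakes."""
    return config.giving_stake + taking_stake(n_targets, config.taking_coin) + (
        config.reduction_budget
    )


@dataclasses.dataclass
class GameSummary:
    mean: float
    median: float
    sd: float
    min: float
    max: float
    mean_percent: float
    median_percent: float

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def summarize_game(amounts, stake: float) -> GameSummary:
    """Descriptive statistics of per-focal amounts, plus percent-of-stake.

    Percentages are reported to one decimal using round-half-even; the raw
    statistics are kept at full precision.
    """
    x = np.asarray(amounts, dtype=float)
    if x.size == 0:
        raise ValidationError("no amounts to summarise")
    if (x < 0).any() or (x > stake).any():
        raise ValidationError("amounts must lie in [0, stake]")
    mean = float(x.mean())
    median = float(np.median(x))
    return GameSummary(
        mean=mean,
        median=median,
        sd=float(x.std(ddof=0)),
        min=float(x.min()),
        max=float(x.max()),
        mean_percent=percent_of_stake(mean, stake),
        median_percent=percent_of_stake(median, stake),
    )


def percent_of_stake(amount: float, stake: float) -> float:
    """Percentage of the stake, rounded half-even to one decimal."""
    if stake <= 0:
        raise ValidationError("stake must be positive")
    return float(np.round(100.0 * amount / stake, 1))


@dataclasses.dataclass
class PayoutLedger:
    """Per-individual totals (pesos) across the three games."""

    frame: pd.DataFrame  # one row per roster member

    def total_payout(self) -> float:
        return float(self.frame["final_payout"].sum())


def compute_payouts(
    roster: Roster,
    giving: AllocationSet,
    taking: BinaryLayer,
    reduction: AllocationSet,
    config: GameConfig,
    floor_at_zero: bool = False,
) -> PayoutLedger:
    """Full per-individual earnings ledger.

    final_payout_i = giving_coin * (self-kept + received giving coins)
                   + taking_coin * (coins i took + focals who left i's coin)
                   + (reduction_budget - token_cost * tokens i spent)
                   - token_cost * multiplier * (tokens targeting i)

    The taking layer codes 1 = the focal *left* the target's coin; a focal's
    take count is therefore the number of zero entries over their targets.
    Intermediate and final values may be negative unless ``floor_at_zero``.
    """
    n = len(roster)
    ids = roster.ids

    give_m = giving.count_matrix()  # (n_give_focals, n)
    give_idx = np.array([roster.index[i] for i in giving.focal_ids], dtype=int)
    kept = np.zeros(n)
    kept[give_idx] = give_m[np.arange(len(give_idx)), give_idx]
    given_to = give_m.sum(axis=0).astype(float)  # includes self-kept coins
    received = given_to - kept  # coins allocated to i by *others*... see below
    # received must exclude i's own self-kept coins but include coins from others
    recv_m = give_m.copy()
    recv_m[np.arange(len(give_idx)), give_idx] = 0
    received = recv_m.sum(axis=0).astype(float)

    take_idx = taking.focal_index
    adj = taking.adjacency.astype(float)
    n_targets = n - 1
    took = np.zeros(n)
    took[take_idx] = n_targets - adj[take_idx].sum(axis=1)
    left_for_me = adj[take_idx].sum(axis=0)  # per-column count of focals leaving

    red_m = reduction.count_matrix()
    red_idx = np.array([roster.index[i] for i in reduction.focal_ids], dtype=int)
    spent = np.zeros(n)
    tokens_spent = red_m.sum(axis=1) - red_m[np.arange(len(red_idx)), red_idx]
    spent[red_idx] = tokens_spent
    targeted = red_m.copy()
    targeted[np.arange(len(red_idx)), red_idx] = 0
    reduction_received = targeted.sum(axis=0).astype(float)

    is_give_focal = np.zeros(n, dtype=bool)
    is_give_focal[give_idx] = True
    is_take_focal = np.zeros(n, dtype=bool)
    is_take_focal[take_idx] = True
    is_red_focal = np.zeros(n, dtype=bool)
    is_red_focal[red_idx] = True

    final = (
        config.giving_coin * (kept + received)
        + config.taking_coin * (took + left_for_me)
        + np.where(is_red_focal, config.reduction_budget - config.token_cost * spent, 0.0)
        - config.token_cost * config.reduction_multiplier * reduction_received
    )
    if floor_at_zero:
        final = np.maximum(final, 0.0)
    frame = pd.DataFrame(
        {
            "id": ids,
            "kept_giving": config.giving_coin * kept,
            "received_giving": config.giving_coin * received,
            "taken_from_others": config.taking_coin * took,
            "left_for_me": config.taking_coin * left_for_me,
            "reduction_spent": config.token_cost * spent,
            "reduction_received": config.token_cost
            * config.reduction_multiplier
            * reduction_received,
            "final_payout": final,
        }
    )
    return PayoutLedger(frame)


def population_identity_residual(
    ledger: PayoutLedger,
    roster: Roster,
    giving: AllocationSet,
    taking: BinaryLayer,
    reduction: AllocationSet,
    config: GameConfig,
) -> float:
    """Total payout minus (total stakes - cost*(multiplier+1)*tokens). Zero
    for any valid play when payouts are not floored."""
    n_targets = len(roster) - 1
    stakes = (
        config.giving_stake * len(giving.focal_ids)
        + taking_stake(n_targets, config.taking_coin) * len(taking.focal_ids)
        + config.reduction_budget * len(reduction.focal_ids)
    )
    red_m = reduction.count_matrix()
    red_idx = np.array([roster.index[i] for i in reduction.focal_ids], dtype=int)
    tokens = int(red_m.sum() - red_m[np.arange(len(red_idx)), red_idx].sum())
    expected = stakes - config.token_cost * (config.reduction_multiplier + 1) * tokens
    return ledger.total_payout() - expected


def ingroup_outgroup_rates(taking: BinaryLayer, roster: Roster) -> pd.DataFrame:
    """Per-focal in-group and out-group coin-leaving rates.

    ``in_rate`` is the fraction of same-group targets whose coin the focal
    left; ``out_rate`` likewise over other-group targets.  A rate with no
    targets of that class is NaN (missing), never 0.  ``side`` classifies
    the focal relative to the diagonal: "out_group_favouring" if
    out_rate > in_rate, "in_group_favouring" if in_rate > out_rate, else
    "indiscriminate".
    """
    g = roster.group_array()
    adj = taking.adjacency
    rows = []
    for i in taking.focal_index:
        same = (g == g[i])
        same[i] = False
        other = ~(g == g[i])
        n_in, n_out = int(same.sum()), int(other.sum())
        in_rate = float(adj[i, same].sum() / n_in) if n_in else np.nan
        out_rate = float(adj[i, other].sum() / n_out) if n_out else np.nan
        if np.isnan(in_rate) or np.isnan(out_rate):
            side = "undefined"
        elif out_rate > in_rate:
            side = "out_group_favouring"
        elif in_rate > out_rate:
            side = "in_group_favouring"
        else:
            side = "indiscriminate"
        rows.append(
            {
                "id": roster.ids[i],
                "group": roster.groups[i],
                "in_rate": in_rate,
                "out_rate": out_rate,
                "side": side,
            }
        )
    return pd.DataFrame(rows)


def site_game_summaries(
    giving: AllocationSet,
    taking: BinaryLayer,
    reduction: AllocationSet,
    config: GameConfig,
    roster: Roster,
) -> pd.DataFrame:
    """Per-game descriptive summaries, one row per game x statistic.

    The summarised per-focal amounts follow the reporting conventions:

      * giving    — pesos given to others (stake minus pesos kept);
      * taking    — pesos left for targets (stake minus pesos taken);
      * reduction — pesos spent on reduction tokens.

    Each amount also carries its percent-of-stake.
    """
    give_m = giving.count_matrix()
    give_idx = np.array([roster.index[i] for i in giving.focal_ids], dtype=int)
    given_away = config.giving_coin * (
        give_m.sum(axis=1) - give_m[np.arange(len(give_idx)), give_idx]
    )
    adj = taking.adjacency
    left = config.taking_coin * adj[taking.focal_index].sum(axis=1)
    red_m = reduction.count_matrix()
    red_idx = np.array([roster.index[i] for i in reduction.focal_ids], dtype=int)
    spent = config.token_cost * (
        red_m.sum(axis=1) - red_m[np.arange(len(red_idx)), red_idx]
    )
    n_targets = len(roster) - 1
    stakes = {
        "giving": config.giving_stake,
        "taking": taking_stake(n_targets, config.taking_coin),
        "reduction": config.reduction_budget,
    }
    rows = []
    for game, amounts in (
        ("giving", given_away),
        ("taking", left),
        ("reduction", spent),
    ):
        summary = summarize_game(amounts, stakes[game])
        for stat, value in summary.to_dict().items():
            rows.append({"game": game, "statistic": stat, "value": value})
    return pd.DataFrame(rows)
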