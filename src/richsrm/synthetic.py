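"""Synthetic two-ethnicity community generator.

Emulates the statistical structure the analysis assumes for the two study
communities: a large Afrocolombian and a small Embera sub-community
(88 + 28 coastal, 130 + 21 inland), log-normal household wealth with a
between-group mean ratio of about 3.7, kinship confined to within-group
family clusters, predominantly within-ethnicity marriage, and five network
layers (friendship, double-reported food/money transfers, coin leaving in
the taking game, and multinomial giving and costly-reduction allocations)
drawn from the SRM generative process with configurable true parameters.

Everything is reproducible: a scenario plus a seed fully determines the
dataset, and writing the same site twice produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .network_data import (
    AllocationSet,
    BinaryLayer,
    DyadTable,
    Roster,
    Individual,
    ValidationError,
    build_dyad_table,
    load_allocations,
    load_dyads,
    load_layer,
    load_roster,
    merge_transfer_reports,
)
from .rich_games import COASTAL_CONFIG, INLAND_CONFIG, GameConfig
from .srm.design import build_design
from .srm.simulate import simulate_layer
from .srm.spec import (
    FULL_CONTROL_ALTER,
    FULL_CONTROL_DYAD,
    FULL_CONTROL_FOCAL,
    SRMParameters,
    SRMSpec,
)

LAYER_KINDS = {
    "friendship": "bernoulli",
    "transfer": "bernoulli",
    "taking_leave": "bernoulli",
    "giving": "multinomial",
    "reduction": "multinomial",
}


@dataclasses.dataclass
class SiteScenario:
    """Full generative recipe for one synthetic site.

    The wealth model is log-normal per group with the Afrocolombian /
    Embera *mean* ratio fixed at ``wealth_ratio`` in expectation; the
    within-group log-SDs are free parameters (wider at the coastal site,
    where the groups' wealth distributions overlap more).  Food insecurity
    is a 0-4 ordinal negatively correlated with log wealth.  ``layer_params``
    holds the true SRM parameters per layer (standardised covariate scale).
    """

    name: str
    site: str
    group_sizes: dict[str, int]
    wealth_ratio: float = 3.7
    wealth_base: float = 1_000_000.0  # median Embera household wealth, pesos
    wealth_log_sd: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"afro": 0.8, "embera": 0.8}
    )
    income_ratio: float = 1.8
    income_base: float = 300_000.0  # median Embera monthly income, pesos
    income_log_sd: float = 0.6
    food_wealth_corr: float = -0.5
    kin_cluster_mean_size: float = 4.0
    marriage_rate: float = 0.3  # fraction of adults with an in-sample spouse
    interethnic_marriage_rate: float = 0.02
    report_recall: float = 0.8  # per-direction name-generator recall
    n_noncompleters: int = 0
    game_config: GameConfig = dataclasses.field(default_factory=lambda: COASTAL_CONFIG)
    layer_params: dict[str, SRMParameters] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.group_sizes.values()):
            raise ValidationError("group sizes must be positive")
        if self.wealth_ratio <= 0 or self.income_ratio <= 0:
            raise ValidationError("wealth and income ratios must be positive")

    @property
    def n(self) -> int:
        return sum(self.group_sizes.values())


def coastal_like() -> SiteScenario:
    """Coastal-style site: 88 afro + 28 embera, anti-parochial Afrocolombian
    taking behaviour, wide within-group wealth overlap."""
    return SiteScenario(
        name="coastal_like",
        site="coastal",
        group_sizes={"afro": 88, "embera": 28},
        wealth_log_sd={"afro": 0.9, "embera": 0.9},
        income_ratio=1.8,
        n_noncompleters=22,
        game_config=COASTAL_CONFIG,
        layer_params={
            "friendship": SRMParameters(
                fixed={
                    "intercept": -3.5,
                    "parochial:afro": 1.2,
                    "parochial:embera": 1.2,
                    "alter:log_wealth": 0.2,
                    "dyad:relatedness": 0.8,
                    "dyad:marriage": 2.0,
                },
                sigma_s=0.7, sigma_r=0.7, rho_gr=0.3, sigma_d=1.0, rho_dd=0.5,
            ),
            "transfer": SRMParameters(
                fixed={
                    "intercept": -3.8,
                    "parochial:afro": 0.0,
                    "parochial:embera": 1.0,
                    "alter:log_wealth": 0.2,
                    "dyad:relatedness": 1.0,
                    "dyad:marriage": 2.0,
                },
                sigma_s=0.7, sigma_r=0.7, rho_gr=0.3, sigma_d=1.0, rho_dd=0.5,
            ),
            "taking_leave": SRMParameters(
                fixed={
                    "intercept": 0.9,
                    "parochial:afro": -0.5,
                    "parochial:embera": 0.8,
                    "alter:log_wealth": -0.4,
                    "alter:food_insecurity": 0.3,
                },
                sigma_s=0.8, sigma_r=0.3, rho_gr=0.2,
            ),
            "giving": SRMParameters(
                fixed={
                    "self_intercept": 4.2,
                    "parochial:afro": 0.8,
                    "parochial:embera": 0.8,
                    "alter:log_wealth": -0.3,
                },
                sigma_s=0.8, sigma_r=0.5,
            ),
            "reduction": SRMParameters(
                fixed={
                    "self_intercept": 6.5,
                    "parochial:afro": 0.0,
                    "parochial:embera": 0.0,
                    "alter:log_wealth": 0.3,
                },
                sigma_s=1.0, sigma_r=0.5,
            ),
        },
    )


def inland_like() -> SiteScenario:
    """Inland-style site: 130 afro + 21 embera, parochial taking and
    transfers for both groups, less within-group wealth overlap."""
    base = coastal_like()
    params = dict(base.layer_params)
    params["transfer"] = dataclasses.replace(
        params["transfer"],
        fixed={**dict(params["transfer"].fixed), "parochial:afro": 0.8},
    )
    params["taking_leave"] = dataclasses.replace(
        params["taking_leave"],
        fixed={
            **dict(params["taking_leave"].fixed),
            "parochial:afro": 0.6,
            "parochial:embera": 0.8,
            "intercept": -0.1,
        },
    )
    params["giving"] = dataclasses.replace(
        params["giving"],
        fixed={**dict(params["giving"].fixed), "self_intercept": 4.4},
    )
    params["reduction"] = dataclasses.replace(
        params["reduction"],
        fixed={**dict(params["reduction"].fixed), "self_intercept": 7.3},
    )
    return dataclasses.replace(
        base,
        name="inland_like",
        site="inland",
        group_sizes={"afro": 130, "embera": 21},
        wealth_log_sd={"afro": 0.5, "embera": 0.5},
        income_ratio=3.9,
        n_noncompleters=14,
        game_config=INLAND_CONFIG,
        layer_params=params,
    )


PRESETS = {"coastal_like": coastal_like, "inland_like": inland_like}


# --------------------------------------------------------------------------
# roster and dyads
# --------------------------------------------------------------------------

def generate_roster(scenario: SiteScenario, seed: int | np.random.Generator) -> Roster:
    """Draw a roster with the configured group sizes and covariates."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = sorted(scenario.group_sizes)
    ref = groups[-1]  # ratios are relative to the (last, smaller) group
    individuals: list[Individual] = []
    log_wealths = []
    prefix = scenario.site[0]
    k = 0
    for g in groups:
        n_g = scenario.group_sizes[g]
        sd_g = scenario.wealth_log_sd.get(g, 0.8)
        sd_ref = scenario.wealth_log_sd.get(ref, 0.8)
        # group mean ratio fixed in expectation: E[W] = exp(mu + sd^2/2)
        mu = np.log(scenario.wealth_base) + sd_ref**2 / 2 - sd_g**2 / 2
        if g != ref:
            mu += np.log(scenario.wealth_ratio)
        mu_inc = np.log(scenario.income_base)
        if g != ref:
            mu_inc += np.log(scenario.income_ratio)
        lw = mu + sd_g * rng.standard_normal(n_g)
        li = mu_inc + scenario.income_log_sd * rng.standard_normal(n_g)
        for w, inc in zip(lw, li):
            individuals.append(
                Individual(
                    id=f"{prefix}{k:03d}",
                    site=scenario.site,
                    group=g,
                    wealth=float(np.exp(w)),
                    income=float(np.exp(inc)),
                    food_insecurity=0.0,
                )
            )
            log_wealths.append(w)
            k += 1
    # food insecurity: 0-4 ordinal, negatively correlated with log wealth
    lw = np.asarray(log_wealths)
    z = (lw - lw.mean()) / lw.std()
    c = scenario.food_wealth_corr
    latent = c * z + np.sqrt(1.0 - c * c) * rng.standard_normal(len(z))
    cuts = np.quantile(latent, [0.2, 0.4, 0.6, 0.8])
    score = np.digitize(latent, cuts)
    for ind, f in zip(individuals, score):
        ind.food_insecurity = float(f)
    return Roster(individuals)


def generate_dyads(
    roster: Roster,
    scenario: SiteScenario,
    seed: int | np.random.Generator,
) -> tuple[DyadTable, dict]:
    """Kin clusters and marriages; returns the table plus bookkeeping.

    Each ethnic group is partitioned into family clusters; within a cluster
    a random pedigree tree assigns relatedness 0.5 / 0.25 / 0.125 by
    distance (floored at 0.125).  Marriages are sampled at
    ``marriage_rate`` with cross-ethnicity couples at
    ``interethnic_marriage_rate``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(roster)
    groups = roster.group_array()
    kin: dict[tuple[str, str], float] = {}
    n_kin_pairs = 0
    mean_size = scenario.kin_cluster_mean_size
    for g_code in np.unique(groups):
        members = list(np.nonzero(groups == g_code)[0])
        rng.shuffle(members)
        while members:
            if mean_size > 1:
                size = 1 + int(rng.geometric(1.0 / (mean_size - 1)))
            else:
                size = 1
            size = min(len(members), size)
            cluster = [members.pop() for _ in range(size)]
            if size == 1:
                continue
            # random pedigree tree: node t attaches to a uniform earlier node
            adj: dict[int, list[int]] = {t: [] for t in range(size)}
            for t in range(1, size):
                p = int(rng.integers(0, t))
                adj[p].append(t)
                adj[t].append(p)
            for a in range(size):
                # BFS distances from a on the tree
                seen = {a: 0}
                frontier = [a]
                while frontier:
                    nxt = []
                    for u in frontier:
                        for v in adj[u]:
                            if v not in seen:
                                seen[v] = seen[u] + 1
                                nxt.append(v)
                    frontier = nxt
                for b, d_ab in seen.items():
                    if b > a:
                        r = 0.5 ** min(int(d_ab), 3)
                        kin[(roster.ids[cluster[a]], roster.ids[cluster[b]])] = r
                        n_kin_pairs += 1
    # marriages
    n_couples = int(round(scenario.marriage_rate * n / 2))
    unmarried = set(range(n))
    marriages: list[tuple[str, str]] = []
    n_interethnic = 0
    group_codes = list(np.unique(groups))
    for _ in range(n_couples):
        cross = rng.uniform() < scenario.interethnic_marriage_rate
        if cross and len(group_codes) >= 2:
            picked = rng.choice(group_codes, size=2, replace=False)
            g1, g2 = int(picked[0]), int(picked[1])
        else:
            sizes = np.array([np.sum(groups == g) for g in group_codes], dtype=float)
            g1 = g2 = int(
                group_codes[int(rng.choice(len(group_codes), p=sizes / sizes.sum()))]
            )
        pool1 = [i for i in unmarried if groups[i] == g1]
        if not pool1:
            continue
        a = int(rng.choice(pool1))
        pool2 = [i for i in unmarried if groups[i] == g2 and i != a]
        if not pool2:
            continue
        b = int(rng.choice(pool2))
        unmarried.discard(a)
        unmarried.discard(b)
        marriages.append((roster.ids[a], roster.ids[b]))
        if groups[a] != groups[b]:
            n_interethnic += 1
    table = build_dyad_table(roster, kin, marriages)
    info = {
        "n_kin_unordered_pairs": n_kin_pairs,
        "kin_dyad_fraction": 2 * n_kin_pairs / (n * (n - 1)),
        "n_marriages": len(marriages),
        "n_interethnic_marriages": n_interethnic,
    }
    return table, info


# --------------------------------------------------------------------------
# full site
# --------------------------------------------------------------------------

@dataclasses.dataclass
class SiteData:
    scenario: SiteScenario
    roster: Roster
    dyads: DyadTable
    layers: dict[str, BinaryLayer]  # friendship, transfer (+ give/receive reports)
    allocations: dict[str, AllocationSet]  # giving, reduction
    completers: list[str]
    info: dict

    @property
    def game_config(self) -> GameConfig:
        return self.scenario.game_config


def _sim_spec(kind: str) -> SRMSpec:
    return SRMSpec(
        outcome_kind=kind,
        variant="full_controls",
        focal_covariates=FULL_CONTROL_FOCAL,
        alter_covariates=FULL_CONTROL_ALTER,
        dyad_covariates=FULL_CONTROL_DYAD,
        include_dyad_effects=False,  # simulation draws dyad effects directly
    )


def _thin(layer: BinaryLayer, recall: float, rng: np.random.Generator,
          name: str) -> BinaryLayer:
    keep = rng.uniform(size=layer.adjacency.shape) < recall
    adj = np.where(keep, layer.adjacency, 0).astype(np.int8)
    return BinaryLayer(name, layer.roster, adj, focal_ids=layer.focal_ids)


def generate_site(scenario: SiteScenario, seed: int) -> SiteData:
    """Roster, dyads and all five layers from the SRM generative process.

    Interview layers (friendship, transfers) treat every roster member as a
    focal; game layers only the completers.  The transfer layer is produced
    as a true tie set double-reported with per-direction recall and merged
    by union.
    """
    root = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(8)]
    roster = generate_roster(scenario, rngs[0])
    dyads, dyad_info = generate_dyads(roster, scenario, rngs[1])
    n = len(roster)
    completer_idx = np.sort(
        rngs[2].choice(n, size=n - scenario.n_noncompleters, replace=False)
    )
    completers = [roster.ids[i] for i in completer_idx]
    cfg = scenario.game_config

    layers: dict[str, BinaryLayer] = {}
    allocations: dict[str, AllocationSet] = {}

    # friendship: everyone focal
    p = scenario.layer_params["friendship"]
    design = build_design(_sim_spec("bernoulli"), roster, dyads)
    layers["friendship"] = simulate_layer(design, p, rngs[3], layer_name="friendship")

    # transfers: true layer + double reports merged by union
    p = scenario.layer_params["transfer"]
    design = build_design(_sim_spec("bernoulli"), roster, dyads)
    true_transfer = simulate_layer(design, p, rngs[4], layer_name="transfer")
    give_rep = _thin(true_transfer, scenario.report_recall, rngs[4], "transfer")
    recv_rep = _thin(true_transfer, scenario.report_recall, rngs[4], "transfer")
    layers["transfer_true"] = true_transfer
    layers["transfer_give_reports"] = give_rep
    layers["transfer_receive_reports"] = recv_rep
    layers["transfer"] = merge_transfer_reports(give_rep, recv_rep, rule="union")

    # taking game: completers focal
    p = scenario.layer_params["taking_leave"]
    design = build_design(_sim_spec("bernoulli"), roster, dyads, focal_ids=completers)
    layers["taking_leave"] = simulate_layer(design, p, rngs[5],
                                            layer_name="taking_leave")

    # giving and reduction games: multinomial allocations
    p = scenario.layer_params["giving"]
    design = build_design(_sim_spec("multinomial"), roster, dyads,
                          focal_ids=completers)
    allocations["giving"] = simulate_layer(
        design, p, rngs[6], layer_name="giving",
        budgets=cfg.giving_coins, coin_value=cfg.giving_coin,
    )
    p = scenario.layer_params["reduction"]
    design = build_design(_sim_spec("multinomial"), roster, dyads,
                          focal_ids=completers)
    allocations["reduction"] = simulate_layer(
        design, p, rngs[7], layer_name="reduction",
        budgets=cfg.reduction_tokens, coin_value=cfg.token_cost,
    )

    info = {"seed": seed, **dyad_info}
    return SiteData(
        scenario=scenario,
        roster=roster,
        dyads=dyads,
        layers=layers,
        allocations=allocations,
        completers=completers,
        info=info,
    )


# --------------------------------------------------------------------------
# serialisation
# --------------------------------------------------------------------------

def write_site(site: SiteData, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    site.roster.save(outdir / "roster.csv")
    site.dyads.save(outdir / "dyads.csv")
    for name in ("friendship", "transfer_give_reports", "transfer_receive_reports",
                 "taking_leave"):
        site.layers[name].save(outdir / f"layer_{name}.csv")
    for game, alloc in site.allocations.items():
        alloc.save(outdir / f"allocations_{game}.csv")
    (outdir / "completers.csv").write_text(
        "id\n" + "\n".join(site.completers) + "\n"
    )
    scenario_to_yaml(site.scenario, outdir / "scenario.yaml")
    cfg = site.game_config
    (outdir / "game_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    )


def load_site(datadir: str | Path) -> SiteData:
    """Reload a written site (reconstructing the merged transfer layer)."""
    datadir = Path(datadir)
    scenario = scenario_from_yaml(datadir / "scenario.yaml")
    roster = load_roster(datadir / "roster.csv")
    dyads = load_dyads(datadir / "dyads.csv", roster)
    completers = [
        line.strip()
        for line in (datadir / "completers.csv").read_text().splitlines()[1:]
        if line.strip()
    ]
    cfg_d = yaml.safe_load((datadir / "game_config.yaml").read_text())
    cfg = GameConfig(**cfg_d)
    layers = {
        "friendship": load_layer(datadir / "layer_friendship.csv", roster,
                                 "friendship"),
        "transfer_give_reports": load_layer(
            datadir / "layer_transfer_give_reports.csv", roster, "transfer"
        ),
        "transfer_receive_reports": load_layer(
            datadir / "layer_transfer_receive_reports.csv", roster, "transfer"
        ),
        "taking_leave": load_layer(
            datadir / "layer_taking_leave.csv", roster, "taking_leave",
            focal_ids=completers,
        ),
    }
    layers["transfer"] = merge_transfer_reports(
        layers["transfer_give_reports"], layers["transfer_receive_reports"], "union"
    )
    allocations = {
        "giving": load_allocations(
            datadir / "allocations_giving.csv", roster, "giving",
            budget=cfg.giving_coins, coin_value=cfg.giving_coin,
            focal_ids=completers,
        ),
        "reduction": load_allocations(
            datadir / "allocations_reduction.csv", roster, "reduction",
            budget=cfg.reduction_tokens, coin_value=cfg.token_cost,
            focal_ids=completers,
        ),
    }
    scenario = dataclasses.replace(scenario, game_config=cfg)
    return SiteData(
        scenario=scenario,
        roster=roster,
        dyads=dyads,
        layers=layers,
        allocations=allocations,
        completers=completers,
        info={},
    )


def scenario_to_dict(scenario: SiteScenario) -> dict:
    d = dataclasses.asdict(scenario)
    d["layer_params"] = {
        name: {
            "fixed": dict(p.fixed),
            "sigma_s": p.sigma_s,
            "sigma_r": p.sigma_r,
            "sigma_d": p.sigma_d,
            "rho_gr": p.rho_gr,
            "rho_dd": p.rho_dd,
        }
        for name, p in scenario.layer_params.items()
    }
    return d


def scenario_from_dict(d: dict) -> SiteScenario:
    d = dict(d)
    d["layer_params"] = {
        name: SRMParameters(**pd) for name, pd in d.get("layer_params", {}).items()
    }
    if "game_config" in d and isinstance(d["game_config"], dict):
        d["game_config"] = GameConfig(**d["game_config"])
    return SiteScenario(**d)


def scenario_to_yaml(scenario: SiteScenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=True))


def scenario_from_yaml(path: str | Path) -> SiteScenario:
    return scenario_from_dict(yaml.safe_load(Path(path).read_text()))
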