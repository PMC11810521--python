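"""Data model, validation and I/O for rosters, dyads and multi-layer networks.

The analysis operates on a near-complete census of a community: a *roster*
of individuals (with ethnic-group labels and household covariates), a table
of dyadic covariates (genetic relatedness, marriage), and several directed
network layers — interview-elicited friendship and food/money-transfer ties,
and the outcomes of photo-roster economic games.

All files are comma-delimited UTF-8 with a header row.  Network layers are
stored long-form (``focal_id,alter_id,value``); absent pairs are zeros.
The roster file order is canonical: it fixes the row/column order of every
adjacency matrix derived from it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

SITES = ("coastal", "inland")
BINARY_LAYERS = ("friendship", "transfer", "taking_leave")
GAMES = ("giving", "reduction")

ROSTER_COLUMNS = ["id", "site", "group", "wealth", "income", "food_insecurity"]


class ValidationError(ValueError):
    """Raised when an input file or structure violates a data invariant."""


@dataclasses.dataclass
class Individual:
    """One adult on the photo roster.

    ``wealth`` is household material wealth in pesos and must be strictly
    positive so that log-wealth is defined.  ``extra`` holds any additional
    numeric controls.
    """

    id: str
    site: str
    group: str
    wealth: float
    income: float
    food_insecurity: float
    extra: dict[str, float] = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        if self.site not in SITES:
            raise ValidationError(
                f"individual {self.id!r}: unknown site {self.site!r} "
                f"(expected one of {SITES})"
            )
        if not self.wealth > 0:
            raise ValidationError(
                f"individual {self.id!r}: wealth must be strictly positive, "
                f"got {self.wealth}"
            )
        if self.income < 0:
            raise ValidationError(
                f"individual {self.id!r}: income must be >= 0, got {self.income}"
            )
        if self.food_insecurity < 0:
            raise ValidationError(
                f"individual {self.id!r}: food_insecurity must be >= 0, "
                f"got {self.food_insecurity}"
            )


class Roster:
    """Ordered collection of individuals at one site.

    The order of ``individuals`` is canonical and defines matrix row/column
    order for every layer over this roster.
    """

    def __init__(self, individuals: Iterable[Individual], site: str | None = None):
        self.individuals: list[Individual] = list(individuals)
        if len(self.individuals) < 2:
            raise ValidationError("a roster needs at least 2 individuals")
        seen: set[str] = set()
        for ind in self.individuals:
            ind.validate()
            if ind.id in seen:
                raise ValidationError(f"duplicate id {ind.id!r} in roster")
            seen.add(ind.id)
        sites = {ind.site for ind in self.individuals}
        if len(sites) > 1:
            raise ValidationError(f"roster mixes sites: {sorted(sites)}")
        self.site = site or self.individuals[0].site
        self.ids: list[str] = [ind.id for ind in self.individuals]
        self.index: dict[str, int] = {i: k for k, i in enumerate(self.ids)}
        self.groups: list[str] = [ind.group for ind in self.individuals]
        self.group_labels: list[str] = sorted(set(self.groups))

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def group_array(self) -> np.ndarray:
        """Integer group codes in roster order (codes index group_labels)."""
        code = {g: k for k, g in enumerate(self.group_labels)}
        return np.array([code[g] for g in self.groups], dtype=int)

    def covariate(self, name: str) -> np.ndarray:
        """Numeric covariate vector in roster order.

        ``log_wealth`` is available as a derived covariate; other names are
        looked up on the Individual fields and then in ``extra``.
        """
        if name == "log_wealth":
            return np.log([ind.wealth for ind in self.individuals])
        out = []
        for ind in self.individuals:
            if hasattr(ind, name):
                out.append(float(getattr(ind, name)))
            elif name in ind.extra:
                out.append(float(ind.extra[name]))
            else:
                raise KeyError(f"unknown covariate {name!r} (individual {ind.id!r})")
        return np.asarray(out, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        extra_keys = sorted({k for ind in self.individuals for k in ind.extra})
        rows = []
        for ind in self.individuals:
            row = {
                "id": ind.id,
                "site": ind.site,
                "group": ind.group,
                "wealth": ind.wealth,
                "income": ind.income,
                "food_insecurity": ind.food_insecurity,
            }
            for k in extra_keys:
                row[k] = ind.extra.get(k, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_roster(path: str | Path) -> Roster:
    """Read a roster CSV; the file order becomes the canonical order."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing roster columns {missing}")
    extra_cols = [c for c in df.columns if c not in ROSTER_COLUMNS]
    individuals = []
    for _, row in df.iterrows():
        extra = {c: float(row[c]) for c in extra_cols if pd.notna(row[c])}
        individuals.append(
            Individual(
                id=str(row["id"]),
                site=str(row["site"]),
                group=str(row["group"]),
                wealth=float(row["wealth"]),
                income=float(row["income"]),
                food_insecurity=float(row["food_insecurity"]),
                extra=extra,
            )
        )
    return Roster(individuals)


class DyadTable:
    """Covariates for every ordered pair of distinct roster members.

    Internally stores symmetric n x n matrices for relatedness and marriage
    (diagonal zero, ignored) plus the derived same-group indicator.
    """

    def __init__(self, roster: Roster, relatedness: np.ndarray, marriage: np.ndarray):
        n = len(roster)
        relatedness = np.asarray(relatedness, dtype=float)
        marriage = np.asarray(marriage, dtype=float)
        for name, m in (("relatedness", relatedness), ("marriage", marriage)):
            if m.shape != (n, n):
                raise ValidationError(f"{name} matrix must be {n}x{n}, got {m.shape}")
            if not np.allclose(m, m.T):
                raise ValidationError(f"{name} must be symmetric")
        if relatedness.min() < 0 or relatedness.max() > 1:
            raise ValidationError("relatedness must lie in [0, 1]")
        if not np.isin(marriage[~np.eye(n, dtype=bool)], (0.0, 1.0)).all():
            raise ValidationError("marriage must be 0/1")
        self.roster = roster
        self.relatedness = relatedness.copy()
        self.marriage = marriage.copy()
        np.fill_diagonal(self.relatedness, 0.0)
        np.fill_diagonal(self.marriage, 0.0)
        g = roster.group_array()
        self.same_group = (g[:, None] == g[None, :]).astype(float)
        np.fill_diagonal(self.same_group, 0.0)

    def __len__(self) -> int:
        n = len(self.roster)
        return n * (n - 1)

    def matrix(self, name: str) -> np.ndarray:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown dyad covariate {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        ids = self.roster.ids
        n = len(ids)
        focal, alter = np.nonzero(~np.eye(n, dtype=bool))
        return pd.DataFrame(
            {
                "focal_id": [ids[i] for i in focal],
                "alter_id": [ids[j] for j in alter],
                "relatedness": self.relatedness[focal, alter],
                "marriage": self.marriage[focal, alter].astype(int),
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_dyad_table(
    roster: Roster,
    kin: Mapping[tuple[str, str], float] | None = None,
    marriages: Iterable[tuple[str, str]] | None = None,
) -> DyadTable:
    """Assemble a DyadTable from sparse kin/marriage inputs.

    Unsupplied relatedness defaults to 0.  If both (a, b) and (b, a) appear
    in ``kin`` with different values that is an error — no silent averaging.
    """
    n = len(roster)
    idx = roster.index
    rel = np.zeros((n, n))
    if kin:
        seen: dict[frozenset, float] = {}
        for (a, b), r in kin.items():
            for x in (a, b):
                if x not in idx:
                    raise ValidationError(f"kin pair references unknown id {x!r}")
            if a == b:
                raise ValidationError(f"self-pair in kin map: {a!r}")
            key = frozenset((a, b))
            if key in seen and not np.isclose(seen[key], float(r)):
                raise ValidationError(
                    f"asymmetric relatedness for pair ({a!r}, {b!r}): "
                    f"{seen[key]} vs {r}"
                )
            seen[key] = float(r)
            rel[idx[a], idx[b]] = rel[idx[b], idx[a]] = float(r)
    mar = np.zeros((n, n))
    if marriages:
        for a, b in marriages:
            for x in (a, b):
                if x not in idx:
                    raise ValidationError(f"marriage references unknown id {x!r}")
            if a == b:
                raise ValidationError(f"self-marriage: {a!r}")
            mar[idx[a], idx[b]] = mar[idx[b], idx[a]] = 1.0
    return DyadTable(roster, rel, mar)


def load_dyads(path: str | Path, roster: Roster) -> DyadTable:
    """Read a long-form dyad CSV (focal_id, alter_id, relatedness, marriage)."""
    df = pd.read_csv(path, dtype={"focal_id": str, "alter_id": str})
    kin: dict[tuple[str, str], float] = {}
    marriages = []
    for _, row in df.iterrows():
        a, b = str(row["focal_id"]), str(row["alter_id"])
        r = float(row.get("relatedness", 0.0))
        if r != 0.0:
            prev = kin.get((b, a))
            if prev is not None and not np.isclose(prev, r):
                raise ValidationError(
                    f"{path}: asymmetric relatedness for ({a!r}, {b!r})"
                )
            kin[(a, b)] = r
        if int(row.get("marriage", 0)):
            marriages.append((a, b))
    return build_dyad_table(roster, kin, marriages)


class BinaryLayer:
    """A directed 0/1 network layer aligned to a roster.

    For ``taking_leave`` a value of 1 means the focal *left* the alter's
    pre-allocated coin (so positive model coefficients mean less
    exploitation).  ``focal_ids`` restricts which rows carry observations
    (non-completers appear only as alters); it defaults to the full roster.
    """

    def __init__(
        self,
        name: str,
        roster: Roster,
        adjacency: np.ndarray,
        focal_ids: list[str] | None = None,
        provenance: np.ndarray | None = None,
    ):
        n = len(roster)
        adjacency = np.asarray(adjacency)
        if adjacency.shape != (n, n):
            raise ValidationError(f"adjacency must be {n}x{n}, got {adjacency.shape}")
        if not np.isin(adjacency, (0, 1)).all():
            raise ValidationError("layer values must be 0 or 1")
        if np.diag(adjacency).any():
            raise ValidationError("self-edges are not allowed")
        self.name = name
        self.roster = roster
        self.adjacency = adjacency.astype(np.int8)
        self.focal_ids = list(focal_ids) if focal_ids is not None else list(roster.ids)
        unknown = set(self.focal_ids) - set(roster.ids)
        if unknown:
            raise ValidationError(f"focal ids not in roster: {sorted(unknown)}")
        self.provenance = provenance

    @property
    def focal_index(self) -> np.ndarray:
        return np.array([self.roster.index[i] for i in self.focal_ids], dtype=int)

    def edge_count(self) -> int:
        return int(self.adjacency[self.focal_index].sum())

    def to_frame(self, include_zeros: bool = False) -> pd.DataFrame:
        ids = self.roster.ids
        rows = []
        for i in self.focal_index:
            for j in range(len(ids)):
                if i == j:
                    continue
                v = int(self.adjacency[i, j])
                if v or include_zeros:
                    rows.append((ids[i], ids[j], v))
        return pd.DataFrame(rows, columns=["focal_id", "alter_id", "value"])

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_graphml(self, path: str | Path) -> None:
        """Export as GraphML with group attributes, for visualisation."""
        g = nx.DiGraph()
        for ind in self.roster:
            g.add_node(ind.id, group=ind.group)
        for _, row in self.to_frame().iterrows():
            g.add_edge(row["focal_id"], row["alter_id"])
        nx.write_graphml(g, path)


def load_layer(
    path: str | Path,
    roster: Roster,
    layer_name: str,
    focal_ids: list[str] | None = None,
) -> BinaryLayer:
    """Read a long-form edge list; missing pairs are filled as 0."""
    df = pd.read_csv(path, dtype={"focal_id": str, "alter_id": str})
    n = len(roster)
    adj = np.zeros((n, n), dtype=np.int8)
    for _, row in df.iterrows():
        a, b = str(row["focal_id"]), str(row["alter_id"])
        for x in (a, b):
            if x not in roster.index:
                raise ValidationError(f"{path}: unknown id {x!r}")
        if a == b:
            raise ValidationError(f"{path}: self-edge on {a!r}")
        v = int(row["value"])
        if v not in (0, 1):
            raise ValidationError(f"{path}: value {v} outside {{0,1}} for ({a},{b})")
        adj[roster.index[a], roster.index[b]] = v
    return BinaryLayer(layer_name, roster, adj, focal_ids=focal_ids)


def merge_transfer_reports(
    give_reports: BinaryLayer,
    receive_reports: BinaryLayer,
    rule: str = "union",
) -> BinaryLayer:
    """Combine double-sampled transfer reports into one giving layer.

    ``receive_reports`` must already be oriented so an edge i -> j means
    "i gave to j" (i.e. the receiver's nomination has been transposed by the
    caller or loader).  ``union`` (default) keeps a tie named by either
    party; ``intersection`` requires both.
    """
    if give_reports.roster is not receive_reports.roster and (
        give_reports.roster.ids != receive_reports.roster.ids
    ):
        raise ValidationError("transfer report layers are over different rosters")
    if rule == "union":
        adj = give_reports.adjacency | receive_reports.adjacency
    elif rule == "intersection":
        adj = give_reports.adjacency & receive_reports.adjacency
    else:
        raise ValueError(f"unknown merge rule {rule!r}")
    prov = np.where(
        give_reports.adjacency & receive_reports.adjacency,
        3,  # both
        np.where(give_reports.adjacency, 1, np.where(receive_reports.adjacency, 2, 0)),
    )
    return BinaryLayer(
        "transfer",
        give_reports.roster,
        adj,
        focal_ids=give_reports.focal_ids,
        provenance=prov,
    )


@dataclasses.dataclass
class AllocationRecord:
    """One focal's allocation of a game budget over {self} and all alters."""

    game: str
    focal_id: str
    counts: dict[str, int]
    budget: int
    coin_value: int

    def validate(self, roster: Roster) -> None:
        if self.focal_id not in roster.index:
            raise ValidationError(f"unknown focal id {self.focal_id!r}")
        unknown = set(self.counts) - set(roster.ids)
        if unknown:
            raise ValidationError(
                f"allocation by {self.focal_id!r} targets unknown ids "
                f"{sorted(unknown)}"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError(f"negative count in allocation by {self.focal_id!r}")
        total = sum(self.counts.values())
        if total != self.budget:
            raise ValidationError(
                f"allocation by {self.focal_id!r} sums to {total}, "
                f"budget is {self.budget}"
            )

    def self_count(self) -> int:
        return self.counts.get(self.focal_id, 0)


class AllocationSet:
    """All focals' allocation records for one game, matrix-accessible.

    The count matrix is (n_focal x n_roster); a focal's own column holds the
    self-kept count.
    """

    def __init__(self, game: str, roster: Roster, records: Iterable[AllocationRecord]):
        self.game = game
        self.roster = roster
        self.records: list[AllocationRecord] = list(records)
        seen = set()
        for rec in self.records:
            rec.validate(roster)
            if rec.game != game:
                raise ValidationError(
                    f"record for game {rec.game!r} in {game!r} AllocationSet"
                )
            if rec.focal_id in seen:
                raise ValidationError(f"duplicate allocation record {rec.focal_id!r}")
            seen.add(rec.focal_id)
        self.focal_ids = [rec.focal_id for rec in self.records]

    def count_matrix(self) -> np.ndarray:
        n = len(self.roster)
        m = np.zeros((len(self.records), n), dtype=int)
        for k, rec in enumerate(self.records):
            for tid, c in rec.counts.items():
                m[k, self.roster.index[tid]] = c
        return m

    def budgets(self) -> np.ndarray:
        return np.array([rec.budget for rec in self.records], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for tid, c in sorted(rec.counts.items()):
                if c:
                    rows.append((rec.focal_id, tid, c))
        return pd.DataFrame(rows, columns=["focal_id", "target_id", "count"])

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_allocations(
    path: str | Path,
    roster: Roster,
    game: str,
    budget: int,
    coin_value: int,
    focal_ids: list[str] | None = None,
) -> AllocationSet:
    """Read long-form allocation records (focal_id, target_id, count).

    Unlisted focal/target combinations count 0; any shortfall against the
    budget is assigned to the focal's self-kept cell only if the file omits
    a self row entirely — otherwise the records must sum to the budget.
    """
    df = pd.read_csv(path, dtype={"focal_id": str, "target_id": str})
    per_focal: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        per_focal.setdefault(str(row["focal_id"]), {})[str(row["target_id"])] = int(
            row["count"]
        )
    if focal_ids is None:
        focal_ids = [i for i in roster.ids if i in per_focal]
    records = []
    for fid in focal_ids:
        counts = per_focal.get(fid, {})
        if fid not in counts:
            shortfall = budget - sum(counts.values())
            if shortfall < 0:
                raise ValidationError(
                    f"{path}: allocations by {fid!r} exceed budget {budget}"
                )
            counts = dict(counts)
            counts[fid] = shortfall
        records.append(
            AllocationRecord(
                game=game, focal_id=fid, counts=counts, budget=budget,
                coin_value=coin_value,
            )
        )
    return AllocationSet(game, roster, records)
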