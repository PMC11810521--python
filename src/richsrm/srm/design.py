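"""Design construction and covariate standardisation for SRM fits.

Continuous covariates are centred and scaled to unit SD (wealth is
log-transformed first); binary indicators (marriage, group dummies) are left
as 0/1.  The scaling record is retained so coefficients can be mapped back
to natural units.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..network_data import DyadTable, Roster, ValidationError
from .spec import SRMSpec

#: covariates treated as binary indicators (never rescaled)
BINARY_COVARIATES = {"marriage"}


@dataclasses.dataclass
class ScalingRecord:
    """Per-covariate (mean, sd) used for standardisation; identity for
    binary indicators."""

    scales: dict[str, tuple[float, float]]

    def transform(self, name: str, x: np.ndarray) -> np.ndarray:
        mean, sd = self.scales[name]
        return (x - mean) / sd

    def inverse_coefficient(self, name: str, beta_std: float) -> float:
        """Coefficient per natural unit from a standardised coefficient."""
        _, sd = self.scales[name]
        return beta_std / sd


def standardize(values: np.ndarray, name: str) -> tuple[np.ndarray, tuple[float, float]]:
    """Centre/scale a continuous covariate; error on zero variance."""
    x = np.asarray(values, dtype=float)
    sd = float(x.std(ddof=0))
    if sd == 0.0:
        raise ValidationError(f"covariate {name!r} has zero variance")
    if name in BINARY_COVARIATES or _is_binary(x):
        return x, (0.0, 1.0)
    mean = float(x.mean())
    return (x - mean) / sd, (mean, sd)


def _is_binary(x: np.ndarray) -> bool:
    return np.isin(x, (0.0, 1.0)).all()


class SRMDesign:
    """Precomputed design tensors for one SRM fit.

    ``X`` is a (p, n_f, n) stack of dyad-cell covariate matrices (rows =
    focals, columns = all roster members) with names ``x_names``.  For the
    multinomial family there is additionally a self-cell design ``S`` of
    shape (p_self, n_f) with names ``s_names``; the focal's own column in
    the dyad-cell grid is reused as the self/keep category.  ``mask`` is
    True on valid alter cells (self cells excluded).
    """

    def __init__(
        self,
        spec: SRMSpec,
        roster: Roster,
        dyads: DyadTable,
        focal_ids: list[str] | None = None,
    ):
        self.spec = spec
        self.roster = roster
        self.dyads = dyads
        self.focal_ids = list(focal_ids) if focal_ids is not None else list(roster.ids)
        unknown = set(self.focal_ids) - set(roster.ids)
        if unknown:
            raise ValidationError(f"focal ids not in roster: {sorted(unknown)}")
        self.n = len(roster)
        self.n_f = len(self.focal_ids)
        self.focal_idx = np.array([roster.index[i] for i in self.focal_ids], dtype=int)
        if spec.include_dyad_effects and self.n_f != self.n:
            raise ValidationError(
                "dyad random effects need both directions of every pair: "
                "the focal set must equal the roster"
            )

        self.groups = roster.group_array()
        self.group_labels = roster.group_labels
        self.ref_group = self.group_labels[0]

        self.mask = np.ones((self.n_f, self.n), dtype=bool)
        self.mask[np.arange(self.n_f), self.focal_idx] = False

        scales: dict[str, tuple[float, float]] = {}
        x_mats: list[np.ndarray] = []
        x_names: list[str] = []
        s_rows: list[np.ndarray] = []
        s_names: list[str] = []
        ones_cell = np.ones((self.n_f, self.n))

        multinomial = spec.outcome_kind == "multinomial"
        if multinomial:
            s_rows.append(np.ones(self.n_f))
            s_names.append("self_intercept")
        elif not spec.block_parameterisation:
            # the block parameterisation saturates the group-by-group cells,
            # so a separate intercept would be redundant
            x_mats.append(ones_cell)
            x_names.append("intercept")

        # ethnicity main effects (reference group omitted)
        focal_groups = self.groups[self.focal_idx]
        if not spec.block_parameterisation:
            for g_code, g in enumerate(self.group_labels):
                if g == self.ref_group:
                    continue
                f_ind = (focal_groups == g_code).astype(float)
                a_ind = (self.groups == g_code).astype(float)
                if multinomial:
                    s_rows.append(f_ind)
                    s_names.append(f"self_group:{g}")
                else:
                    x_mats.append(np.repeat(f_ind[:, None], self.n, axis=1))
                    x_names.append(f"focal_group:{g}")
                x_mats.append(np.repeat(a_ind[None, :], self.n_f, axis=0))
                x_names.append(f"alter_group:{g}")
            if spec.parochial_terms:
                for g_code, g in enumerate(self.group_labels):
                    same = (focal_groups[:, None] == g_code) & (
                        self.groups[None, :] == g_code
                    )
                    x_mats.append(same.astype(float))
                    x_names.append(f"parochial:{g}")
        else:
            for gi_code, gi in enumerate(self.group_labels):
                for gj_code, gj in enumerate(self.group_labels):
                    cell = (focal_groups[:, None] == gi_code) & (
                        self.groups[None, :] == gj_code
                    )
                    x_mats.append(cell.astype(float))
                    x_names.append(f"block:{gi}->{gj}")

        for name in spec.focal_covariates:
            z, scale = standardize(roster.covariate(name), name)
            scales[f"focal:{name}"] = scale
            zf = z[self.focal_idx]
            if multinomial:
                s_rows.append(zf)
                s_names.append(f"self:{name}")
            else:
                x_mats.append(np.repeat(zf[:, None], self.n, axis=1))
                x_names.append(f"focal:{name}")
        for name in spec.alter_covariates:
            z, scale = standardize(roster.covariate(name), name)
            scales[f"alter:{name}"] = scale
            x_mats.append(np.repeat(z[None, :], self.n_f, axis=0))
            x_names.append(f"alter:{name}")
        for name in spec.dyad_covariates:
            w = dyads.matrix(name)[self.focal_idx, :]
            flat, scale = standardize(w[self.mask], name)
            scales[f"dyad:{name}"] = scale
            w_std = np.zeros_like(w, dtype=float)
            w_std[self.mask] = flat
            x_mats.append(w_std)
            x_names.append(f"dyad:{name}")

        self.X = np.stack(x_mats) if x_mats else np.zeros((0, self.n_f, self.n))
        self.x_names = x_names
        if multinomial:
            self.S = np.stack(s_rows)
            self.s_names = s_names
        else:
            self.S = np.zeros((0, self.n_f))
            self.s_names = []
        # zero out self cells of dyad-cell design (they are never alter cells)
        self.X[:, ~self.mask] = 0.0
        self.scaling = ScalingRecord(scales)

        # unordered pairs for dyad random effects (only when n_f == n)
        if spec.include_dyad_effects:
            iu, ju = np.triu_indices(self.n, k=1)
            self.pair_i = iu
            self.pair_j = ju
        else:
            self.pair_i = self.pair_j = np.zeros(0, dtype=int)

        # which roster positions are focals (for the sender/receiver block)
        self.is_focal = np.zeros(self.n, dtype=bool)
        self.is_focal[self.focal_idx] = True

    @property
    def param_names(self) -> list[str]:
        return self.s_names + self.x_names

    def fixed_vector(self, fixed: dict[str, float] | None) -> tuple[np.ndarray, np.ndarray]:
        """(beta_self, beta) vectors from a name->value mapping."""
        fixed = fixed or {}
        unknown = set(fixed) - set(self.param_names)
        if unknown:
            raise ValidationError(
                f"fixed effects not in design: {sorted(unknown)}; "
                f"available: {self.param_names}"
            )
        beta_self = np.array([fixed.get(n, 0.0) for n in self.s_names], dtype=float)
        beta = np.array([fixed.get(n, 0.0) for n in self.x_names], dtype=float)
        return beta_self, beta


def build_design(
    spec: SRMSpec,
    roster: Roster,
    dyads: DyadTable,
    focal_ids: list[str] | None = None,
) -> SRMDesign:
    return SRMDesign(spec, roster, dyads, focal_ids=focal_ids)
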