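"""Fitting, posterior summaries, parochialism contrasts and diagnostics."""

from __future__ import annotations

import dataclasses
import warnings

import arviz as az
import numpy as np
import pandas as pd

from ..network_data import ValidationError
from . import hmc
from .design import SRMDesign, build_design
from .model import SRMModel
from .spec import SRMSpec


@dataclasses.dataclass
class SRMPosterior:
    """Posterior draws of the reported SRM parameters.

    ``draws`` maps parameter name -> array of shape (chains, samples) on the
    natural scale (sigmas positive, correlations in [-1, 1]).  Summaries
    (median and the 90% credible interval used to flag reliable effects) are
    recomputed from the draws on demand.
    """

    spec: SRMSpec
    design: SRMDesign
    draws: dict[str, np.ndarray]
    divergences: int
    accept_rate: float
    seed: int

    @property
    def chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def summary(self) -> pd.DataFrame:
        """Median, 90% interval and reliable-effect flag per parameter."""
        rows = []
        for name, d in self.draws.items():
            flat = d.reshape(-1)
            q05, med, q95 = np.quantile(flat, [0.05, 0.5, 0.95])
            rows.append(
                {
                    "parameter": name,
                    "median": med,
                    "q05": q05,
                    "q95": q95,
                    "reliable": bool(q05 > 0 or q95 < 0),
                    "self_category": name.startswith("self"),
                }
            )
        return pd.DataFrame(rows)

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict({k: v for k, v in self.draws.items()})

    def diagnostics(self) -> pd.DataFrame:
        return diagnostics(self)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form draws (chain, iteration, parameter, value)."""
        rows = []
        for name, d in self.draws.items():
            for c in range(d.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(d.shape[1]),
                            "parameter": name,
                            "value": d[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def fit(
    spec: SRMSpec,
    roster,
    dyads,
    outcome,
    focal_ids: list[str] | None = None,
) -> SRMPosterior:
    """Fit the SRM by HMC and return the posterior of reported parameters.

    ``outcome`` is a BinaryLayer (bernoulli) or AllocationSet (multinomial);
    its focal set determines which roster members contribute focal rows.
    Convergence problems are flagged, never hidden: divergent transitions
    raise a warning with the count, and ``diagnostics`` reports split-Rhat
    and bulk ESS per parameter.
    """
    if focal_ids is None:
        focal_ids = list(outcome.focal_ids)
    design = build_design(spec, roster, dyads, focal_ids=focal_ids)
    model = SRMModel(design, outcome)
    layout = model.layout
    mc = spec.mcmc

    def init(rng: np.random.Generator) -> np.ndarray:
        x = 0.1 * rng.standard_normal(layout.size)
        # start scales small so early trajectories stay stable
        for name in ("log_sigma_s", "log_sigma_r", "log_sigma_d"):
            if name in layout.slices:
                x[layout.slices[name]] = np.log(0.3) + 0.1 * rng.standard_normal()
        return x

    results = hmc.sample(
        model.logp_and_grad,
        init,
        chains=mc.chains,
        n_warmup=mc.warmup,
        n_samples=mc.samples,
        seed=mc.seed,
        target_accept=mc.target_accept,
        max_leapfrog=mc.max_leapfrog,
        trajectory_length=mc.trajectory_length,
    )
    raw = np.stack([r.draws for r in results])  # (chains, samples, dim)
    divergences = sum(r.divergences for r in results)
    accept = float(np.mean([r.accept_rate for r in results]))
    if divergences > 0:
        warnings.warn(
            f"{divergences} divergent transitions during sampling", RuntimeWarning
        )

    draws: dict[str, np.ndarray] = {}
    for k, name in enumerate(design.s_names):
        draws[name] = raw[:, :, layout.slices["beta_self"]][:, :, k]
    for k, name in enumerate(design.x_names):
        draws[name] = raw[:, :, layout.slices["beta"]][:, :, k]
    draws["sigma_s"] = np.exp(raw[:, :, layout.slices["log_sigma_s"]][:, :, 0])
    draws["sigma_r"] = np.exp(raw[:, :, layout.slices["log_sigma_r"]][:, :, 0])
    draws["rho_gr"] = np.tanh(raw[:, :, layout.slices["u_gr"]][:, :, 0])
    if spec.include_dyad_effects:
        draws["sigma_d"] = np.exp(raw[:, :, layout.slices["log_sigma_d"]][:, :, 0])
        draws["rho_dd"] = np.tanh(raw[:, :, layout.slices["u_dd"]][:, :, 0])

    return SRMPosterior(
        spec=spec,
        design=design,
        draws=draws,
        divergences=divergences,
        accept_rate=accept,
        seed=mc.seed,
    )


def extract_parochial_contrasts(posterior: SRMPosterior, groups=None) -> pd.DataFrame:
    """Per-group in-group bonus: median, 90% interval, reliability, sign.

    The contrast reported for group g is the identified quantity
    ``score(g -> g) - mean over h != g of score(g -> h)`` at a fixed focal:
    the same-group bonus net of alter-ethnicity main effects.  (The raw
    ``parochial:<g>`` coefficient alone is not identified — the cell-mean
    parameterisation has a flat direction that only the priors resolve —
    so it is combined with the ``alter_group:<g>`` draws.)  Under the block
    parameterisation the contrast is ``block:g->g`` minus the mean of
    ``block:g->g'`` over other groups, which is the same quantity.
    Positive values mean in-group favouritism (for the taking game: leaving
    more coins for co-ethnics).
    """
    design = posterior.design
    if groups is None:
        groups = design.group_labels
    all_groups = list(design.group_labels)

    def alter_main(g: str) -> np.ndarray:
        name = f"alter_group:{g}"
        if name in posterior.draws:
            return posterior.stacked(name)
        return np.zeros_like(next(iter(posterior.draws.values())).reshape(-1))

    rows = []
    for g in groups:
        if not posterior.spec.block_parameterisation:
            name = f"parochial:{g}"
            if name not in posterior.draws:
                raise ValidationError(f"group {g!r} absent from the model")
            others = [alter_main(h) for h in all_groups if h != g]
            contrast = (
                posterior.stacked(name)
                + alter_main(g)
                - np.mean(others, axis=0)
            )
        else:
            own = f"block:{g}->{g}"
            if own not in posterior.draws:
                raise ValidationError(f"group {g!r} absent from the model")
            others = [
                posterior.stacked(f"block:{g}->{h}")
                for h in design.group_labels
                if h != g
            ]
            contrast = posterior.stacked(own) - np.mean(others, axis=0)
        q05, med, q95 = np.quantile(contrast, [0.05, 0.5, 0.95])
        reliable = bool(q05 > 0 or q95 < 0)
        if reliable:
            direction = "in_group_favouring" if med > 0 else "out_group_favouring"
        else:
            direction = "none"
        rows.append(
            {
                "group": g,
                "median": med,
                "q05": q05,
                "q95": q95,
                "reliable": reliable,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def diagnostics(posterior: SRMPosterior) -> pd.DataFrame:
    """Split-Rhat and bulk ESS per reported parameter, with a verdict.

    Requires at least two chains (Rhat is undefined on one and flagged).
    """
    rows = []
    single_chain = posterior.chains < 2
    for name, d in posterior.draws.items():
        if single_chain:
            rhat = np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = float(az.rhat(az.convert_to_dataset(d))["x"].values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(az.convert_to_dataset(d))["x"].values)
        rows.append({"parameter": name, "rhat": rhat, "ess_bulk": ess})
    table = pd.DataFrame(rows)
    if single_chain:
        table.attrs["verdict"] = "rhat undefined: single chain"
    elif (table["rhat"] > 1.01).any():
        bad = table.loc[table["rhat"] > 1.01, "parameter"].tolist()
        table.attrs["verdict"] = f"not converged: rhat > 1.01 for {bad}"
    else:
        table.attrs["verdict"] = "ok"
    return table
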