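"""Orchestrate the full analysis design: 5 outcomes x 2 variants per site.

For every site the plan fits an independent SRM to each outcome layer
(friendship, merged transfers, giving, taking-leave, costly reduction)
under two model variants — ``no_controls`` (ethnicity main effects and the
parochial same-group bonuses only) and ``full_controls`` (adding wealth,
food security, relatedness and marriage) — and collects coefficient
summaries, parochialism contrasts and convergence diagnostics into one
combined table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .network_data import ValidationError
from .rich_games import ingroup_outgroup_rates, site_game_summaries
from .srm.fit import SRMPosterior, extract_parochial_contrasts, fit
from .srm.spec import MCMCConfig, SRMSpec
from .synthetic import LAYER_KINDS, SiteData

log = logging.getLogger("richsrm.pipeline")

OUTCOMES = ("friendship", "transfer", "giving", "taking_leave", "reduction")
VARIANTS = ("no_controls", "full_controls")
#: dyad random effects are fitted only on the interview layers, where both
#: directions of every pair are observed
DYAD_EFFECT_OUTCOMES = ("friendship", "transfer")


@dataclasses.dataclass
class AnalysisPlan:
    """What to run: outcomes x variants per site, sampler settings, seed."""

    outcomes: tuple[str, ...] = OUTCOMES
    variants: tuple[str, ...] = VARIANTS
    seed: int = 0
    mcmc: MCMCConfig = dataclasses.field(default_factory=MCMCConfig)

    @property
    def n_fits(self) -> int:
        return len(self.outcomes) * len(self.variants)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisPlan":
        """Load a plan from YAML.

        Schema (all keys optional)::

            outcomes: [friendship, transfer, giving, taking_leave, reduction]
            variants: [no_controls, full_controls]
            seed: 0
            mcmc:
              chains: 4
              warmup: 1000
              samples: 1000
              target_accept: 0.9
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "outcomes" in raw:
            kwargs["outcomes"] = tuple(raw["outcomes"])
        if "variants" in raw:
            kwargs["variants"] = tuple(raw["variants"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "mcmc" in raw:
            kwargs["mcmc"] = MCMCConfig(**raw["mcmc"])
        return cls(**kwargs)


@dataclasses.dataclass
class FitResult:
    site: str
    outcome: str
    variant: str
    posterior: SRMPosterior | None
    contrasts: pd.DataFrame | None
    diagnostics: pd.DataFrame | None
    error: str | None = None
    wall_time: float = 0.0


@dataclasses.dataclass
class ResultBundle:
    site: str
    fits: list[FitResult]
    summary: pd.DataFrame
    data: SiteData | None = None


def make_spec(plan: AnalysisPlan, outcome: str, variant: str,
              fit_index: int = 0) -> SRMSpec:
    """One fit's specification, with a per-fit derived seed."""
    kind = LAYER_KINDS[outcome]
    mcmc = dataclasses.replace(
        plan.mcmc, seed=(plan.seed * 1009 + fit_index) % (2**31 - 1)
    )
    return SRMSpec(
        outcome_kind=kind,
        variant=variant,
        include_dyad_effects=outcome in DYAD_EFFECT_OUTCOMES,
        mcmc=mcmc,
    )


def run_plan(plan: AnalysisPlan, data: SiteData) -> ResultBundle:
    """Fit every outcome x variant for one site, isolating failures."""
    fits: list[FitResult] = []
    rows = []
    for k, (outcome, variant) in enumerate(
        (o, v) for o in plan.outcomes for v in plan.variants
    ):
        spec = make_spec(plan, outcome, variant, fit_index=k)
        t0 = time.perf_counter()
        try:
            if outcome in data.allocations:
                out = data.allocations[outcome]
            else:
                out = data.layers[outcome]
            posterior = fit(spec, data.roster, data.dyads, out)
            contrasts = extract_parochial_contrasts(posterior)
            diags = posterior.diagnostics()
            wall = time.perf_counter() - t0
            log.info(
                "fit site=%s outcome=%s variant=%s wall=%.1fs divergences=%d "
                "max_rhat=%.3f",
                data.scenario.site, outcome, variant, wall,
                posterior.divergences, np.nanmax(diags["rhat"].values),
            )
            fits.append(
                FitResult(data.scenario.site, outcome, variant, posterior,
                          contrasts, diags, wall_time=wall)
            )
            summ = posterior.summary()
            rhat = diags.set_index("parameter")["rhat"]
            for _, row in summ.iterrows():
                rows.append(
                    {
                        "site": data.scenario.site,
                        "outcome": outcome,
                        "variant": variant,
                        "parameter": row["parameter"],
                        "median": row["median"],
                        "q05": row["q05"],
                        "q95": row["q95"],
                        "reliable": row["reliable"],
                        "rhat": rhat.get(row["parameter"], np.nan),
                    }
                )
        except ValidationError as exc:
            wall = time.perf_counter() - t0
            log.warning(
                "fit site=%s outcome=%s variant=%s FAILED: %s",
                data.scenario.site, outcome, variant, exc,
            )
            fits.append(
                FitResult(data.scenario.site, outcome, variant, None, None,
                          None, error=str(exc), wall_time=wall)
            )
    summary = pd.DataFrame(rows)
    return ResultBundle(site=data.scenario.site, fits=fits, summary=summary,
                        data=data)


def report(bundle: ResultBundle, outdir: str | Path,
           include_draws: bool = False) -> dict[str, Path]:
    """Write contrast/summary CSVs, coefficient and leaving-rate figures,
    and a run manifest.  With ``include_draws`` also writes each fit's
    posterior as long-form CSV (chain, iteration, parameter, value).
    Re-running on the same bundle reproduces identical CSV bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    manifest = {
        "site": bundle.site,
        "n_fits": len(bundle.fits),
        "n_failed": sum(1 for f in bundle.fits if f.error),
        "richsrm_version": __version__,
        "seeds": sorted(
            {f.posterior.seed for f in bundle.fits if f.posterior is not None}
        ),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = manifest_path

    if not bundle.summary.empty:
        p = outdir / "summary.csv"
        bundle.summary.to_csv(p, index=False)
        written["summary"] = p
        contrast_rows = []
        for f in bundle.fits:
            if f.contrasts is None:
                continue
            c = f.contrasts.copy()
            c.insert(0, "variant", f.variant)
            c.insert(0, "outcome", f.outcome)
            c.insert(0, "site", f.site)
            contrast_rows.append(c)
        if contrast_rows:
            p = outdir / "parochial_contrasts.csv"
            pd.concat(contrast_rows, ignore_index=True).to_csv(p, index=False)
            written["contrasts"] = p
        written["coefficients_figure"] = _coefficient_figure(bundle, outdir)
    if include_draws:
        for f in bundle.fits:
            if f.posterior is None:
                continue
            p = outdir / f"draws_{f.outcome}_{f.variant}.csv"
            f.posterior.to_long_frame().to_csv(p, index=False)
            written[f"draws_{f.outcome}_{f.variant}"] = p
    if bundle.data is not None and "taking_leave" in bundle.data.layers:
        written["leaving_rates_figure"] = _leaving_rate_figure(bundle, outdir)
    return written


def _coefficient_figure(bundle: ResultBundle, outdir: Path) -> Path:
    """Dot-and-interval plot of standardised coefficients, one panel per
    outcome, both variants overlaid."""
    outcomes = sorted(bundle.summary["outcome"].unique())
    fig, axes = plt.subplots(
        1, len(outcomes), figsize=(3.2 * len(outcomes), 6), sharey=False
    )
    if len(outcomes) == 1:
        axes = [axes]
    colors = {"no_controls": "#8ebcdd", "full_controls": "#1f4e79"}
    for ax, outcome in zip(axes, outcomes):
        sub = bundle.summary[bundle.summary["outcome"] == outcome]
        params = list(sub["parameter"].unique())
        for vk, variant in enumerate(VARIANTS):
            s = sub[sub["variant"] == variant].set_index("parameter")
            ys, meds, lo, hi = [], [], [], []
            for i, prm in enumerate(params):
                if prm not in s.index:
                    continue
                ys.append(i + 0.18 * vk)
                meds.append(s.loc[prm, "median"])
                lo.append(s.loc[prm, "q05"])
                hi.append(s.loc[prm, "q95"])
            ax.hlines(ys, lo, hi, color=colors.get(variant, "grey"), lw=2)
            ax.plot(meds, ys, "o", color=colors.get(variant, "grey"), ms=4,
                    label=variant)
        ax.axvline(0.0, ls="--", c="k", lw=0.8)
        ax.set_yticks(range(len(params)))
        ax.set_yticklabels(params, fontsize=6)
        ax.set_title(outcome, fontsize=9)
        ax.invert_yaxis()
    axes[0].legend(fontsize=7)
    fig.suptitle(f"SRM coefficients (medians, 90% CI) — {bundle.site}")
    fig.tight_layout()
    path = outdir / "coefficients.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _leaving_rate_figure(bundle: ResultBundle, outdir: Path) -> Path:
    """In-group vs out-group coin-leaving scatter with the diagonal."""
    rates = ingroup_outgroup_rates(
        bundle.data.layers["taking_leave"], bundle.data.roster
    )
    fig, ax = plt.subplots(figsize=(5, 5))
    palette = {"afro": "#1f4e79", "embera": "#b8860b"}
    for group, sub in rates.groupby("group"):
        ax.scatter(sub["in_rate"], sub["out_rate"], s=18, alpha=0.7,
                   color=palette.get(group, "grey"), label=group)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("in-group coin leaving rate")
    ax.set_ylabel("out-group coin leaving rate")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    ax.set_title(f"Taking game leaving rates — {bundle.site}")
    fig.tight_layout()
    path = outdir / "leaving_rates.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
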