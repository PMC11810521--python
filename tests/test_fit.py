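import warnings

import numpy as np
import pytest
from scipy.special import logit

from richsrm.network_data import build_dyad_table
from richsrm.srm.design import build_design
from richsrm.srm.fit import extract_parochial_contrasts, fit
from richsrm.srm.simulate import simulate_layer
from richsrm.srm.spec import MCMCConfig, SRMParameters, SRMSpec

from conftest import make_roster

FAST = MCMCConfig(chains=2, warmup=250, samples=250, seed=5)


def _intercept_only_spec(**kw):
    return SRMSpec(
        outcome_kind="bernoulli",
        variant="full_controls",
        focal_covariates=(),
        alter_covariates=(),
        dyad_covariates=(),
        parochial_terms=False,
        **kw,
    )


def _fit_quiet(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit(*args, **kwargs)


def test_fit_deterministic():
    roster = make_roster(10)
    dyads = build_dyad_table(roster)
    spec = _intercept_only_spec(mcmc=MCMCConfig(chains=2, warmup=100,
                                                samples=100, seed=9))
    design = build_design(spec, roster, dyads)
    layer = simulate_layer(design, SRMParameters(fixed={"intercept": -0.5}),
                           seed=1)
    a = _fit_quiet(spec, roster, dyads, layer)
    b = _fit_quiet(spec, roster, dyads, layer)
    for name in a.draws:
        assert np.array_equal(a.draws[name], b.draws[name])


def test_logistic_limit_recovers_density():
    """No random effects in the generator, intercept-only model: the
    posterior for the intercept concentrates near logit(density)."""
    roster = make_roster(40)
    dyads = build_dyad_table(roster)
    spec = _intercept_only_spec(mcmc=FAST)
    design = build_design(spec, roster, dyads)
    layer = simulate_layer(design, SRMParameters(fixed={"intercept": -1.0}),
                           seed=2)
    mask = ~np.eye(40, dtype=bool)
    density = layer.adjacency[mask].mean()
    post = _fit_quiet(spec, roster, dyads, layer)
    b0 = post.stacked("intercept")
    assert np.median(b0) == pytest.approx(logit(density), abs=0.15)


def test_posterior_summary_and_reliability():
    roster = make_roster(16)
    dyads = build_dyad_table(roster)
    spec = SRMSpec(outcome_kind="bernoulli", variant="no_controls", mcmc=FAST)
    design = build_design(spec, roster, dyads)
    layer = simulate_layer(
        design,
        SRMParameters(fixed={"intercept": -0.5}, sigma_s=0.5, sigma_r=0.5),
        seed=3,
    )
    post = _fit_quiet(spec, roster, dyads, layer)
    summ = post.summary()
    assert set(summ["parameter"]) == set(post.draws)
    row = summ.set_index("parameter").loc["sigma_s"]
    assert row["q05"] <= row["median"] <= row["q95"]
    # sigma draws are positive, rho draws are within [-1, 1]
    assert (post.stacked("sigma_s") > 0).all()
    assert (np.abs(post.stacked("rho_gr")) <= 1).all()


def test_contrast_direction_labels():
    roster = make_roster(16)
    dyads = build_dyad_table(roster)
    spec = SRMSpec(outcome_kind="bernoulli", variant="no_controls", mcmc=FAST)
    design = build_design(spec, roster, dyads)
    layer = simulate_layer(design, SRMParameters(fixed={"intercept": -0.5}),
                           seed=4)
    post = _fit_quiet(spec, roster, dyads, layer)
    contrasts = extract_parochial_contrasts(post)
    assert list(contrasts["group"]) == ["afro", "embera"]
    for _, row in contrasts.iterrows():
        if not row["reliable"]:
            assert row["direction"] == "none"
        elif row["median"] > 0:
            assert row["direction"] == "in_group_favouring"
        else:
            assert row["direction"] == "out_group_favouring"


def test_block_contrast_matches_default_contrast():
    """The two parochialism parameterisations report the same identified
    quantity (up to Monte-Carlo error)."""
    roster = make_roster(30)
    dyads = build_dyad_table(roster)
    gen_spec = SRMSpec(outcome_kind="bernoulli", variant="no_controls")
    design = build_design(gen_spec, roster, dyads)
    truth = SRMParameters(
        fixed={"intercept": -0.3, "parochial:afro": 1.2,
               "parochial:embera": -0.8},
        sigma_s=0.3, sigma_r=0.3,
    )
    layer = simulate_layer(design, truth, seed=6)
    default = _fit_quiet(SRMSpec(outcome_kind="bernoulli",
                                 variant="no_controls", mcmc=FAST),
                         roster, dyads, layer)
    block = _fit_quiet(SRMSpec(outcome_kind="bernoulli", variant="no_controls",
                               block_parameterisation=True, mcmc=FAST),
                       roster, dyads, layer)
    ca = extract_parochial_contrasts(default).set_index("group")["median"]
    cb = extract_parochial_contrasts(block).set_index("group")["median"]
    assert ca["afro"] == pytest.approx(cb["afro"], abs=0.3)
    assert ca["embera"] == pytest.approx(cb["embera"], abs=0.3)


def test_single_chain_diagnostics_flagged():
    roster = make_roster(10)
    dyads = build_dyad_table(roster)
    spec = _intercept_only_spec(mcmc=MCMCConfig(chains=1, warmup=100,
                                                samples=100, seed=1))
    design = build_design(spec, roster, dyads)
    layer = simulate_layer(design, SRMParameters(), seed=1)
    post = _fit_quiet(spec, roster, dyads, layer)
    d = post.diagnostics()
    assert d["rhat"].isna().all()
    assert "single chain" in d.attrs["verdict"]


def test_diagnostics_verdict_ok_on_easy_posterior():
    roster = make_roster(12)
    dyads = build_dyad_table(roster)
    spec = _intercept_only_spec(mcmc=MCMCConfig(chains=2, warmup=400,
                                                samples=400, seed=2))
    design = build_design(spec, roster, dyads)
    layer = simulate_layer(design, SRMParameters(fixed={"intercept": 0.3}),
                           seed=5)
    post = _fit_quiet(spec, roster, dyads, layer)
    d = post.diagnostics()
    assert (d["rhat"] < 1.05).all()


def test_long_frame_layout():
    roster = make_roster(8)
    dyads = build_dyad_table(roster)
    spec = _intercept_only_spec(mcmc=MCMCConfig(chains=2, warmup=50,
                                                samples=60, seed=3))
    design = build_design(spec, roster, dyads)
    layer = simulate_layer(design, SRMParameters(), seed=2)
    post = _fit_quiet(spec, roster, dyads, layer)
    lf = post.to_long_frame()
    assert set(lf.columns) == {"chain", "iteration", "parameter", "value"}
    assert len(lf) == len(post.draws) * 2 * 60
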