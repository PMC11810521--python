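# Methods

This document specifies the statistical machinery implemented in
`richsrm`: the data model, the economic-game accounting, the Social
Relations Model (SRM) variants, the sampler, and the validation strategy.

## 1. Data model

A **roster** is the complete list of adults at one site. Each individual
carries an ethnic-group label, household wealth and monthly income (pesos),
and a 0–4 food-insecurity score. Wealth enters all models as
`log_wealth`. A **dyad table** holds, for every ordered pair, the
pedigree relatedness coefficient (0, 1/8, 1/4 or 1/2), a marriage
indicator and a same-group indicator. Directed binary **layers**
(friendship nominations, food/money transfers, taking-game decisions) are
stored as n×n adjacency matrices with an explicit *focal set*: the rows
that were actually observed. **Allocation sets** store the coin-level
choices of the giving and reduction games: each focal distributes an
integer budget over the categories {self} ∪ {everyone else}.

Interview layers treat every roster member as a focal. Game layers only
include *completers*; non-completers still appear as targets (columns),
contributing no focal rows but remaining eligible recipients.

Transfer networks are double-sampled: each direction is reported by both
parties with imperfect recall, and the analysis layer is the union of the
give-reports and receive-reports (an intersection rule is also available).

## 2. Game accounting

Per-site stakes (pesos):

| quantity | coastal | inland |
|---|---|---|
| giving stake | 15,000 (15 × 1,000 coins) | 20,000 (20 coins) |
| taking stake | 500 per target photo | 500 per target |
| reduction budget | 10,000 (10 × 1,000 tokens) | 15,000 (15 tokens) |

In the taking game a focal facing `n − 1` targets controls a pre-allocated
endowment of `500 × (n − 1)` pesos (57,500 for 115 targets, 75,500 for
151). The binary decision is coded **1 = the focal left the target's
coin**, so a focal's take equals the number of zeros over their targets.
In the reduction game each 1,000-peso token a focal spends removes
4 × 1,000 pesos from the target. Final payouts add up giving coins kept
plus coins received, taking coins taken plus coins left *for* the focal by
others, and the unspent reduction budget, minus 4,000 pesos per token
targeting the focal.

Summing over the population gives an exact conservation identity used
throughout the tests: every token spent destroys its own cost plus the
fourfold reduction, so

```
Σ final payouts = Σ stakes − token_cost × (multiplier + 1) × tokens spent.
```

`population_identity_residual` returns the deviation from this identity
(exactly zero for any valid play when payouts are not floored at zero).

## 3. The Social Relations Model

### 3.1 Bernoulli layers

For a directed tie from focal *i* to alter *j*:

```
logit P(y_ij = 1) = β₀ + s_i + r_j + d_ij
                  + Σ_g φ_g · 1[g(i) = g(j) = g]          (parochial terms)
                  + focal/alter group main effects
                  + z_iᵀ γ + x_jᵀ β_A + w_ijᵀ β_D          (covariates)
```

Random effects: sender/receiver pairs `(s_i, r_i)` are bivariate normal
with SDs `σ_s, σ_r` and correlation `ρ_gr` (*generalised reciprocity*);
for fully observed layers, within-dyad pairs `(d_ij, d_ji)` are bivariate
normal with SD `σ_d` and correlation `ρ_dd` (*dyadic reciprocity*). Dyad
effects are disabled for single-shot game layers, where they are
unidentifiable from outcome noise.

### 3.2 Multinomial layers

Giving and reduction allocations are multinomial: focal *i* drops a
budget of B indistinguishable coins over {self} ∪ {alters} with
probabilities `softmax(η_i·)`. Alter cells use the same linear predictor
as above (without the intercept); the self cell has its own score
`λ₀ + self-group effect + z_iᵀ γ_self + s_i`. The log-pmf includes the
multinomial coefficient, so probabilities over all allocations of a
budget sum to one. The softmax is shift-invariant per focal, which is why
the alter-cell intercept is absorbed into the self score.

### 3.3 Model variants

Every outcome is fitted twice, following a paired-model design:

* **no_controls** — ethnicity main effects and the per-group parochial
  (same-group) terms only;
* **full_controls** — adds focal and alter `log_wealth` and
  `food_insecurity`, and dyadic `relatedness` and `marriage`.

Comparing the two variants separates genuine in-group preference from
covariates that are merely *correlated* with ethnicity (wealth above
all). Continuous covariates are standardised (zero mean, unit SD);
binary indicators are left as 0/1; a `ScalingRecord` maps coefficients
back to natural units.

### 3.4 The identified in-group contrast

The per-group parochial coefficient is **not identified on its own**: the
parameterisation {intercept, focal-group, alter-group, parochial} of the
2×2 group-by-group cell means has a one-dimensional flat direction that
only the priors resolve. The package therefore reports, for each group
*g*, the invariant contrast

```
Δ_g = score(g → g) − mean over h ≠ g of score(g → h)
```

at a fixed focal, i.e. `parochial:g + alter_group:g − mean_h alter_group:h`.
This is the same-group bonus net of alter-ethnicity main effects; it
equals `block:g→g − mean_h block:g→h` under the saturated block
parameterisation (also implemented), and is invariant to the flat
direction. Positive Δ means in-group favouritism; for the taking game,
leaving more coins for co-ethnics. An effect is flagged *reliable* when
its central 90% credible interval excludes zero.

### 3.5 Priors

Fixed effects and parochial terms: Normal(0, 1) on the standardised
scale. Random-effect SDs: half-Normal(0, 1). The two 2×2 correlation
blocks (sender–receiver, and the two directions within a dyad):
LKJ(η = 2), i.e. density ∝ (1 − ρ²) on each correlation.

### 3.6 Sampler

Posteriors are drawn with a self-contained Hamiltonian Monte Carlo
implementation: unconstrained parameterisation (log-SDs, atanh
correlations, non-centred random effects), jittered leapfrog trajectories,
dual-averaging step-size adaptation to a target acceptance rate of 0.9,
and diagonal mass-matrix estimation over expanding warmup windows.
Defaults are 4 chains × 1,000 warmup + 1,000 retained draws. Divergent
transitions after warmup are counted and raised as warnings, never
hidden; `diagnostics()` reports split-R̂ and bulk ESS per parameter and a
verdict string. Layers with zero outcome variance abort with a clear
error instead of returning a degenerate fit.

## 4. Synthetic sites

`synthetic.generate_site` draws a full site from the generative process
above: a roster with configurable group sizes, a log-normal wealth model
with a fixed between-group mean ratio (default 3.7), income, a
food-insecurity score negatively correlated with log wealth, kin clusters
with pedigree relatedness, mostly ethnically endogamous marriages, and
all five outcome layers from per-layer true SRM parameters. Two presets
ship with the package: `coastal_like` (88 + 28, anti-parochial taking by
the majority group, wide within-group wealth overlap) and `inland_like`
(130 + 21, parochial taking by both groups). Transfer layers are
generated as a true tie set, double-reported with per-direction recall
0.8 and merged by union. All generation is deterministic given a seed.

## 5. Validation

The test suite checks, among much else:

1. **Accounting identities** — stakes, per-person totals and
   percent-of-stake statistics reproduce their printed values exactly.
2. **Likelihood oracles** — the multinomial log-pmf matches exhaustive
   enumeration (all allocations of budget ≤ 3 over ≤ 4 categories;
   probability mass sums to one within 1e−12) and an independent
   `scipy.stats.multinomial` evaluation; the Bernoulli log-likelihood
   matches a per-dyad loop; softmax shift invariance holds to 1e−12.
3. **Generative consistency** — simulated `(s, r)` and `(d_ij, d_ji)`
   correlations match the configured ρ within ±0.02 at 10⁴ draws;
   allocation shares match softmax probabilities within 1% at budget 10⁴.
4. **Parameter recovery** — on coastal-like data (n = 116) the fitted 90%
   intervals recover the sign of both configured in-group contrasts in
   ≥ 95% of 20 replicates at reduced MCMC settings; simulation-based
   calibration over 50 cheap replicates (truth drawn from the priors)
   keeps fixed-effect interval coverage compatible with 90%.
5. **Mediation pattern** — when alter wealth (correlated with ethnicity)
   is the only driver of taking, the no-controls model shows an apparent
   anti-parochial contrast for the wealthier group that attenuates once
   wealth controls enter.
6. **Payout conservation** — the population identity holds exactly on 100
   random plays.

`scripts/acceptance.py --seed N --out results.json` recomputes all of
these quantities and writes them as machine-readable JSON.
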