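# Methods

## The model

`irmsim` simulates the evolution of polygenic insecticide resistance in a
mosquito population under four resistance-management strategies. Resistance
to each insecticide *i* is summarized by the population-mean Polygenic
Resistance Score (PRS), written `z̄_I`, a latent additive trait under the
infinitesimal model: many loci of small effect, so genetic variances are
treated as constant under selection and the population mean is the only
state variable per trait and patch. Generations are discrete and
non-overlapping (ten per year for *Anopheles gambiae*), exposure happens
once per adult generation, mating precedes dispersal, and the model is
fully deterministic.

**Observable scale.** Mean PRS maps to diagnostic-dose bioassay survival
through a Hill function

    K_B(z) = K_max · z^n / (z50 + z^n),    K_max = 1, z50 = 900, n = 1,

anchored so that z = 100 corresponds to 10% bioassay survival — the WHO
"confirmed resistance" level used as the withdrawal threshold. Field
(experimental-hut) survival is a linear transform of bioassay survival,
`K_F = 0.48·K_B + 0.15`, the regression of paired hut-trial and cylinder
bioassay survivals; it ranges over [0.15, 0.63].

**Selection.** The per-generation response under full solo deployment is
the sex-averaged breeder's equation

    R = β · h² · x · (1 + m) / 2,

with female selection differential `x·β` and male differential `x·m·β`
(females blood-feed, so male exposure `m` is a fraction of female exposure
`x`). β is the exposure scaling factor absorbing the unknown field
selection differential and field heritability; see Calibration.

**Fitness costs.** Resistance decays by `ψ·R` per generation wherever the
insecticide is not selecting (idle in the intervention site, and always in
the refugia), with the mean clamped at zero — `z̄ = 0` is the
evolutionarily stable susceptible baseline. The cost uses the *potential*
response R regardless of deployment status, so cost strength scales with
the same genetic variance that fuels the response.

**Per-trait updates in the intervention site** (all deltas clamped at 0):

| deployment        | change in z̄_I |
|-------------------|----------------|
| solo i deployed   | `+R_i(1 − ψ_i)` |
| solo j deployed   | `−ψ_i R_i + α_JI (R_j − ψ_j R_j)` |
| nothing relevant  | `−ψ_i R_i` |
| mixture of i, j   | `+K_jF R_i − ψ_i R_i + K_iF α_JI (R_j − ψ_j R_j)` |

Cross resistance enters as a genetic correlation α producing a correlated
response; both traits share the PRS scale so no variance rescaling is
needed. In a full-dose mixture, a mosquito must survive the partner
component before the focal component can select, so the direct response is
damped by the partner's field survival `K_jF` (and the indirect, correlated
response by `K_iF`); both field survivals are evaluated at the means at the
start of the generation so the two traits update symmetrically.

**Dispersal.** Two patches: the intervention site (a fraction C of the
population) and an untreated refugia. After selection, means mix as

    z̄_t″ = z̄_t′(1 − r_t) + z̄_u′ r_t,   r_t = (1 − C)·θe
    z̄_u″ = z̄_u′(1 − r_u) + z̄_t′ r_u,   r_u = C·θe

computed simultaneously from the same primed values. Both are convex
combinations, so non-negativity is preserved without further clamping.

## Deployment rules and strategies

Decisions happen only at epochs `g = 0, d, 2d, …` (d = 10 generations for
IRS-like annual deployment, 30 for LLIN-like 3-year deployment). At an
epoch, per-insecticide bioassay survival is computed from the
intervention-site means (decisions and bioassays are made in the same
generation, in the treated area); then:

* **withdrawal** — an available insecticide with survival ≥ 10% leaves the
  armory (inclusive comparison: 10.0% is withdrawn, 9.9% is not);
* **return** — a withdrawn insecticide with survival strictly below 8%
  becomes available again (the 8–10% hysteresis band stops a just-failed
  product from bouncing straight back).

Policies: **sequence** keeps the incumbent until withdrawal, then deploys
the lowest-numbered available product; **rotation** switches to the other
product every epoch and terminates when the switch is impossible
(redeploying the incumbent would be a de facto sequence); **adaptive
rotation** relaxes exactly that rule, continuing the incumbent while it is
the sole available product and resuming rotation when the other returns;
**mixture** deploys both products in one full-dose formulation and
terminates — finally, with no return pathway — as soon as either
component's survival reaches 10%. The first deployment (epoch 0) is itself
a decision; all strategies start with insecticide 1 (or the mixture). A
run ends when the policy has nothing to deploy ("strategy lifespan" = that
epoch's generation, so a mid-interval failure is only acted on at the next
epoch) or at the 500-generation cap (~50 years, beyond any policy
horizon).

The engine records per-generation trajectories and two secondary outcomes:
the mean bioassay survival of the currently deployed insecticide(s)
(mixtures: the average of the two components) and the peak bioassay
survival of any trait at any generation in the intervention site.

## Calibration of β

β converts exposure into selection on the PRS scale. It is set so that a
typical insecticide, deployed continuously against an initially
susceptible *closed* population, most frequently fails (reaches 10%
bioassay survival) at about 10 years. The closed-population choice is
deliberate: the calibration pins the intrinsic timescale of selection, so
the lifespan has the closed form `ceil(z_threshold / (R(1 − ψ)))`
generations; running the calibration with the two-patch dynamics instead
lets low-coverage/high-dispersal draws never reach threshold and pushes
the histogram mode to the cap, which cannot reproduce the intended
~10-year mode (the two-patch variant is retained behind
`two_patch=True` for exploration). Lifespans are histogrammed in 1-year
bins centred on integer years; the mode is the lowest midpoint among tied
maxima. With β = 10 the mode sits at 9–10 years across seeds, inside the
expected 8–12-year band.

## Experiment designs (the synthetic-data generator)

No external data enter the simulator; the designs *are* the study
conditions.

* **Equal-properties design** — both insecticides share h², ψ and starting
  PRS. Continuous parameters are Latin-hypercube sampled
  (scipy's stratified LHS) over h² ∈ U(0.05, 0.30), x ∈ U(0.4, 0.9),
  m ∈ U(0, 1), ψ ∈ U(0.01, 0.2), C ∈ U(0.1, 0.9), θe ∈ U(0.1, 0.9), then
  crossed with cross-resistance α ∈ {−0.5, −0.4, …, 0.5}, starting PRS
  ∈ {0, 50} (novel vs pre-used, ~5% survival) and deployment interval
  ∈ {10, 30}: 44 factor combinations per LHS row. The reference design
  uses 5000 LHS rows (220,000 parameter sets per strategy); tests and the
  acceptance script use 150–500 rows, which holds the headline
  percentages to within a couple of points (checked by bootstrap).
* **Unique-properties design** — h², ψ and starting PRS (U(0, 80), always
  below the z = 100 failure anchor) are drawn independently per
  insecticide; α ∈ U(−0.5, 0.5); x, m, C, θe are shared (they describe
  exposure and landscape, not the product); d = 10 by default. This is the
  design under which strict rotation is handicapped by its own stopping
  rule and adaptive rotation is evaluated.

Every strategy runs on identical rows, so comparisons are exactly paired.
A strategy *wins* a pairing with a strictly longer lifespan and wins
*operationally* at a lifespan ratio ≥ 1.1 (longer/shorter); equal
lifespans draw. Three-way classes compare the mixture against both solo
strategies (draw / mixtures-win / sequences-lose / rotations-lose, with a
separately counted mixtures-lose class that the model is not expected to
produce).

What the generator does **not** emulate: genetic drift and changing
variances, population dynamics and density dependence, imperfect
surveillance and delayed decisions, non-programme (e.g. agricultural)
selection pressure, seasonality, and more than two insecticides. Passing
tests therefore demonstrate the deterministic mean-trait logic and the
strategy bookkeeping, not forecasts for any real deployment programme.

## Sensitivity analyses

* **PRCC** — outcome and inputs are rank-transformed; each parameter's
  partial correlation with lifespan controls all other parameters via
  least-squares residuals on ranks; two-sided p-values from the
  t-distribution with n − 2 − k df. Computed per strategy/stratum
  (starting resistance, α), as the design is balanced across those
  factors.
* **Count regression** — a Poisson GLM is fit first purely as an
  over-dispersion diagnostic (Pearson χ²/df ≫ 1 on these lifespans), then
  a maximum-likelihood negative-binomial regression of lifespan on h², x,
  m, C, ψ, strategy, starting-resistance and interval factors, with a
  cubic B-spline basis (df = 6, i.e. three internal knots) on θe, whose
  effect is clearly nonlinear. Cap-terminated runs are excluded as
  censored.
* **Random forests** — scikit-learn forests (500 trees, default feature
  subsampling; the reference analysis specifies no hyperparameters) are
  trained on a random 70% of comparisons to predict the operational
  outcome, with accuracy reported on the held-out 30% and parameters
  ranked by permutation importance (mean decrease in held-out accuracy).
  Eight configurations cross design (equal/unique) × comparison
  (pair/triple) × coverage filter (all vs C ≥ 0.5; at low coverage the
  no-operational-win class dominates and coverage masks the genuinely
  decision-relevant parameters).

## Numerical and design choices

* The mixture cost term is *not* scaled by the partner's survival
  (`K_jF·R − ψR`), consistent with the idle-product update; a
  `Scenario(mixture_cost_scaled=True)` toggle enables the grouped reading
  `K_jF·(R − ψR)`.
* The correlated-response term on an idle trait is grouped,
  `−ψ_i R_i + α(R_j − ψ_j R_j)`, the only reading that reduces to the pure
  cost update at α = 0.
* `r_t = (1 − C)θe` and `r_u = C·θe` are used as immigrant fractions into
  site and refugia respectively; this convention reproduces the
  420-generation worked example exactly (the alternative reading does
  not).
* Clamping at zero applies after the selection/cost step; dispersal needs
  none.
* In the worked example (d = 10, α = 0, z0 = 0, h² = 0.2028686,
  m = 0.2500806, x = 0.8645515, ψ = 0.1730878, C = 0.6885651,
  θe = 0.8844445) the sequence strategy terminates at generation 420 and
  rotation reaches the cap. The withdrawn first insecticide crosses below
  the 8% return threshold at generation 304 and is marked available at
  epoch 310; the published trajectory figure reads this off as "300
  generations", and no update-order or threshold convention consistent
  with the 420/500 lifespans yields an earlier return epoch.
* `population_averaged_survival` integrates the Hill curve against a
  Normal PRS distribution by adaptive quadrature on [0, mean + 12σ]
  (negative-PRS mass survives with probability 0); it exists to verify
  that the z = 100 ↔ 10% anchor is stable for population SD up to 25, and
  plays no role in the mean-tracking dynamics.
* A vectorized batch engine advances all design rows simultaneously; it is
  asserted bit-identical (lifespans, outcome summaries) to the scalar
  reference engine on randomized parameter sets.
* Random-forest train/test splits, LHS draws and forest randomness are all
  seeded; identical seeds give identical artifacts.

## Known limitations

Mean-only tracking ignores transient variance changes under strong
selection; fitness costs are a single global proportion rather than
trait-specific life-history effects; the two patches are closed to the
outside world; cross resistance acts on selection responses only (no
cost-side correlation); mixtures are always full-dose; and the withdrawal
threshold (10%) is deliberately low — higher thresholds drive most
comparisons to the cap and would require recalibrating β.
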