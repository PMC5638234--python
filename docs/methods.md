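# Methods

## Scope and model family

The package compares four empirical stomatal conductance models that share
a multiplicative structure — a supply term in assimilation A and leaf-surface
CO₂ Cₛ, an atmospheric-drought term in VPD D, and (in two of the four) a
hydraulic term in leaf water potential ψ:

- Medlyn (`M`): gₛ = 1.6 (A/Cₛ)(1 + g₁/√D). One free parameter, g₁
  (kPa^0.5). D is floored at 0.05 kPa: the 1/√D singularity is unphysical
  and gas-exchange measurements below that VPD are unreliable.
- Ball–Berry–Leuning (`BBL`): gₛ = αA/((Cₛ − Γ\*)(1 + D/d₁)), free (α, d₁).
  The residual conductance g₀ is omitted in all four models, so every model
  predicts gₛ = 0 at A = 0 and fits have no intercept.
- Tuzet variant (`T`): the VPD term is replaced by a sigmoidal dependence
  on ψ, implemented as a survival-form Weibull e^(−(|ψ|/c)ᵇ); free
  (α, b, c).
- Combined (`BBL.H`): both terms; free (α, d₁, b, c). `BBL.H` nests `BBL`
  (c → ∞) and, at D = 0, reduces to `T`; these identities are exact in the
  implementation and are property-tested.

Water potentials are stored as ψ ≤ 0 MPa everywhere; Weibulls are
evaluated on |ψ| with a positive scale c (MPa), avoiding fractional powers
of negative numbers. Γ\* defaults to 42.75 µmol mol⁻¹ at 25 °C with an
Arrhenius temperature response, overridable per species.

The same Weibull form describes xylem vulnerability. Given the potentials
at 50% and 88% conductivity loss (P50, P88), the closed form

    b = ln(ln(1/0.12)/ln 2) / ln(|P88|/|P50|),  c = |P50| / (ln 2)^(1/b)

reproduces both anchors exactly; percent loss of conductivity is
PLC(ψ) = 100(1 − S(ψ)).

## Fitting and model selection

Each (species, model) pair is fit by minimizing Σ(gₛ_pred − gₛ_obs)² with
Nelder–Mead simplex runs started from a Latin-hypercube sample in
log-parameter space (default 20 starts plus the bounds midpoint) over
g₁∈[0.1,20], α∈[0.5,50], d₁∈[0.05,10], b∈[0.3,15], c∈[0.2,12]. Optimizing
log-parameters enforces positivity while keeping the objective smooth; the
simplex tolerances are 1e−10 (x) and 1e−12 (f), and log-parameters are
clipped to ±30 so the exponential stays finite wherever the simplex roams.
The ψ covariate is midday ψ, with predawn substituted where midday was
never measured.

AIC uses the least-squares form n ln(SSE/n) + 2k with k the number of
structural parameters (error variance not counted); the omitted constant
cancels in within-species differences, which are the only comparisons made.
Fits entering a selection must be computed on identical record subsets
(enforced via a fingerprint of the rows used; `common_row_mask` builds the
subset all models can evaluate). A model is declared best only when every
competitor is more than 3 AIC units worse; otherwise the selection is
"ambiguous". Pairwise relative likelihoods are 1/(1 + e^(−|ΔAIC|/2)).
R² is 1 − SSE/SStot about the observed mean (a predicted-vs-observed
correlation R² is also available as `regression_r2`); RMSE is √(SSE/n).

## Marginal gₛ(ψ) curve and ψ_gs50

A bagged ensemble of 500 CART regression trees predicts gₛ from
{ψ, D, A, Cₐ}; a node with fewer than 5 observations is not split, and one
of p/3 features is considered per split (with four predictors this is one;
considering all features lets greedy splits ride the collinear A covariate
and flattens the marginal ψ response). Species with fewer than three
distinct ψ values are excluded — the marginal curve cannot be
reconstructed. Missing A is filled with the Farquhar model at
Ci = 0.7 Cₐ. Out-of-bag R² is reported as the out-of-sample explanatory
power; on default synthetic campaigns it runs around 0.9 — higher than is
typical for heterogeneous field compilations (~0.6) because the generator
has a single, clean noise process and no between-study instrument or site
effects.

The marginal curve is classic partial dependence: at each of 50 grid
points from 0 to the species' minimum observed ψ, every record's ψ is
replaced by the grid value and predictions are averaged. The raw curve is
then rescaled to the observed degree of stomatal closure: an affine map
sends the wet-end value to 1 and the curve minimum to the ratio of the
lowest to the highest gₛ measured under high light (PAR ≥ 800
µmol m⁻² s⁻¹, or the top PAR quartile when few records reach that) and
near-median CO₂ (±10%). A species measured between 100 and 40 mmol
m⁻² s⁻¹ therefore spans [0.4, 1]. When the filter removes every record the
unfiltered extremes are used with a warning; when no closure was observed
the curve is flagged and returned as constant 1.

Shape classification: a curve is "erratic" when its cumulative upward
movement (toward drier ψ) exceeds 15% of its range or it rises overall;
otherwise it is labelled by the best least-squares template among Weibull,
logistic and negative exponential (each with a free dry-end floor).
ψ_gs50 — the potential at 50% loss of stomatal conductance — is read from
the scaled curve by linear interpolation between the bracketing grid
points; if the curve never reaches 0.5 it is solved from the fitted
Weibull template and flagged extrapolated. Erratic curves have no ψ_gs50.

Accuracy: on coupled-generator panels (below) the estimator carries a
wet-ward attenuation of roughly 0.3–0.5 MPa for species that close late,
because assimilation, measured concurrently, declines with closure through
Ci starvation, and partial dependence credits part of the closure to A.
Controlled runs with a causally inert A reduce the error to ~0.1 MPa, so
this is a property of marginalizing over a mediator, not of the surrogate;
no setting of the per-split feature count removes it (a scan over 1/3,
1/2, 3/4 and all features gives median midpoint errors of 0.40, 0.43,
0.48 and 0.73 MPa). Estimates for early-closing (isohydric) species are
substantially more accurate than for late closers. The flat-generator null
is clean: species with no ψ effect are essentially never assigned a
shallow closure midpoint.

## Drought bias

Residuals are observed − predicted gₛ from each fitted model. Bias slopes
are OLS regressions of residuals on T_leaf, D and predawn ψ (the
soil-moisture proxy), each with its SE and t-test p-value; p-values are
reported raw. Dry-condition bias is
100 (mean obs − mean pred)/mean obs over records with predawn ψ at or
below the species' 10th-percentile predawn ψ (linear-interpolation
quantile); the ratio-of-means avoids division by near-zero records, and
the sign convention makes over-prediction negative. Collinearity screens:
VIFs among {ψ, D, A, Cₐ} from auxiliary regressions (∞ sentinel on exact
collinearity), the cross-species correlation between the BBL.H-over-BBL
AIC gain and the within-species corr(D, ψ), and pairwise correlations
among fitted BBL.H parameters.

## Hydraulic coupling

ψ_gs50 is regressed (OLS) on ψ_x50 = P50 across species, both as signed
MPa. A species lies "below the 1:1 line" when |ψ_gs50| < |ψ_x50| —
stomata close before half the stem conductivity is lost — which is
equivalent to PLC(ψ_gs50) < 50%; the implementation treats these as one
predicate and the equivalence is asserted over whole synthetic panels.
Species with extrapolated ψ_gs50 are flagged and can be excluded from the
regression with a toggle.

## The synthetic generator

Real multi-species compilations of this kind are rarely deposited, so the
pipeline is exercised end-to-end on a coupled leaf with known truth. For
each environmental draw the solver finds the joint fixed point of

    A = Farquhar(Ci),  Ci : A(Ci) = gₛ(Cₐ − Ci)/1.6,
    gₛ = stomatal_model(A, Cₐ, D, ψ_leaf),
    E = gₛ D / P_atm,  ψ_leaf = ψ_soil − E/K_eff,

with K_eff = K·S_xylem(ψ_leaf) when hydraulic feedback is on. The inner
carbon balance is monotone in Ci and solved by bisection (unconditionally
stable even as stomata shut); the outer gₛ/ψ loop is damped (factor 0.5)
and iterated to 1e−8 relative change, up to 1500 sweeps — a few percent of
records near the hydraulic-feedback oscillation decay slowly. Records
that fail to converge are excluded and counted; more than 20% failing
aborts the campaign. Converged records satisfy all coupling equations to
<1e−6 when re-evaluated independently (the plug-back oracle in the tests).
Closed stomata are represented by a gₛ floor of 1e−4 mol m⁻² s⁻¹ with A
pinned near −Rd.

Campaign design (defaults are the study conditions): n = 300 records;
soil water potential from a two-mode beta mixture on [ψ_min, 0] with 80%
of draws in a wet mode hugging zero (field campaigns over-sample benign
conditions) and the rest in a dry mode centered near 0.7 ψ_min; D
lognormal with median 1.5 kPa (σ = 0.4), T_leaf ~ N(25, 4) °C, PAR ~
U[400, 2000] µmol m⁻² s⁻¹, Cₐ ~ N(400, 5) µmol mol⁻¹, all truncated to
physical ranges. Noise is multiplicative lognormal on gₛ (CV 10%;
gas-exchange error grows with flux) and additive Gaussian on ψ (sd 0.05
MPa; pressure-chamber error is roughly absolute). ψ_pd records the noisy
soil potential, ψ_md the noisy solved leaf potential. Each species'
campaign reaches 1 MPa beyond its true closure midpoint.

Species priors: |P50| lognormal (median 3 MPa, σ = 0.30, clipped to
[1.2, 8]); P88 = P50 × U(1.35, 1.8); closure scale c at U(0.40, 0.70)·|P50|
for conservative (isohydric) species and U(0.85, 1.10)·|P50| for risky
(anisohydric) ones; shape b ~ U(1.5, 4); α lognormal (median 9), d₁
lognormal (median 1.2 kPa); plant conductance K lognormal (median 4·10⁻³
mol m⁻² s⁻¹ MPa⁻¹, giving soil-to-leaf drawdowns of a few tenths of a
MPa at typical fluxes); Vcmax25 ~ N(60, 10) with Jmax25 = 1.67 Vcmax25 and
Rd25 = 0.015 Vcmax25. In a default panel, species are flagged "no A
measured" and "predawn-only ψ" in the proportions 10/34 and 3/34 to
exercise the pipeline's substitution paths. The true closure midpoint is
available in closed form, ψ_gs50 = −c (ln 2)^(1/b).

What the generator does not emulate: diurnal dynamics and hysteresis,
plant capacitance, soil–root resistance networks, patchy stomatal
behavior, non-Weibull ("r-shaped") vulnerability curves, and
instrument-specific error structure. Passing tests therefore demonstrate
the pipeline's internal consistency and its operating characteristics
under a realistic but idealized steady-state leaf, not performance on any
particular field dataset.

## Problem sizes and numerical choices

Stochastic operating characteristics (selection rates, parameter
recovery, bias direction) are evaluated over 50 replicate campaigns of
n = 300 at the default noise level, with 8–12 optimizer starts per fit;
the acceptance script uses a 24-species panel with 12 starts and 20
dedicated selection replicates. Single-fit examples use the full 20-start
default. Tie-breaks and degenerate inputs: constant observations make R²
undefined (error, not NaN); SSE = 0 maps to a −∞ AIC sentinel with a
warning; constant covariates make bias slopes undefined; an empty
light/CO₂ filter falls back to unfiltered extremes with a warning; exact
predictor collinearity yields an ∞ VIF sentinel.
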