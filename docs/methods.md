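# Methods

## Model

Risk is age-specific log(incidence) (the same algebra applies to
logit(cumulative incidence)). A risk factor enters as a standardized
score Z ~ N(0, 1) acting multiplicatively on incidence:

    log(incidence) = μ + Δ·Z,

so log(incidence) is N(μ, Δ²) across people of the same age. Δ =
log(OPERA) — the log odds ratio per adjusted standard deviation — is
both the case–control difference in mean score and the standard
deviation of log(incidence); Δ² is the variance in risk the score
explains. Cases' scores are distributed N(Δ, 1) against controls'
N(0, 1) in the rare-disease limit, which yields the equal-variance
binormal AUC = Φ(Δ/√2) and the ROC form TPR = Φ(Δ + Φ⁻¹(FPR)).

Quartile ratios follow from E[e^{ΔZ}; Z > q] = e^{Δ²/2}·Φ(Δ − q) with
q = Φ⁻¹(0.75): the interquartile risk ratio is Φ(Δ−q)/Φ(−q−Δ) and the
upper-quartile-to-average ratio Φ(Δ−q)/0.25, bounded by 4 (a quartile
can hold at most four times its share of cases). Both closed forms are
pinned in the tests against adaptive numerical integration of the
quartile-conditional mean incidence, and the package's internal
consistency demands that regenerating the seven-metric profile from any
single metric reproduces the others to 1e-9 (IQRR is inverted by
bracketed Brent root-finding; all other inversions are closed-form).

A score correlated r between the members of a relative pair generates a
familial odds ratio exp(r·Δ²) — the identity that converts familial
aggregation into variance in risk. For rare diseases the familial odds
ratio and risk ratio are interchangeable; the simulation engine
quantifies the divergence outside that regime. On the covariance scale
cov = log(FRR), the classic twin model (equal environments; MZ score
correlation 1, DZ correlation (A/2 + C)/(A + C)) is linear:
cov_MZ = A + C, cov_DZ = A/2 + C, giving A = 2(cov_MZ − cov_DZ) and
C = 2·cov_DZ − cov_MZ. The AUC ceiling from all familial causes is
Φ(√(cov_MZ/2)); a genetic-only variant Φ(√(A/2)) is exposed separately
because the two are easy to conflate — the tabulated reference values
the tests pin correspond to the total-familial form.

## Parameters and defaults

* **Δ (delta)** — natural-log odds ratio per adjusted SD; ≥ 0 by
  convention. Protective inputs (OPERA < 1, AUC < 0.5) are flipped to
  the positive orientation and flagged rather than rejected, since
  direction is a labelling choice.
* **r (pair correlation)** — in [0, 1]: 1 for MZ twins, 1/2 for DZ
  twins/first-degree relatives, 1/4 for second-degree, under Fisher's
  additive model; for measured non-genetic scores it is the empirical
  MZ score correlation.
* **Baseline incidence** — simulation default exp(μ) = 1e-3, safely in
  the rare regime: probability capping stays negligible up to Δ ≈ 2.5.
* **Link** — `exponential-capped` (p = min(e^{μ+ΔZ}, 1)) is the native
  multiplicative-risk form; the fraction of capped draws is recorded and
  a warning raised above 0.1%. `logistic` is provided for non-rare
  settings and is the default for the liability-comparison curves, which
  extend to 50% prevalence where the pure exponential is infeasible. The
  comparison's qualitative conclusions hold under both links (tested).
* **Quadrature** — pair-concordance tables use 96 Gauss–Hermite nodes
  per axis; the baseline μ is calibrated by Brent root-finding against
  the *same* node set, so the table margins equal the requested
  prevalence to solver precision (~1e-13) by construction.
* **Tetrachoric inversion** — the equal-threshold bivariate normal CDF
  is evaluated exactly as Φ₂(h,h;ρ) = Φ(h) − 2·T(h, √((1−ρ)/(1+ρ)))
  via Owen's T (accurate to ~1e-15), and ρ solved by bracketed Brent
  iteration on (−1, 1) with tolerance 1e-12; tables at the perfect
  concordance/Fréchet boundaries are reported at the bracket edge with
  the convergence flag reflecting the residual.

## Design choices where the design was open

* **AUC radical.** The binormal AUC is implemented as Φ(Δ/√2). The
  internal cross-tabulation (Δ = 1.19 at AUC 0.80, Δ = 1.81 at 0.90) and
  the FRR-to-AUC conversion at r = 1 are consistent only with the √2
  form; Φ(Δ/2) would contradict every other identity in the package.
* **Quartile-ratio definitions.** IQRR is the ratio of quartile-mean
  incidences, not the ratio of risks at the quartile boundaries
  (e^{2qΔ}); only the former reproduces the pinned table (22 vs 5.0 at
  Δ = 1.19). UQRR's e^{Δ²/2} factors cancel analytically; the
  integration-oracle tests verify the cancellation numerically.
* **Falconer on the covariance scale.** The twin decomposition operates
  directly on log-FRR covariances rather than correlations; DZ/sibling
  correlations are derivable on request via (A/2 + C)/(A + C).
* **Negative components.** cov_DZ > cov_MZ is a model violation and
  always raises. 2·cov_DZ < cov_MZ (raw C < 0) raises by default;
  clamping to C = 0, A = cov_MZ is opt-in and flagged, because silent
  clamping biases A upward.
* **Correlated score combination.** The combined gradient is
  √(δᵀRδ) for joint coefficients δ under the linear-Gaussian
  log-incidence model — a reconstruction fixed by two requirements: it
  reduces to the Pythagorean rule at R = I and it matches the
  Monte-Carlo case-control oracle for jointly simulated scores. Marginal
  (separately fitted) gradients are explicitly converted first
  (joint = R⁻¹·marginal); the two conventions are kept apart in the API
  because they are easy to confuse. Attenuation with rising ρ holds for
  marginal inputs in the practically relevant range; near the collinear
  limit unequal marginals force sign-flipped joint coefficients and the
  quadratic form turns back up, so monotonicity is asserted only where
  it is a theorem (equal marginals on [0, 1); unequal marginals away
  from the collinear corner).
* **Woolf standard errors** for simulated pair odds ratios, with a 0.5
  continuity correction on zero cells, flagged on the estimate.

## What the simulations emulate — and what they do not

The Monte-Carlo engine draws standard-normal scores (bivariate for
pairs), applies the chosen link and samples Bernoulli outcomes — exactly
the generative model behind the closed forms, with a single seeded
generator per run (grid cells derive child seeds from one seed
sequence). Passing tests therefore demonstrate internal consistency of
model, closed forms and estimators, not realism of the model itself:
real risk scores need not be normal, real familial covariance need not
be age-constant, the equal-environments assumption is untestable from
MZ/DZ ratios alone, and case-control estimates of OPERA in real data
require covariate adjustment that is out of scope here. Published FRRs
are consumed as point estimates; their sampling error is not propagated.

Problem sizes: the unifying-equation sweep uses 2×10⁶ pairs per
(Δ, r) cell at baseline 1e-3 — at the smallest gradient this leaves only
a handful of doubly affected pairs, which is precisely why the
acceptance property asks 8 of 9 cells within 3 Woolf SEs rather than
all 9. Case-control oracles use 15–20k cases and controls, putting
~0.01–0.013 standard errors on the estimated gradient.

## Known limitations

* The printed reference cross-tabulation that the golden tests pin
  contains six familial-risk-ratio cells that are not consistent with
  its own Δ column at any single rounding provenance (worst case 26.8
  printed vs exp(Δ²) = 26.70); the strict half-last-digit golden test
  documents and fails on exactly those cells, while all agree within 1%.
* No extended-pedigree likelihoods, cohabitation-structured shared
  environment, parent-offspring/spouse models, or censoring-aware
  estimation of the underlying twin data.
* The exponential link leaves the model's rare-disease comfort zone
  above a few percent prevalence; use the logistic link there.
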