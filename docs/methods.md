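# Methods

This note records the statistical model behind each stage, the conventions
chosen where the classical protocols leave the procedure under-specified,
and what the synthetic-data tests do and do not demonstrate.

## Assay model and percent inhibition

An observation is a triple of absorbance changes at 405 nm over 30 min
(ΔA_sample, ΔA_blank, ΔA_control): the inhibited enzymatic signal, the
non-enzymatic substrate hydrolysis measured without enzyme, and the
uninhibited enzymatic signal. Percent inhibition is

    rate% = (1 − (ΔA_sample − ΔA_blank) / ΔA_control) × 100.

Conventions:

* ΔA_control is taken to be already blank-corrected (the blank subtraction
  is written only for the sample term); plate exports holding a raw control
  can set `control_is_blank_corrected=False` to subtract internally.
* Rates outside [0, 100] are preserved and flagged, not clipped — clipping
  is opt-in — so downstream regression sees measured values.
* "Complete inhibition" is rate ≥ 90%, inclusive.
* Doses ride on the prescribed-daily-dose Unit scale (1 U = one daily dose
  per mL; mU = 10⁻³ U, μU = 10⁻⁶ U). Scale conversions shift the decimal
  exponent exactly (via decimal arithmetic, not float multiplication), so
  0.1 mU/mL ≡ 100 μU/mL holds identically and round-trips are lossless.
* Replicate wells are averaged on the ΔA scale before the rate is formed;
  per-sample mean ± SD over replicate rates is also available. This
  aggregation order is a convention — with shared blank/control it matches
  averaging the rates.

## IC50 by semi-log linear regression

The estimator is ordinary least squares of inhibition% on
log₁₀(concentration), restricted to points with rates strictly inside a
working band (default 5–95%), and

    IC50 = 10^((50 − intercept)/slope).

Choices and their reasons:

* The 5–95% band keeps the regression on the near-linear midsection of a
  sigmoid dose-response; the band, and the log base (which cancels in the
  estimate), are configurable.
* The estimate is exactly equivariant under rescaling all concentrations,
  and exact on data that are truly log-linear.
* If the observed rates do not bracket 50%, the estimate is an
  extrapolation: it is returned with `bracketed=False` and a `UserWarning`,
  never silently.
* A non-positive slope (flat or inverted series) raises rather than
  returning a meaningless crossing.
* The reported `ci_halfwidth` is a delta-method ~95% interval propagated
  from the regression standard errors; it is a rough dispersion summary,
  not a calibrated coverage statement, for the small n typical of dilution
  series.
* A four-parameter logistic fit is deliberately out of scope: the semi-log
  line *is* the estimator under study. Its bias on Hill-shaped truth is
  bounded empirically in the tests (below).

## Inhibition kinetics and mode classification

Velocities on a substrate × inhibitor grid are modelled by the general
linear-inhibition rate law

    v = Vmax·S / (Km(1 + I/Ki) + S(1 + I/Ki′)),

which nests the four classical modes: competitive (Ki′ = ∞), uncompetitive
(Ki = ∞), noncompetitive (Ki = Ki′) and mixed. In double-reciprocal
coordinates the primary-line slope and intercept are both linear in I, with
x-intercepts −Ki (slope replot) and −Ki′ (intercept replot).

Estimation. Two paths are provided:

* `method="joint"` (default): since 1/v = c_s·(1/S) + s_s·(I/S) + c_i +
  s_i·I, both replot lines are estimated in a single weighted least-squares
  regression over all grid cells, with weights w = v² — the delta-method
  variance of 1/v under multiplicative velocity noise, which counters the
  well-known error amplification of the reciprocal transform at low
  velocities. With a 4 × 4 grid this leaves 12 residual degrees of freedom
  for the flatness tests.
* `method="two-stage"`: the classical textbook procedure — unweighted OLS
  per inhibitor level, then two 1-D replots. It gives identical answers on
  exact data but its replot t-tests have only n_I − 2 degrees of freedom
  (2, for four inhibitor levels), making noisy mode calls markedly less
  reliable; it is retained for comparability with manual analyses.

Flatness rule. A replot yields an infinite constant unless its slope is
significantly *positive* (one-sided t-test at `flat_pvalue`, default 0.05,
at the regression's residual df) **and** the implied constant K would
modulate the line by at least `min_modulation` (default 0.3, i.e.
I_max/K ≥ 0.3) over the dosed range. The one-sided test reflects the
physical constraint that replot slopes cannot be negative — a significant
negative fit is noise on a flat replot, and is treated as flat. The
modulation floor discards "significant" constants so large that the dosed
range could not have probed them. A significant positive slope paired with
a non-positive replot intercept is reported as inconsistent data.

Classification. With both constants finite, α = Ki′/Ki;
α ∈ [1/1.5, 1.5] is called noncompetitive (the band is a convention,
configurable), otherwise mixed with tendency competitive-like (α > 1.5) or
uncompetitive-like (α < 1/1.5). One finite constant gives the pure mode;
both infinite returns a no-inhibition sentinel rather than a mode. Under
the reference design (substrate 2/4/8/16 mM, inhibitor 0/2/5/7, 3%
multiplicative noise) the default path recalls each of the four modes in
≥ 95% of replicate grids — this operating point is what the defaults were
designed for; the two-stage path at the same conditions sits several
points lower.

No conversion of formulation doses to molarity is attempted (mixtures have
no molecular weight); Ki and Ki′ carry the dose scale of the input.

## Selectivity

At one matched dose, selectivity of a sample for the reference phosphatase
(PTP1B by default) over a homologue is the rate difference
`rate(reference) − rate(enzyme)`, with enzymes ranked by inhibition.
IC50-ratio selectivity would require full dose-response curves on every
panel enzyme, which a single-dose panel does not measure. The index is
antisymmetric under swapping reference and comparator, and adding an enzyme
never changes existing rows.

## PLS1 with leave-one-out PRESS

Composition matrices are wide and collinear (ingredients co-occur in fixed
recipes), so ingredient attribution uses univariate partial least squares
rather than ordinary least squares. The implementation is NIPALS-PLS1 on
mean-centred data, without Y-deflation (equivalent for a univariate
response): per component, w ∝ X_cᵀy_c (unit norm), t = X_c w,
p = X_cᵀt/(tᵀt), q = tᵀy_c/(tᵀt), deflate X_c ← X_c − t pᵀ. Original-space
coefficients are b = W(PᵀW)⁻¹q and b₀ = Ȳ − X̄·b.

* Preprocessing is mean-centring only; unit-variance autoscaling is
  available behind `scale=True` but off by default because dose weights
  share a common unit.
* The component count A minimises leave-one-out PRESS; ties break toward
  the smaller A (parsimony). Each fold fits one decomposition at A_max and
  reads off predictions for every smaller A (the first A components of a
  NIPALS fit equal the A-component fit), so the profile costs n fits; the
  test suite checks it against a literal refit-per-(A, fold) oracle to
  1e-10.
* Zero-variance columns are dropped with a warning and reported as "not
  estimable" (their contribution is absorbed into the intercept); an
  exactly constant response returns the trivial model (b = 0, b₀ = Ȳ)
  rather than an error.
* At A = rank(X) with full column rank the coefficients equal the ordinary
  least-squares solution; scores are mutually orthogonal; predictions via
  the latent route (Ȳ + Tq) and the coefficient route (b₀ + Xb) agree to
  numerical precision. All three are enforced in tests, plus agreement
  with scikit-learn's PLSRegression as an independent oracle (tests only).
* Ranking direction is explicit: on an IC50 response, lower is more potent,
  so the most negative coefficient ranks first; on a potency response the
  largest positive ranks first. Exact ties keep input order and are
  flagged.

On the five-formulation worked example (experimental IC50s 4.1, 4.3, 4.9,
6.3, 6.6 μU/mL vs model predictions 4.4, 3.9, 5.1, 6.3, 6.4), residuals are
−0.3, 0.4, −0.2, 0.0, 0.2 and R² = 1 − 0.33/5.272 ≈ 0.937 as computed by
`evaluate_fit` on those printed, rounded vectors; an R² computed from
unrounded predictions would differ in the second decimal, so no tighter
agreement is forced.

## Synthetic-data generator

The generators define the package's reference study conditions:

* **Kinetics grids**: rate-law velocities on substrate 2/4/8/16 mM ×
  inhibitor 0/2/5/7 (dose units), the factorial a bench protocol would run.
* **Dose-response**: a Hill curve (default slope 1), deliberately *not* the
  straight semi-log line the IC50 estimator assumes — the mismatch is part
  of what the recovery tests measure. Eight half-log dilutions centred on
  the true IC50 mirror a 0.001–0.1 mU/mL dilution series. Noisy rates are
  truncated to [0, 100] as a plate reader's derived quantities would be.
* **Screening plates**: absorbance triples constructed by inverting the
  rate formula, with a planted number of complete inhibitors (22 of 147 in
  the reference panel).
* **Formulation panels**: n = 40 formulations × m = 11 crude drugs; each
  formulation draws 3–6 ingredients with dose weights uniform on 0.5–3
  (grams per daily Unit), one drug carries dominant potency (1.0 vs 0.05
  background) and appears in about half the panel, and the response follows
  the reciprocal law IC50_j = scale / (x_j · potency) — potency pools
  additively, so doubling the only active ingredient halves the IC50.
* **Noise** is multiplicative Gaussian with a coefficient of variation
  (default 3% for velocity grids, 2% for dose-response recovery studies,
  5% for panels), because plate-assay error scales with signal. No
  replication or error magnitudes are published for assays of this kind at
  these conditions, so the cv values are conventions chosen at the level of
  a well-behaved colourimetric assay, not estimates. All generators are
  bit-reproducible under a fixed seed.

What passing tests show — and do not. Recovery tests demonstrate that each
estimator inverts its own generative model (plus the deliberate
Hill/semi-log mismatch) at realistic noise. They do not capture systematic
plate effects (edge effects, drift), correlated errors within a dilution
series, compound-level chemistry within a crude drug, or composition
matrices more collinear than the random sparse recipes generated here;
attribution accuracy on real panels with near-duplicated recipes will be
lower than the synthetic figure.

## Numerical choices and degenerate inputs

* NIPALS stops with a component-collapse error (reporting achieved rank)
  when a weight or score norm vanishes before the requested A; tolerances
  scale with the data norms.
* Replot constants are infinite (not huge floats) when flat; classification
  treats infinity exactly.
* The IC50 working band is an open interval; points exactly at 5% or 95%
  are excluded.
* Duplicate concentrations are rejected; unordered input is sorted.
* Problem sizes in the test and acceptance runs (100 replicates per mode,
  200 dose-response replicates, 100 panels) were chosen to estimate the
  recovery rates to a few percent while keeping the whole suite in the
  seconds range.

## Known limitations

* The mode classifier's operating point (≥ 95% per-mode recall) is specific
  to the reference design and 3% noise; sparser grids or higher noise push
  the call toward the flat/infinite decisions by construction.
* The semi-log IC50 estimator is biased when the sampled window is
  asymmetric around the midpoint of a steep Hill curve; the tests bound
  this under the reference dilution design only.
* PLS attribution identifies the dominant ingredient under additive potency
  pooling; synergistic or antagonistic ingredient interactions are outside
  the model class.
* Selectivity is a single-dose contrast, not a potency ratio.
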