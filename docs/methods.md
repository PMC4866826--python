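# Methods

## The equilibrium gating model

GIRK2 is modeled as a homotetramer with four equivalent Gβγ sites and four
equivalent Na⁺ sites at thermodynamic equilibrium. A macrostate is the
occupancy pair (i, j); the 5 × 5 = 25 states carry statistical weights

    w(i,j) = C(4,i) C(4,j) x^i y^j · n^{-i(i-1)/2} · b^{-j(j-1)/2} · η^{-ij}

with x = [Na⁺]/K_dn, y = m/K_db, and m the membrane Gβγ level in
Ni-NTA-lipid mole-fraction units (the experimental unit of membrane
density; the molar Gβγ density is m/3 for the His10-anchored construct).
The binomial factors count site combinations; each cooperativity factor is
a per-pair free-energy increment: 1/b per occupied Gβγ-site pair (so the
j-th state gains b^{-j(j-1)/2} relative to the empty channel, equivalent to
denominator exponents b⁶, b⁶, b⁵, b³, 1 across j = 0…4 in the one-ligand
polynomial), 1/n per Na⁺-site pair, and 1/η per occupied Na⁺-site/Gβγ-site
pair.

Two of these forms are modeling choices worth stating explicitly:

- **Cross-cooperativity form.** η enters once per occupied cross pair,
  η^{-ij}. This is the unique pairwise form under which full Na⁺ occupancy
  multiplies every stepwise Gβγ constant by η⁴ — i.e. a 6.3-fold affinity
  gain at η = 0.63 — and it makes the linkage symmetric (Gβγ occupancy
  raises Na⁺ affinity identically).
- **Na⁺ self-cooperativity.** n is fixed at 1 (Na⁺ titration of the
  Gβγ-saturated channel is hyperbolic), but it is kept as an explicit field
  so the assumption can be relaxed.

Activity is the population-weighted sum A = Σ c(i,j) θ(i,j) with
c = w/Z. Opening requires all four Gβγ: θ(i,j) = 0 for j ≠ 4, and θ rises
linearly with Na⁺ occupancy, θ(i,4) = θ₀₄ + i(θ₄₄−θ₀₄)/4. θ₄₄ = 1.19
exceeds 1 on the normalized-current scale (normalization is to saturation
with lipid-anchored native Gβγ, which evidently does not reach the model's
fully liganded limit); the θ are treated simply as free amplitudes.

Weights are evaluated in log space and normalized by the maximum before
exponentiation, so fits may push parameters to extremes
((m/K_db)⁴ b⁻⁶ ≫ 10¹²) without overflow; the conventions 0·log 0 = 0 keep
the zero-concentration axes exact rather than approximate.

## Limiting-slope analysis

At Na⁺ = 0 the model reduces to a one-ligand polynomial in m (the j = 0…4
terms above). If only the fully occupied state conducts, log A vs log m has
slope 4 at small m; if three Gβγ sufficed, the limiting slope would be
smaller. The implementation computes d ln A/d ln m by central difference
with relative step 10⁻⁴ in log space — discretization error O(h²) ≈ 10⁻⁸,
far below the 0.01 tolerance used in tests. The asymptotic regime is
m ≪ s·K_db with s = min(1/4, √(b/6), 4^{-1/3} b, b^{3/2}) (s ≈ 0.164 at
b = 0.30); evaluations outside it trigger a warning rather than an error,
since the quantity is still well defined.

## Calibration fits and activity matching

All 1-D fits (Hill, rectangular hyperbola, shared-n Hill family, Kd-vs-Na⁺
hyperbola) are weighted least squares through lmfit with a small multistart
over initializations. Weights are 1/SEM² when per-point SEMs are present,
uniform otherwise. **Standard errors:** when SEMs are supplied they are
treated as known measurement uncertainties and the covariance is *not*
rescaled by the reduced χ² (the `absolute_sigma` convention of
`scipy.optimize.curve_fit`); with 4–6 points and 2–3 parameters, rescaling
by a χ² estimated on 2–3 degrees of freedom makes ±2·SE intervals behave
like a t₃ statistic (≈ 86% coverage) rather than the nominal ≈ 95%.
Without SEMs the residual variance is estimated and the covariance scaled,
as usual.

The activity-matching step inverts the membrane titration curve: a
solution-titration point with normalized current r is assigned the mole
fraction m solving f(m) = r, where f is by default the fitted 25-state
model curve at the titration's Na⁺ level (a monotone PCHIP interpolant
through the membrane data is a config alternative). Points above the
membrane plateau are clipped to the top of the calibrated range and
flagged, never extrapolated. Response SEMs are propagated through the
inversion by the delta method, sem(m) = sem(r)/f′(m); because f′ → 0 at
the plateau this automatically down-weights near-saturated points, which
would otherwise dominate the isotherm fit with wildly amplified noise
(without this weighting, a noisy His4 run can misread the 3:1 anchoring
stoichiometry as 4:1).

The stoichiometry estimate fits rectangular hyperbolas to the His10 and
His4 mapped isotherms and reports the plateau ratio: His4 binds one
Ni-NTA lipid, so a ratio of ~3 means three lipids per His10-anchored Gβγ.

## Global surface fit

The 2-D titration surface (normalized current on the mole-fraction × Na⁺
grid) is fit by minimizing Σ w·(data − A)² where the 1/SEM² weights are
normalized to mean 1; this "scaled RSS" makes weighted and unweighted
objectives commensurate and is the figure reported for model comparison.
Points below 0.02 normalized current are excluded first (bilayer currents
at the lowest mole fraction are background-dominated) and logged. The
optimizer is trust-region least squares restarted from 16 log-uniform
draws within bounds (K_dn ∈ [1, 1000] mM, K_db ∈ [10⁻⁴, 1],
b, η ∈ [0.01, 3], θ ∈ [10⁻³, 2]), seeded; the first start is the geometric
midpoint of the bounds. Inside the objective the θ₀₄ ≤ θ₄₄ ordering is not
enforced (the optimizer may cross it smoothly); it is validated on the
returned optimum. Parameters ending within 1% of a bound, and parameters
structurally unidentifiable from the design (e.g. K_dn and η with a single
Na⁺ level), are flagged. The cooperativity comparison re-fits the
identical point set with b pinned to 1; by nesting its scaled RSS can
never be lower, and the steep rise between the mole fractions flanking
half-activation is the feature the constrained model systematically
under-predicts.

## Na⁺-amplification inference

Amplification is A(na_high, m)/A(na_low, m); under the reference
parameters it falls monotonically from ~10 at low m to ~2.2 at m = 0.03.
Inversion brackets m in [10⁻⁴, 3×10⁻²], verifies monotonicity on a
64-point grid, and solves by bisection to 10⁻⁶ relative; folds outside the
attainable range raise with the attainable bounds. Neuronal recordings at
27 mM internal Na⁺ are read against the model's 32 mM curve, matching how
the titrations were tabulated (pass `na_model_high=27` to interpolate the
model exactly instead). The measured fold is the **ratio of group means**
(matching how an "average fold" over cell groups is formed), with a
nonparametric bootstrap over cells (default 1000 resamples, seeded) giving
a percentile CI that is pushed through the monotone inversion to a CI on
the mole fraction.

Unit conversions: areal density = (m / NTA-per-Gβγ) / (area per lipid),
single-leaflet convention; the default head-group area is 0.83 nm², the
value consistent with ~1200 Gβγ μm⁻² at m = 0.003 and 3 lipids per Gβγ
(the more common 0.65–0.70 nm² is selectable, and every estimate
serializes its assumptions). Slab molarity spreads the areal density
through a 70 Å layer (the linear dimension of Gβγ). The fourth-subunit
dissociation constant is K_db·b³ in mole-fraction units, converted to
molarity with the fixed linear factor 0.1 M per mole-fraction unit
(anchored by 0.019 ↔ 1.9 mM). Lifetimes are 1/(k_on·K_d) for a single
complex and 1/(4·k_on·K_d) for the fully liganded channel, since any of
the four bound Gβγ dissociating ends the active state.

## Synthetic data

The generators emulate the study conditions: the titration grid uses the
experimental mole fractions {0.0001, 0.001, 0.0019, 0.0038, 0.0075,
0.015, 0.03} and Na⁺ levels {0, 4, 8, 16, 32} mM with 4 membranes per
point; solution titrations use the serial two-equilibrium scheme (solution
protein → Ni-NTA lipid at K_d 150 nM for His10, 5 μM for His4; anchored
protein → channel via the gating model), which reproduces the sub-maximal
~0.6 plateau at the 0.0019 lipid fraction; the GUV isotherm is 1:1 binding
with K_d 90 nM over doses {63…2000} nM and 6 vesicles per dose; neuronal
currents place cell-to-cell variability on the Gβγ level (log-normal, CV
20% by default, mean-preserving) with 10% multiplicative measurement
noise, 10 and 11 cells per group. Replicate noise is proportional (CV 5%)
plus an additive floor of 0.01 normalized-current units — chosen once to
approximate the graphically reported SEM scale, since no numeric replicate
tables exist. All generators are deterministic under their seed and report
per-point mean ± SEM; an `analytic_sem` switch reports the noise model's
exact SEM instead of the 4-replicate sample estimate, which the
estimator-calibration studies use so that their weights are correctly
specified (with sample SEMs from n = 4, ±2·SE coverage is t-limited below
90% for any estimator).

What the generators do **not** emulate: membrane-to-membrane versus
within-membrane error structure (noise is single-level), drift and rundown
in bilayer recordings, channel-count variability between neurons (cell
variability is placed entirely on Gβγ level), and any kinetics — the model
is strictly equilibrium. Passing recovery tests therefore demonstrates
estimator correctness under the stated noise model, not robustness to
structured experimental error.

## Numerical and interface choices

- Curves, surfaces and per-cell currents interchange as comma-delimited
  text with an explicit header and a `# units:` comment line; parameters
  and fit reports as YAML with a schema version. Numbers round-trip at
  full precision (`float_precision="round_trip"` on read).
- Degenerate inputs are rejected with specific errors: flat dose-response
  curves, all-zero isotherms, duplicate surface grid points, folds outside
  the attainable amplification range, flat Kd(Na⁺) profiles (flagged
  unidentifiable rather than fit).
- Recovery studies in the test suite use 200 replicates for the 1-D fits
  and the surface fit (3 multistarts per noisy replicate, which suffices
  since noisy optima are well separated from local traps at this noise
  level), keeping the whole suite around a minute on one core.

## Known limitations

- The model assumes four strictly equivalent, order-independent sites per
  ligand; sequential or conformational-selection schemes that produce the
  same binding polynomial are indistinguishable at equilibrium.
- The apparent Hill coefficient of a *solution* titration generated by the
  serial-binding scheme is ≈ 1.7–1.8, visibly below the coefficient of the
  membrane-fraction titration (~2.8–3): hyperbolic occupancy of the lipid
  compresses the dose axis. Composite solution-dose fits are therefore
  summarized by their K_d, not their steepness.
- The bootstrap CI on the fold ratio is percentile-based; with ~10 cells
  per group its coverage is near-nominal but slightly anti-conservative
  for strongly skewed spreads.
- The areal-density and slab-molarity conversions are deliberate
  order-of-magnitude bookkeeping: head-group area, 3:1 anchoring, single
  leaflet and 70 Å thickness are assumptions, serialized alongside every
  estimate.
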