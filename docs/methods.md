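# Methods

## The quantity and its observables

The electron requirement for carbon fixation, Φ_e,C (mol e⁻ (mol C)⁻¹), is
the ratio of the PSII electron transport rate to the chlorophyll-normalised
carbon fixation rate measured on the same water at the same irradiance.
Both rates are hourly and chlorophyll-specific, so the ratio is
dimensionless in time and biomass and compares across instruments and
stations.

ETR is computed from single-turnover FRRf observables in two algebraically
equivalent forms:

* **light/dark form**: ETR = E · σ_PSII′ · Fq′/Fv′ · n_PSII · Φ_RC · κ,
  with Fq′/Fv′ = (Fm′−F′)/(Fm′−F0′);
* **dark-reference form**: ETR = E · σ_PSII · (Fq′/Fm′)/(Fv/Fm) · n_PSII ·
  Φ_RC · κ, for instruments without a dark chamber.

When quenching leaves Fm′ = Fm, F0′ = F0 and σ′ = σ the two coincide
exactly — (Fm−F′)/Fm · Fm/(Fm−F0) = (Fm−F′)/(Fm−F0) — and this identity is
enforced by a randomised property test; it also pins the algebra, together
with the unit constant below.

κ converts Å² quanta⁻¹ · µmol quanta m⁻² s⁻¹ · mol RCII (mol chl a)⁻¹
into mol e⁻ (mg chl a)⁻¹ h⁻¹: κ = N_A · 10⁻²⁰ · 3600 · 10⁻⁶ / M, with the
chlorophyll-a molar mass M = 893 500 mg mol⁻¹ (configurable; this value
reproduces the conventional constant 2.43·10⁻⁵). Φ_RC, the electrons per
charge separation, defaults to 1 and is exposed as a parameter.

n_PSII is resolved from a spec: constants 0.0020 / 0.0030 mol RCII
(mol chl a)⁻¹ for eukaryote- / prokaryote-dominated communities, a measured
value, or an external-algorithm hook. Values outside [0.0010, 0.0060] warn
rather than error — natural variability spans roughly a factor of five, so
a hard bound would reject real data. Fluorescence-based n_PSII estimators
are accepted only through the hook; their internals are out of scope.

Spectral correction of σ_PSII to the actinic source is a scalar divisor
(1.75 and 1.5 are the conventional blue-LED-to-incubator factors used when
no measured correction exists) or a caller-supplied measured multiplier.
σ_PSII′ defaults to the dark-chamber value when no light value exists,
because dark-chamber estimates carry better signal to noise.

Negative computed yield ratios (sensor noise) are clipped to zero with a
warning and a `clipped` flag — never silently.

## Light context

K_d comes either from OLS on ln E(z) versus depth (surface point included;
the profile must attenuate, so a non-positive slope errors) or from the
euphotic depth as K_d = ln(100)/z_eu. Optical depth ζ = K_d·z harmonises
light history across studies; ζ < 4.6 flags the euphotic zone. Boundary
conventions, chosen once and documented: ζ = 4.6 is classified *not*
euphotic (the criterion is strict), and E:E_K = 1 is classified
*saturated* (the light-limited class is the strict ratio < 1). ln(100) is
kept at full precision internally; 4.6 appears only in the categorical
flag.

## Carbon uptake

The PE curve is the exponential-saturation (Webb) form
P(E) = Pmax·(1−exp(−αE/Pmax)) without a photoinhibition term — the minimal
parameterisation consistent with reporting (α, Pmax, E_K = Pmax/α);
photoinhibition is explicitly out of scope. Fitting uses bounded
Levenberg–Marquardt least squares with data-driven starts; recovery is
tested noiseless (exact) and at 2% noise (bias < 1% over replicates).
Daily simulated-in-situ uptake is distributed over daylight hours with a
user-supplied weight vector (weights ≥ 0, summing to 1); no respiration
model is applied. The weighting is a required input because source studies
rarely document their light regime in a recoverable form. mg C → mol C
uses 12.011 g mol⁻¹.

Φ_e,C is flagged against two bands: the theoretical 4–6 (4 e⁻/O₂ × PQ
1–1.5) and a configurable plausibility envelope [1, 60] with margin around
the span reported in field studies (≈1.15–54.2). Zero uptake raises an
undefined-ratio error rather than yielding infinity.

## Multivariate workflow

Order of operations: square-root transform the right-skewed covariates
(default set: salinity, temperature, chl a, NO₃⁻, PO₄³⁻) → normalise each
variable to mean 0, SD 1 (denominator n−1) → Euclidean resemblance →
ordination and clustering. Location variables (latitude, longitude, Julian
day) and Boolean method flags are excluded from the default resemblance
set because they inflate between-study distances and cannot enter
predictive algorithms; a configuration switch re-enables them.

**PCA** is SVD on the centred table with a fixed sign convention (largest
absolute loading positive). **nMDS** runs SMACOF non-metric scaling with
`n_restarts` random starts, returning the configuration with the lowest
Kruskal stress-1; stress-1 is recomputed from the final embedding via
isotonic regression so the reported number has a single, standard
definition regardless of the optimiser's internal normalisation.

**SIMPROF**: the observed profile is the ordered vector of pairwise
distances; the null ("no structure among these samples") permutes each
variable independently across the node's samples. A mean null profile is
built from `n_perm_profile` permutations; π is the summed absolute
departure of a profile from that mean; `n_perm_null` further permutations
give the null distribution of π, and p = (#{π_null ≥ π_obs}+1)/(n_perm+1).
Clustering is agglomerative with group-average (UPGMA) linkage —
configurable; UPGMA is the default of the standard software for this
workflow — and the tree is traversed top-down, splitting a node only when
its SIMPROF p < α (default 0.005). Nodes of fewer than 3 samples are
terminal and logged as untestable. Permutation counts default to 999+999:
the α = 0.005 stopping rule needs a p floor below 0.005, which 99-class
permutation schemes cannot reach. A 500-replicate calibration test checks
that the observed type-I rate of the whole traversal matches α on
homogeneous data.

**BEST/BIOENV**: for every non-empty variable subset up to
`max_subset_size` (default 5; hard cap 2¹⁵ subsets), the Spearman rank
correlation ρ is computed between the condensed environmental-subset
distance matrix and the condensed distance matrix of Φ_e,C (Euclidean on
the scalar phi values — the resemblance measure for a 1-D response).
Global significance permutes the sample labels of the environmental table
(default 99 permutations) and repeats the *full* subset search each time,
so the null distribution is that of the maximal ρ — the conservative
construction that accounts for selection over subsets. With 99
permutations the attainable minimum p is exactly 1/100, so the 1%-level
gate is p ≤ 0.01. Plain (unweighted) Spearman is used for the matrix
correlation; ties get average ranks.

**Spearman screening** reports ρ and two-sided p per predictor, pooled and
per grouping column, with 0.05/0.01 significance annotations; all-tied
variables report missing rather than a fabricated ρ.

Missing data are handled complete-case per analysis with dropped-row
counts logged; missing values are never zero-filled.

## Regional algorithms

Per-cluster models are ordinary least squares of Φ_e,C on **raw-scale**
variables — the deliberate dual-scale convention: resemblance and subset
selection run on transformed/normalised variables, while regression
coefficients carry physical units (e.g. mol e⁻ (mol C)⁻¹ per °C). Variable
choice comes only from the BEST stage; there is no stepwise selection.
Clusters with fewer than 5 complete rows are refused. Rank-deficient
designs error, naming the collinear variables.

The shipped registry stores each published algorithm's coefficients as the
printed strings (so serialisation round-trips the published equation
text), plus R² and significance bounds. One entry prints no intercept and
is stored with an explicit no-intercept flag rather than a guessed zero
correction. Predictions ≤ 0 are returned flagged invalid with a warning
(Φ_e,C is physically positive); fitted algorithms also record their
training envelope and warn on extrapolation.

## Synthetic data

The generator defines the package's test conditions. Environmental
covariates are per-cluster multivariate normal, truncated at physical
bounds by resampling (not clipping, to avoid point masses at zero). Φ_e,C
is a regional algorithm's linear prediction plus Gaussian noise, redrawn
while non-positive. Raw FRRf observables are synthesised by inverting the
ETR algebra: the target ETR (phi × a fixed uptake rate) fixes
σ′ · Fq′/Fv′; a cross-section is drawn from a typical field span
(400–900 Å² quanta⁻¹) and the efficiency factor solved for, then yields
with Fv/Fm in 0.45–0.65 and a 0.75–0.95 quenching factor are constructed
around it. Infeasible targets (requiring Fq′/Fv′ outside (0, 1]) error.

The default demonstration scenario has six clusters whose means are
hand-set plausible values for contrasting regimes (estuarine winter,
temperate spring bloom, oligotrophic surface and DCM, shelf summer,
upwelling). It is a fixture with deliberately clear separation; what the
generator does **not** emulate — instrument noise models, taxonomic
composition effects, within-study temporal autocorrelation, the messy
overlap of real water masses, non-normal covariate distributions — bounds
what passing tests show: they validate the machinery (recovery of known
structure and coefficients, calibrated error rates), not the field
variability of Φ_e,C itself.

## Problem sizes and numerical choices

Test simulations use a few hundred samples and 99–999 permutations;
regression-recovery checks use n = 200–500 with noise SDs of 0.05–0.1 on
the phi scale, sizes at which coefficient standard errors are comfortably
below the asserted tolerances. The SIMPROF calibration uses 500 replicates
of n = 30, p = 5 at 199+199 permutations and α = 0.05, giving a binomial
95% CI of ±0.019 around the nominal rate. All stochastic operations take
explicit seeds; the pipeline derives per-stage seeds from one master seed
and records them in its manifest, so a rerun is byte-identical.

## Known limitations

* Fq′/Fv′ measured after brief dark exposure can overestimate ETR (up to
  ~30% in cultures) when fast-relaxing quenching components reverse during
  the dark measurement; this is documented, not modelled.
* The PE form has no photoinhibition term; strongly inhibited surface
  curves will fit poorly (the residual diagnostic exposes this).
* Published regional algorithms are linear and carry low R² in several
  regions; the positivity guard and extrapolation warning are mitigations,
  not fixes.
* Biogeographic region boundaries are not derived from coordinates; the
  user chooses the algorithm.
* Spectral correction beyond scalar factors (full wavelength-resolved
  weighting) is provided only as a hook.
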