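# Methods

This note documents the models, default parameters and numerical choices of
the package, and what the synthetic-data tests do and do not demonstrate
about field data.

## Harmonization

Living trees enter the analysis at dbh ≥ 11 cm (boundary inclusive), lying
deadwood at ≥ 15 cm. The 15 cm threshold is applied to the **larger** end
diameter of a piece: the sources the rule harmonizes differ in which
diameter they record, and the larger-end rule is the conservative inclusion
choice. Standing deadwood (snags) is not subject to the lying-piece
threshold. Decay stages are mapped from protocol-specific codes onto the
common ordinal scale 1 (undecayed) … 5 (almost decomposed) via explicit
per-protocol lookup tables; unmapped codes are an error, never guessed.

Missing tree heights are imputed by predictive mean matching: within a
donor stratum (plot, falling back to site, forest type, then the pooled
inventory; a stratum must hold ≥ 5 height-observed trees) a monotone
saturating allometry

    h = 1.3 + a (1 − e^(−b·dbh))^c

is fitted by least squares (fallbacks: c = 1, then a curve through the
stratum mean); each missing height receives the *observed* height of one of
the k = 5 donors whose predictions are nearest the target's prediction,
drawn uniformly with a seeded generator (k = 1 gives the deterministic
nearest-donor rule). Imputed values are therefore always real observed
heights and never leave the donor range; observed heights are never
altered.

## Carbon stocks

Volumes (m³; diameters cm, heights m):

* living stem: `form_factor · π/4 · D² · H`, form factor 0.5 by default and
  configurable — the analysis treats the stem-volume model as a knob so a
  reproduction can substitute the original model;
* lying deadwood: truncated cone `π L/12 (D₁² + D₁D₂ + D₂²)`; pieces with a
  single recorded diameter are treated as cylinders (D₂ := D₁);
* standing deadwood: cone × 0.3, i.e. `0.3 · π/12 · D² · H`; standing dead
  trees from the tree inventory are treated as undecayed snags.

Biomass is volume × basic density (t/m³): species-specific where the
density table provides it, otherwise a wood-group default (coniferous 0.43,
broadleaved 0.58). Deadwood densities are additionally multiplied by a
decay correction indexed by (decay stage, position, wood group). The
shipped correction table is a package default constructed to follow the
shape of published density-reduction measurements for temperate species —
non-increasing in decay stage, steeper for broadleaves, gentler for
standing pieces — and is fully overridable from CSV
(`decay_corrections.csv`); analyses of real data should substitute
measured values. Carbon fractions: 0.48 of living biomass, 0.485 of dead
biomass. Totals are divided by plot area (ha).

## Deadwood typology and richness standardization

Deadwood type richness is the number of distinct (diameter class, position,
decay stage) combinations on a plot, out of 4 × 3 × 5 = 60 possible.
Diameter classes are lower-inclusive: [15, 25) → 1, [25, 35) → 2,
[35, 50) → 3, ≥ 50 → 4 (the interval notation of the field protocol is
ambiguous at the boundaries; lower-inclusive is the fixed convention here).

Species richness from sample-based incidence data is standardized for
unequal effort with the coverage-based framework for incidence frequencies
(T sampling units, frequencies Yᵢ, U = ΣYᵢ, Q₁/Q₂ uniques/duplicates):

* reference-sample coverage: `Ĉ(T) = 1 − (Q₁/U)·[(T−1)Q₁/((T−1)Q₁+2Q₂)]`;
* rarefied richness and coverage at integer t < T via the hypergeometric
  absence probability `C(T−Yᵢ,t)/C(T,t)`;
* extrapolated richness via the Chao2-type undetected richness
  `Q₀ = ((T−1)/T)·Q₁²/(2Q₂)` (Q₁(Q₁−1)/2 when Q₂ = 0) and coverage via
  `1 − (Q₁/U)·A^(t*+1)`.

Between integer unit counts both curves are interpolated linearly — the
combinatorial ratio is discontinuous in real t, so a continuous-t root of
`Ĉ(t) = target` is otherwise ill-defined exactly at a jump. The expected
richness per **site** (pooling the site's units) is evaluated at the effort
where coverage reaches 95%, and each plot's standardized richness is
observed plot richness / expected site richness. When the target coverage
is unattainable (no duplicates to estimate undetected richness from) the
asymptotic estimate is returned and a note logged. Solutions are clamped at
one sampling unit. The formulas are pinned by two independent
implementations (log-gamma vs telescoping products) that agree to < 1e−8,
and by exhaustive subset enumeration at integer efforts.

A caveat found while testing: the Good–Turing-corrected coverage estimator
is *not* monotone under duplicating a sampling unit (a duplicate containing
doubletons shrinks Q₂ and can lower Ĉ); only the aggregate tendency is
upward. The tests assert the correct aggregate property.

## Piecewise SEM

Each endogenous node y gets a linear mixed model on its parents with three
**crossed random intercepts** (site, forest type, management) and no random
slopes. Carbon stocks are natural-log-transformed before scaling (no
offset; the pipeline guarantees positive stocks and errors otherwise), then
every variable is z-scored, so coefficients are standardized and
scale-invariant (verified to 1e−8 under rescaling of raw columns).

The variance-components REML problem is solved by an own profiled
Newton-type optimizer: with H = I + Σ γₖ ZₖZₖ′ and γₖ = σₖ²/σ², the
criterion `(n−p)·log σ̂² + log|H| + log|X′H⁻¹X|` is minimized over log γ
with an analytic gradient, all linear algebra reduced to q × q problems
(q = total random levels ≤ a few dozen) via the Woodbury identity. A fit
costs ~3 ms, which is what makes the bootstrap and the calibration studies
tractable; statsmodels' MixedLM serves as the independent cross-check in
the test suite (agreement ~1e−7 on well-identified designs, and the solver
is required to dominate MixedLM's REML criterion on boundary cases, where
MixedLM itself may fail to converge). Grouping factors with a single
observed level are dropped from the random structure with a log note.
Coefficient p-values use t statistics with n − p residual degrees of
freedom; a Satterthwaite correction is deliberately out of scope, which
makes the d-sep test very slightly anticonservative (measured ~6% null
rejection at α = 5%, n = 300).

**Directed separation.** The basis set contains one claim per non-adjacent
ordered pair — topologically earlier variable as predictor, later as
response — conditioned on the union of both variables' parents. Because the
conditioning set contains only non-descendants of the response, every claim
is a valid d-separation (local Markov + weak union); this is verified
exhaustively against a graph-theoretic d-separation oracle on all DAGs with
≤ 5 nodes. Pairs declared as correlated errors are excluded, and pairs of
two exogenous variables are excluded by default (`include_exogenous_pairs`
toggles this): exogenous drivers are treated as freely covarying, as usual
in SEM. Each claim is tested by adding the predictor to the response's
mixed model and reading the slope's p-value; Fisher's
`C = −2 Σ ln pᵢ ~ χ²(2k)` summarizes them (no claims → C = 0, p = 1; p = 0
raises unless clamping is enabled).

**Default conceptual graph** (12 nodes, 53 edges): stand age, tree species
richness, mean annual temperature and annual precipitation (the last two
with a correlated error, their Pearson r reported) may influence all eight
endogenous nodes; mean dbh and deadwood type richness may influence both
carbon pools and the four taxa; both carbon pools may influence all taxa;
and vascular plants may influence saproxylic beetles. The implied basis set
has exactly 7 claims (df = 14): the two within-layer structure pairs and
the five untested taxon pairs. The graph is user-overridable from a plain
text file.

## Effect decomposition

Paths are enumerated exhaustively by depth-first search (graphs ≤ 12
nodes): direct = edge coefficient, indirect = Σ over paths of length ≥ 2 of
coefficient products, total = direct + indirect (an identity that holds
exactly in every bootstrap replicate, not just at the point estimate),
mediator effect through m = Σ over paths containing m. Bootstrap:
resampling plots with replacement **stratified by site** — plain resampling
can empty a random-effect level — refitting every node model, percentile
intervals at 95% (BCa deliberately not implemented; percentile is the
transparent default), `significant` = interval excludes 0, deterministic
under a fixed seed. Replicates in which another grouping factor collapses
to one level are redrawn (bounded retries; after that the degenerate
component is dropped by the fitter).

## Synthetic forest generator

The generator defines the study conditions: 301 plots in 16 sites (the
sources are inconsistent about 16 vs 19 site levels, so the count is an
explicit parameter), 5 forest types, 4 management regimes, balanced random
allocation of plots to levels of each factor. The causal layer is a linear
Gaussian SCM on the standardized scale: exogenous nodes are unit normal
(temperature and precipitation correlated, default −0.3), every endogenous
node is Σ coefficient × parent + three random intercepts (sd 0.2 each) +
noise. Residual sds are derived analytically from the implied covariance so
every node has **unit marginal variance** — the generating coefficients are
therefore exactly the standardized coefficients a correct fit should
recover. Default coefficients are ±0.3 on the reported-significant paths
and 0 on the remaining conceptual edges; default magnitudes are moderate by
design since the source's exact values are not available. Raw-scale columns
are fixed affine maps of the z-scores (log-linear for the carbon pools)
whose ranges span the observed study ranges (stand age ~5–212 y, mean dbh
~12–102 cm, living carbon ~0.5–360 t/ha).

The realization layer turns targets into raw data: tree lists with exactly
the target species count and mean dbh (multiplicative lognormal spread
rebased at the 11 cm threshold, so the post-filter mean is exact); deadwood
lists with exactly the target number of distinct type combinations (plus
Poisson-distributed duplicate pieces); stem density (~300/ha) and piece
size coupled to the carbon z-scores so realized carbon stocks correlate
with the generating ones; heights from a known allometry with 20% missing
to exercise imputation; and per-site incidence matrices with independent
Bernoulli detections whose logit is 1.1 × the taxon's generating z-score,
making observed plot richness monotone in the causal driver. Deadwood
targets are clipped to ≥ 1 so log-transformed carbon is always defined.

What the generator does **not** emulate: spatial structure and growth
dynamics, species-specific detection correlations, measurement error in
diameters, unbalanced site sizes, and real allometric variation between
species. Passing tests therefore demonstrate the correctness and
calibration of the estimators under the stated model, not robustness to
these field complications.

## Problem sizes and verified behavior

The simulation studies run at the scale of the field design: parameter
recovery at n = 300 plots × 100 replicates (≥ 90% of standardized
coefficients within ±0.1 of truth), goodness-of-fit calibration over 500
null replicates (rejection within 3–8% at α = 5%) and 150 replicates with
one omitted 0.4 edge (rejection ≥ 80%), bootstrap CI coverage of a true
indirect effect of 0.2 at n = 500, nboot = 199, 100 outer replicates
(≥ 90% coverage). The bootstrap default nboot = 999 is used in the worked
analysis. All of these are recomputed by `scripts/acceptance.py`.

## Known limitations

* Coefficient p-values ignore random-effect estimation uncertainty (no
  Satterthwaite/Kenward–Roger df), so d-sep tests run marginally hot.
* The decay-correction table and group densities are package defaults, not
  measured values; real-data analyses must override them.
* Only aboveground living and dead wood carbon is modeled — no soil,
  litter, or belowground pools.
* Global-estimation (covariance-based) SEM, latent variables and nonlinear
  paths are out of scope.
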