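# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `mfa13`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Network model and dialect

Models are written in a section-headed tabular text dialect (NETWORK,
LABEL_INPUT, FLUXES, MEASUREMENTS; unknown sections are preserved verbatim
with a warning). Each reaction line carries per-molecule carbon letter
strings (`T#abc + T#def -> H#abcdef`); a reaction with any letters must be
carbon-balanced (letter multisets equal across sides), and repeated
carbon-bearing substrates are written as separate occurrences with distinct
letters. Cofactors (ATP, NAD(P)H) carry no carbons and appear only in
stoichiometry; lumped biomass/sink reactions carry no transition and are
exempt from carbon balancing. Metabolite roles are inferred from usage:
substrate-only species are inputs, product-only species outputs, the rest
balanced. Half-reaction formulations of the non-oxidative pentose phosphate
pathway need no special machinery — 2- and 3-carbon moiety species are
ordinary metabolites in this dialect.

### The bundled fixture

`toyglyc` (10 reactions, 9 species) is the smallest network exercising the
label-routing mechanisms of a compressed core model: uptake, condensation
(T+T→H), reversible cleavage (H↔T+T), a scrambling split
(H→P+T+CO₂ with transition `abcdef → ab + cde + f`), a linear chain to
pyruvate, decarboxylation, and lumped sinks. Two design points matter:

- The scrambled 3-carbon unit (`cde`) straddles both parent halves of H.
  A split that returns the original unit unchanged would make every
  measured MID equal to the substrate MID at all flux values — no flux
  would be label-identifiable. With the straddling transition, positional
  tracer mixtures (any mixture containing 1-¹³C-glycerol) carry split-ratio
  information; pure 2-¹³C, pure 1,3-¹³C, and uniform tracers are provably
  uninformative for this split by position symmetry (hand enumeration),
  which the tracer-design module must and does discover.
- The condensation/cleavage pair forms a futile cycle with no labelling or
  rate signature — a deliberate structural-non-identifiability case
  mirroring parallel dehydrogenase/transport routes in real core models.

`toyglyc_energy` shares the carbon skeleton and reaction ids and adds
cofactor stoichiometry (uptake kinase −1 ATP, lower glycolysis +1 ATP
+1 NADH, scramble +2 NADPH, biomass −2 ATP −0.5 NADPH), a respiration lump
(NADH→2 ATP), and an ATP-maintenance drain. Its hand-derived max-ATPM
optimum is 2 × uptake (all carbon through lower glycolysis + respiration,
nothing to biomass or the scramble). The labelling fixture deliberately
omits cofactors: NADPH coupling would make the scramble flux
rate-identifiable and void the tracer-design tests.

## Label simulation

The EMU decomposition is built backwards from the target fragments
(full molecules of the measured species by default), stratified by size;
each stratum is one dense linear system (`numpy.linalg.solve` — at core-model
scale, ~10² reactions and fragments ≤ 6 carbons, sparse machinery buys
nothing). Reversible reactions are two unidirectional fluxes with the
exchange coordinate x ∈ [0,1) mapped to an absolute exchange flux x/(1−x).
Tracer purity is applied position-wise at the inputs (a nominally labelled
position is ¹³C with probability = purity); unlabelled positions are ¹²C in
this *tracer-only* space — natural abundance is a measurement-space effect
handled by the correction module, which keeps simulation and correction
composable. An EMU with zero total inflow makes the stratum singular and is
reported by name.

The verification oracle solves the *full* isotopomer balance system exactly
via the cumomer cascade: weight-w cumomer balances are linear given all
weights < w (condensation sources factor into strictly lighter cumomers),
so no fixed-point iteration is needed; isotopomer fractions follow by
Möbius inversion. Cost is O(2ⁿ) per species; networks with molecules above
12 carbons are refused with a size report. EMU and oracle agree to ~1e-15
on the fixture (the test bound is 1e-8).

## Isotopologue correction

The correction matrix column j is the expected measured mass-shift
distribution of a molecule with exactly j tracer-¹³C atoms: Binomial(j,
purity) for tracer impurity, natural ¹³C at the n−j untraced and any
non-tracer carbon positions, and (in low-resolution mode) the convolved
natural isotope patterns of H, N, O, S. The default is high-resolution
(Orbitrap-style, resolution 70,000 at m/z 400): only ¹³C interferes, no
mass leaves the 0..n window, and columns sum to 1 exactly; low-resolution
columns are truncated at the measured length. Inversion is non-negative
least squares with renormalization; the relative NNLS residual is reported
as a quality metric. The default isotope table is IUPAC (¹³C 0.0107),
configurable.

Unlabelled-inoculum carryover is inverted explicitly as
`(m − f·m₀)/(1−f)` with clip-then-renormalize (the correction is named in
the field's workflows but its formula rarely written; this is our choice),
with f = X_inoculum/X_sampling under exponential growth (0.025 for an
OD 0.025 inoculum sampled at OD 1).

**Error propagation.** Inverting the correction amplifies MS noise, and the
corrected entries are correlated through the matrix inverse. Per-entry SDs
are propagated as `sd_corr² = (C⁺)² sd_raw² / (1−f)²`; for Monte-Carlo
uncertainty the pipeline goes further and re-noises the *raw* vectors,
re-running the correction per replicate (a parametric bootstrap of the full
measurement pipeline), because independent perturbation of corrected
entries demonstrably under-disperses the flux sample — this was the single
largest contributor to CI under-coverage during development.

## Physiology

Exponential batch growth with constant-CV multiplicative error: the growth
fit is OLS on log X (exactly the weighted least squares of X₀e^{µt} under
that error model), with parameter covariance kept for downstream
propagation. The fit window is selected by greedy end-point trimming: a
point is dropped only if it improves R² by more than 0.005, so lag or
stationary phases are cut while lag-free noisy data keep the full series
(maximizing R² over all sub-windows would reward spuriously short windows
and inflate the variance).

q-rates use the linearity of M(t) in the biomass integral:
M = M₀ + (q/µ)(X(t) − X₀), fitted by weighted linear least squares with the
*fitted* trajectory as regressor (noise-free given the growth fit; an
observed-biomass regressor is available for model-doubt robustness but
injects the biomass CV into the slope). `sd_q` combines the regression
covariance with the growth-trajectory uncertainty evaluated at the
leverage-weighted time of the regression (using the full (log X₀, µ)
covariance — the two are anticorrelated, so naive addition would
overstate). Yields: Y_X/S = µ/(|q_S|·MW_S·10⁻³) g·g⁻¹; product yields
|q_P/q_S| in mol·mol⁻¹, converted with carbon counts and molar masses.
OD₆₀₀→gCDW conversion is a configuration constant (default 0.563 g per OD
unit); µ itself is conversion-independent.

Recovery at the study magnitudes (µ 0.13/0.22 h⁻¹, q_S 2.10/3.37
mmol·gCDW⁻¹·h⁻¹, 5 % noise) is ≲0.6 % (µ) and ≲1.5 % (q_S) median relative
error *provided the batch is sampled to near substrate exhaustion* — the
validation studies schedule 2-hourly early samples and ~hourly samples
through the late exponential phase scaled to each strain's batch length,
emulating the dense exponential-phase sampling such platforms use. With
sampling stopping at a quarter of the batch, no estimator reaches that
precision; the information simply is not in the data.

## Flux fitting

Steady state and fixed fluxes are eliminated by an orthonormal null-space
basis, so every candidate is balanced by construction. The objective
residuals are weighted MID entries (SD floor 0.01 mass fraction — prevents
chi-square blow-up from overconfident MS errors) and rates, plus (i) a
one-sided penalty (weight 10³) keeping irreversible nets non-negative and
(ii) a tiny ridge (10⁻³·θ/uptake) that gives structurally flat directions a
deterministic minimum without measurably biasing measured fluxes
(contribution ~10⁻⁶ SSR units). During optimization, slightly negative
irreversible fluxes are clamped to zero inside the simulator
(`strict=False`) so finite-difference steps at an active boundary see a
well-defined, continuous objective — without this the Jacobian collapses at
zero-flux optima.

Multi-start local least squares (`scipy.optimize.least_squares`, trf):
starts are random feasible flux vectors from LP sampling with the uptake
pinned to its measured value; best SSR wins, ties (<10⁻⁶) broken by lower
flux norm. dof = (number of measurement rows) − rank(J) at the optimum, the
rank computed by SVD with a 10⁻⁷ relative cutoff — this automatically
discounts structurally non-identifiable directions. Chi-square test at
95 %.

**Identifiability** is flagged structurally (fluxes with a component along
the Jacobian's null directions) and heuristically after Monte-Carlo (CI
width > 10× median width, or MC SD > 5× the point estimate). The structural
flag is primary: warm-started Monte-Carlo refits show zero scatter along
gradient-free directions, so an MC-only rule would mislabel them precise.

**Monte-Carlo (n = 100 by default):** each replicate re-noises the data
(through the raw-level resampler when provided), then refits twice — once
warm-started at the point estimate and once from a pooled feasible start —
keeping the better SSR. The second start matters: the likelihood of weakly
identified splits can be bimodal, and warm starts alone never hop basins,
shrinking the CIs. Replicates failing to converge are excluded (warning
above 20 %). CIs are 2.5/97.5 percentiles.

Replicate cultures are fitted separately; `average_replicates` reports
mean ± SD over the replicates that pass the chi-square test and errors when
none do.

## Tracer design

Candidate mixtures are the step-lattice compositions over the commercially
available glycerol tracers (1-, 2-, 1,3-, U-¹³C; optional unlabelled slot).
Each is scored by the linearized covariance: central-difference Jacobian of
the weighted residuals at the reference fluxes, Fisher matrix JᵀWJ,
eigendecomposition with a 10⁻⁹ relative cutoff; fluxes with weight on a
weak eigendirection get SD = +∞ (not an error), others
√(Σ coeff²/λ). SDs are per unit uptake — the SD < 1 selection threshold is
interpreted on normalized fluxes (the field reports normalized maps;
configurable). Ranking is two-stage: (n_precise desc, sum of precise SDs
asc), then the top tier (all mixtures attaining max n_precise) re-ranked by
the summed SD of a configurable pathway set; ties break on the
lexicographic mixture key, making the ranking input-order invariant. A
Monte-Carlo refit scorer verifies the linearization (agreement within ~20 %
for identifiable fluxes).

## FBA energy accounting

`fba_max_atpm` maximizes the maintenance flux by LP (HiGHS — deterministic,
so optima reproduce across runs) with per-flux bounds from the Monte-Carlo
CIs; unbounded fluxes default to [0, 1000] / [−1000, 1000]
mmol·gCDW⁻¹·h⁻¹. Infeasible bound sets raise with a greedily identified
conflicting subset; the pipeline falls back to bounding only the measured
exchange fluxes (logged) when a CI box excludes every cofactor-consistent
point. Cofactor balances list every reaction touching ATP/NADPH with signed
rate = coefficient × flux; production equals consumption for any feasible
vector, not only optima. Alternative-optimum degeneracy is addressed by
`flux_variability` ranges at the fixed optimum. GAME = |biomass ATP
coefficient| × biomass flux; NGAME = the ATPM flux. The pyruvate partition
is 100 × v(mitochondrial entry)/v(cytosolic production).

## Synthetic data

`ScenarioSpec` fixes ground-truth fluxes, tracer mixture (default 20 %
1-¹³C + 80 % 2-¹³C glycerol), physiology (µ 0.22 h⁻¹, inoculation OD 0.025,
2.5 g/L glycerol, uptake 3.37 mmol·gCDW⁻¹·h⁻¹ for the fast reference
culture), noise (OD CV 3 %, concentration CV 5 %, MID SD 0.01 — plausible
for plate-reader/NMR/Orbitrap data; the sources are silent on exact values)
and the sampling schedule (2-hourly to 16 h, hourly to 24 h, final 27 h
sample by default; clipped where the substrate would be exhausted, since
batch growth stops there). Randomness flows from one seed through spawned
substreams, making datasets bit-reproducible. Labelling data are simulated
tracer-only MIDs, convolved with natural abundance, mixed with the
unlabelled-inoculum fraction, and perturbed by Gaussian noise — truncated
at 0 and renormalized by default ("realistic"), or left raw ("gaussian")
for studies that require exactly specified noise (the chi-square
calibration presupposes the assumed error model; truncation and
renormalization are conservative for it). Strain panels apply named
multiplicative flux edits, re-projected to steady state by an L1-closest
LP with the substrate uptake pinned (so relative fold-changes equal the
nominal edits) and irreversibility respected; infeasible edits raise naming
the edit.

What the generator does *not* emulate: amino-acid-specific fragment
formulas and their differing correction structure (measured species carry
configurable formulas but the fixture uses small surrogates), flux changes
over the batch (strict stationarity is assumed), NMR spectral artefacts,
biological replicate-to-replicate variation beyond measurement noise, and
any regulatory coupling between fluxes. Passing recovery tests therefore
demonstrates the *estimators* are correct and calibrated under the stated
error model, not that real cultures satisfy it.

## Validation studies and problem sizes

The standing studies (`mfa13.studies`, shared by the test suite and
`scripts/acceptance.py`) use: 20 random feasible flux vectors × 3 mixtures
for simulator-vs-oracle equivalence; 20 synthetic scenarios × 100
Monte-Carlo draws for CI coverage (≥90 % of identifiable fluxes must cover
truth); 100 replicates for chi-square calibration (pass rate within
90–99 %); 200 seeds for physiology recovery; 3 amino-acid-like formulas ×
20 random compositions for correction round-trips. These sizes keep each
study within minutes on one CPU while leaving Monte-Carlo error well inside
the asserted margins.

## Known limitations

- Measurement weights are diagonal; correlations between corrected MID
  entries enter only through the bootstrap resampler, not the fit weights
  (standard practice, slightly miscalibrates the chi-square on corrected
  data).
- The linearized design scorer shares the fit's local character: strongly
  curved or multimodal likelihoods are only captured by the MC scorer.
- Percentile bootstrap CIs are first-order; boundary-adjacent fluxes
  (near-zero splits) keep slightly conservative/asymmetric intervals.
- The genome-scale-model derivation of the OD→CDW factor and the deposited
  core model's tracer optimum require external files and are out of the
  offline scope; the factor is a configuration constant here.
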