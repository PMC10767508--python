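# Methods

This note documents the models, conventions and numerical choices behind
`soilfate`, in the order the pipeline runs them.

## Degradation kinetics

The observed quantity is the fraction of the day-0 fortified amount
remaining at each sampling day; the canonical design samples days
0, 1, 2, 3, 7, 10, 21 and 30 after fortification at a nominal
100 ng/g. Four decline models are supported (SFO, FOMC, DFOP, hockey
stick; equations in the README). Useful identities, asserted in the test
suite: DFOP with g = 1 reduces to SFO(k1); HS with k1 = k2 reduces to SFO;
every valid parameterisation is non-increasing in time.

**Objective.** Unweighted least squares on the fraction-remaining scale.
The data carry multiplicative error, so weighted or log-scale fitting
would also be defensible; unweighted fitting is the convention in
degradation-kinetics practice and is kept here.

**Optimisation.** `scipy.optimize.least_squares` (trust-region reflective,
bounds respected) from a deterministic multi-start grid: rate-type
parameters start at {0.01, 0.1, 1}/d crossed, the DFOP pool fraction g at
{0.2, 0.5, 0.8}, FOMC α at {0.5, 1, 2} and β at {1, 10, 100}, and the HS
break time at the interior quartiles of the observed days. The converged
start with the lowest RSS wins; no random numbers enter the fitting path.
A series for which no start converges is returned with `converged=False`
rather than raising. Rate constants are bounded below at 1e-8/d, so a
constant (no-decay) series fits at the bound and its DT50 is reported as a
very large finite number, flagged as extrapolated.

**C0.** The initial amount is estimated by default — experiments fortify
at a nominal level but measure day 0 with the same error as any other
day. `fix_c0=` pins it instead; the choice changes the parameter count
and hence the χ² degrees of freedom. Replicate observations at the same
day are retained as separate residuals. Decay values reported below a
detection limit are kept at LOD/2 with a censoring flag (configurable at
load time).

**χ²-error level.** `err = 100/ō · sqrt(RSS / χ²_{0.95, n−p})` percent,
with ō the mean observation. This is the smallest relative measurement
error at which a χ² goodness-of-fit test at α = 0.05 would not reject the
fitted model; df < 1 is an explicit error, never a silent value.

**Selection rule.** SFO is fitted first and kept when its error level is
below 5 %; otherwise the three biphasic models are fitted and the
converged one with the lowest error level is returned. Ties at four
decimals resolve to fewer parameters first, then DFOP > FOMC > HS. A
winner above the 10 % error level is marked not accepted and excluded from
downstream statistics. All candidate fits travel with the result for
audit. Under the default 5 % measurement noise an SFO truth on the
canonical design clears the 5 % gate in roughly nine out of ten series —
the gate is deliberately strict, and the acceptance script reports the
realised rate at its seed.

**DT50/DT90.** Closed forms: SFO `ln2/k`; FOMC `β(2^{1/α} − 1)` (DT90
with 10^{1/α}); HS `ln2/k1` when reached before the break, else
`t_b + (ln2 − k1 t_b)/k2`. DFOP uses bracketed root-finding on the curve
to |Δt| ≤ 1e-6 d. A decline target that is never reached (zero rate, or an
HS plateau above the target) is reported as infinite persistence. FOMC
exponents that would overflow a double (shape parameter at its lower
bound on signal-free data) are treated as no decline, i.e. infinite DT50.
A DT50 beyond the last observed day is flagged as extrapolated — such
values can exceed the observation window many-fold and carry high
uncertainty, exactly as in the underlying experimental design.

## Mobility

Kd is computed from the leaching test as sorbed content over solution
concentration, `(amount_soil/m) / (amount_water/V)` in L/kg with the
design values m = 5 g dry weight and V = 10 mL. The normalisation by mass
and volume (rather than the raw amount ratio, which differs by the
constant V/m = 2) follows the definition Kd = Q/c; this is the single most
consequential unit convention in the package and is fixed here.

Nondetects: a fraction below its LOD enters the ratio at the LOD, making
a water-censored Kd a lower bound and a soil-censored Kd an upper bound
(the flag records which). Both fractions nondetect means no Kd — an
explicit error carrying soil, compound and replicate. Recovered mass
outside 50–120 % of the applied 400 ng triggers a quality warning, not an
error. Duplicate columns are pooled by the geometric mean of replicate Kd
values (the analysis lives on the log scale); arithmetic pooling is a
switch. Any log₁₀ Kd > 2 (Kd > 100 L/kg) is flagged as a rough estimate:
at that partitioning the water fraction approaches the detection limit
and the ratio becomes extrapolative.

Koc = 100·Kd/%OC. Organic carbon comes from loss-on-ignition organic
matter via the Van Bemmelen divisor 1.724 (configurable); the conversion
is a package convention, not part of the measured chain.

## Pedotransfer regression

Responses are log₁₀ DT50 (days) and log₁₀ Kd (L/kg). Candidate terms, in
canonical order: depth (1 = shallow/topsoil, 0 = deep), log₁₀ CEC
(meq/kg), log₁₀ Fe_ox, log₁₀ Al_ox (mmol/kg), log₁₀ clay, log₁₀ SOM (%),
and pH (never transformed). The depth coding is fixed by the sign
convention that a negative depth coefficient means faster degradation in
topsoil.

All 2⁷ = 128 subsets (including intercept-only) are fitted by OLS
(statsmodels) and ranked by `AIC = n·ln(RSS/n) + 2(p+1)` with the Gaussian
constant dropped — stated explicitly so rankings are
implementation-independent. Plain AIC, not AICc, is used; ΔAIC
comparisons are invariant to the dropped constant. An RSS at or below
1e-20 is an exact fit up to round-off; its AIC degenerates to −∞ and ties
resolve to the most parsimonious model, which makes noiseless recovery
well-defined. Rank deficiency is an explicit error naming the collinear
terms. More than 15 candidate terms are refused (combinatorial guard).

Per-coefficient two-sided p-values are starred at P<0.05 / P<0.01 /
P<0.005; non-significant terms stay in the model and are merely flagged,
and no multiple-testing correction is applied — both matching the
practice the models come from, and a caveat for interpretation. Pearson
screening of the (transformed) soil properties is attached as a
diagnostic; collinear pairs are annotated, not barred from co-occurring.
Pooled Kd values flagged as rough estimates are excluded from fitting by
default. Missing values are handled by listwise deletion per
response × compound, with counts logged.

The thirteen published coefficient sets (eight DT50, five Kd) are shipped
as CSVs under `soilfate/data/` and loaded verbatim — coefficients, stars,
R², adjusted R², se(Y), F and n. Kd models for DOX, FLUM and TMP do not
exist because most calibration soils held log₁₀ Kd above 2; the lookup
says so instead of failing silently. Predictions warn (not fail) when a
soil property lies outside the calibration ranges (pH 3.1–7.8, CEC
6.9–821 meq/kg, SOM 0.3–57 %, clay 1–53 %, Al_ox 1.2–152, Fe_ox
2–897 mmol/kg).

## Synthetic study generator

The generator's defaults are the study conditions: 29 soils, the
published per-property (min, median, max) anchors, the published
between-property Pearson targets on the analysis scale, the canonical
8-day decay design with 5 % multiplicative lognormal noise, and duplicate
leaching columns (400 ng applied, 5 g soil, 10 mL eluate, 1 ng LODs, 5 %
CV).

**Soils.** A Gaussian copula on the transformed scale (log₁₀ for all
properties except pH): normal scores with the target correlation (eigen-
value-clipped to PSD if needed) are mapped through Φ and then through a
two-piece triangular quantile per property — density rising linearly from
the minimum to the median and falling to the maximum, each half carrying
probability 1/2. This respects the published bounds exactly, hits the
median exactly in quantile and preserves the strong skew of properties
like Fe_ox (2/88/897) without inventing distribution families beyond the
three published anchors. Monotone marginal transforms perturb Pearson
correlations slightly (rank correlations are preserved); empirically the
SOM–CEC correlation realises ≈0.88 against the 0.89 target at n = 10 000,
within the generator's stated ±0.03 contract, so no copula recalibration
is applied. Depth class is an independent Bernoulli draw; the shallow
fraction defaults to 0.5 because the source set mixes topsoil and subsoil
samples without published counts.

**Truths.** Per-soil true log₁₀ DT50 and log₁₀ Kd are drawn from the
published pedotransfer models with Gaussian residuals of magnitude se(Y);
compounds without a published Kd model (DOX, FLUM, TMP, ENRO) use their
published median log₁₀ Kd with a between-soil spread of 0.2. Decay truths
are SFO with k = ln2/DT50 (configurable to any supported model); ENRO has
no decay data, matching the source study. Leaching amounts follow the
equilibrium split `fraction_in_soil = Kd·(m/V)/(1 + Kd·(m/V))`, which
`compute_kd` inverts exactly in the no-noise case.

**Reproducibility.** One study seed spawns named substreams (soils,
truths, decay, leach) via `numpy.random.SeedSequence`, so each stage is
independently regenerable and the full bundle is byte-identical under a
fixed seed.

**What passing tests do and do not show.** The generator reproduces
distribution-level structure (ranges, medians, correlations, noise
magnitudes), not record-level reality: no LC-MS/MS matrix effects, no
soil-microbiome covariates, no temperature/moisture dynamics, no manure
co-application, and between-compound correlations within a soil only
insofar as they arise from shared soil properties. Recovery results
therefore validate the computational chain under its own assumptions;
they do not certify the published coefficient values themselves, whose
underlying per-soil measurements are not public.

## Problem sizes

The test suite and acceptance script use the study's own scales: n = 29
soils per regression dataset, 100 replicates for kinetic recovery, 200
for coefficient recovery, 20 datasets for the subset-search/enumeration
agreement, 1 000 parameter draws for closed-form/numeric DT50 agreement
(25 for the DFOP grid scan, whose 1e-4-day brute-force grid is the
expensive oracle), and n = 10 000 soils for copula calibration checks.

## Known limitations

- The χ²-selection rule is a hard gate; fits with error levels just above
  a threshold flip the selected model, so summaries near the gate are
  sensitive to noise realisations.
- Censored Kd values enter summaries at their LOD-substituted value; no
  distributional (e.g. maximum-likelihood) censoring model is used.
- Plain AIC on n ≈ 29 with up to 7 terms is mildly liberal; AICc would
  penalise large subsets more and can reorder rankings.
- The stage CSVs encode units in column names (`dt50_days`,
  `kd_l_per_kg`) rather than a separate units row, keeping them directly
  machine-readable.
- No formation/decline of transformation products, no Arrhenius/Walker
  temperature–moisture corrections, no Freundlich nonlinearity (n ≠ 1),
  and no regularised or mixed-effects regression variants.
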