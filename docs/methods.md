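# Methods

## 1. The reduced hepatocyte network (`liverkin`)

### Scope and structure

The kinetic model is deliberately *lumped*: one representative reaction per
central pathway rather than molecular resolution. Published genome-scale
hepatocyte models resolve hundreds of reactions; their rate laws are not
reproducible from summary publications, and this package must be
self-contained and testable. The packaged network has 33 reactions over 10
internal pools (glucose-6-phosphate, glycogen, pyruvate, acetyl-CoA,
acyl-CoA, triacylglycerol, glutamate, ammonium, ATP, and an
inter-membrane-space proton lump), covering the 20 classically numbered
pathways of central liver metabolism — glycogen, fructose and galactose
handling, glycolysis, gluconeogenesis, both pentose-phosphate branches,
fatty-acid synthesis and β-oxidation, triacylglycerol synthesis and
lipid-droplet turnover, VLDL export, TCA cycle, oxidative phosphorylation,
urea cycle, ethanol oxidation, ketogenesis, glutamate/glutamine handling,
alanine/serine utilisation and cholesterol synthesis — plus a fatty-acid
uptake transport group.

Rate laws are irreversible or reversible Michaelis–Menten forms, one
mass-action option, and one Goldman–Hodgkin–Katz (GHK) flux for the
mitochondrial proton leak (fixed membrane potential 0.15 V; the V → 0
singularity is removed by series expansion). Every rate is proportional to
its maximal activity, so the whole flux field is homogeneous of degree one
in the V_max vector — the property that makes proteome scaling
(`vmax = ratio × vmax_ref`) meaningful and is asserted to 1e-8 in tests.

Stoichiometric coefficients are lumped-carbon bookkeeping (carbon is not
conserved exactly across lumps), but **nitrogen is conserved exactly** by
construction: every metabolite carries an integer nitrogen content and the
loader rejects any reaction that violates the balance. At steady state this
forces nitrogen influx (ammonia + amino-acid lumps + glutamine uptake) to
equal efflux (urea + glutamine synthesis) to solver precision, which the
test suite checks at 1e-8.

### Regulation

Hormonal control is a single phenomenological phosphorylation state
γ(G) = 1/(1 + (G/G₁ᐟ₂)ʰ) with defaults G₁ᐟ₂ = 6 mM, h = 4 — γ ≈ 0.94 at
3 mM (fasted, glucagon-dominated) and ≈ 0.06 at 12 mM. A phospho-sensitive
enzyme runs at `γ·v_p + (1−γ)·v_d` of its V_max. Plasma free fatty acids
follow a descending sigmoid between a fasted plateau of 1.0 mM and a fed
plateau of 0.2 mM with the same midpoint. Numeric transfer-function
parameters are this package's documented defaults, as are the fixed diurnal
plasma means (lactate 1.5, amino-acid lump 3.0, ammonia 0.2, glutamine 0.6,
fructose and galactose 0.1, ethanol 0.01 mM).

Four feedback terms are structural stability devices as much as physiology:
glucose-6-phosphate inhibition of glucokinase, acyl-CoA inhibition of
fatty-acid uptake, triacylglycerol inhibition of DGAT, and ATP-dependence
of the sodium-coupled amino-acid/ammonia transporters. Each eliminates a
regime in which a pool could grow without bound or the network could lock
into an ATP-starved state (fuel uptake needs ATP; without these terms a
low-ATP state can become self-consistent, with nitrogen influx exceeding
the ATP-limited capacity of urea synthesis). With them, a unique
physiological steady state exists for all abundance perturbations tested
(30 synthetic cohorts, CV up to 0.2, zero solver failures).

### Reference parameterisation

Reference V_max values were calibrated once so that the all-ones instance
reproduces the magnitudes reported for healthy liver: gluconeogenesis near
−50 µmol/g/h (attained at 3 mM glucose), fatty-acid uptake ≈ 35–40,
tag synthesis ≈ 13, VLDL export ≈ 5, cholesterol synthesis ≈ 0.2, ketone
production ≈ 29 (2:1 acetoacetate:β-hydroxybutyrate), ammonia uptake ≈ 17,
urea ≈ 19 µmol/g/h, maximal tag content ≈ 36 mM, and net glucose exchange
crossing from release to uptake near 8 mM plasma glucose. These magnitudes
document realism; no test asserts them numerically.

### Solver

Steady states solve `S_int · v(c) = 0` by damped Newton in
log-concentration space (positivity for free), finite-difference Jacobian,
backtracking line search and a log-space step cap of 2; hard starts fall
back to LSODA relaxation of the log-space kinetics followed by a Newton
polish. Acceptance requires `|S·v|_∞ < 1e-9 · scale` where the scale is the
largest flux floored at 1e-3 of the largest V_max (so degenerate all-zero
systems face a finite bar); the tolerance is re-evaluated and re-polished
at the solution. The glucose grid (default 3–12 mM, step 0.5) is traversed
with warm starts; warm and cold starts agree to 1e-7 in tests. Capacity
extrema break ties toward the lowest glucose grid point.

## 2. Wave inversion (`waveinv`)

### Conventions

Spatial frequencies are cycles per metre throughout. A damped plane wave is
`u(s) = exp(i·2πf/SWS·s − κ″s)` along propagation coordinate s, and
**PR ≡ f/κ″**. This algebraic definition of PR is a package choice (the
penetration-rate literature rarely writes one down); it makes liver-like
media (SWS ≈ 1.6 m/s) carry PR ≈ 1 m/s, the magnitude reported in vivo.
The filter cutoffs 250 / 15–300 m⁻¹ are interpreted as cycles-per-metre
spatial frequencies; typical liver wavenumbers (25–60 cycles/m at
40–80 Hz) sit comfortably inside the band.

### Estimator

Processing is slice-wise 2-D. All spectral filters operate on mirror-padded
arrays: FFT filtering assumes periodicity, and the wrap-around
discontinuity of a wave decaying by e⁻⁵ across the field of view otherwise
rings across the whole slice. The chain per frequency and encoding
direction:

1. temporal-harmonic extraction from the 8 phase offsets (fundamental DFT
   bin, DC rejected, cosine amplitude preserved);
2. Butterworth low-pass (order 3, 250 m⁻¹) of the complex field;
3. directional decomposition: radial Butterworth band-pass (order 3,
   15–300 m⁻¹) times raised-cosine angular wedges (8 directions) that form
   an exact partition of unity, so components sum to the band-passed field;
4. per wedge, phase and log-amplitude gradients are taken **on the
   low-passed field** (wrapped central differences immune to 2π jumps, and
   np.gradient of ln|u|) and projected on the wedge's nominal direction;
   the wedge components themselves serve as direction, amplitude-weight and
   dominance oracles. This split matters: the 15 m⁻¹ high-pass truncates
   the Lorentzian spectrum of a strongly damped wave and biases its
   apparent decay low, so κ″ measured on band-passed components
   systematically overestimates PR;
5. interference ripple is suppressed by a dominance-weighted local average
   over half the dominant wavelength (weights (amplitude·dominance)⁴,
   edge-extended Gaussian); voxels below 20% relative amplitude or 60%
   wedge dominance, or within 6 mm of the slice border, carry zero weight;
6. amplitude-weighted compounding over frequencies, encoding directions and
   wedges: SWS = Σw·(f/k′)/Σw with k′ < 1 cycle/m zero-weighted, PR
   likewise with κ″ < 1 m⁻¹ masked — an undetectably attenuating voxel is
   masked NaN, never reported as infinite PR.

The literal per-component estimator (k′ = |∇φ|/2π of a component's phase,
weight = component amplitude) remains available as `wavenumber_maps` and is
what the unit tests of the operator exercise; `invert_wavefield` uses the
production path above.

Verified recovery on damped-plane-wave phantoms at all five acquisition
frequencies (two opposed propagation directions, 48×48 voxels at 2 mm,
truth SWS 1.6 m/s, PR 1.0 m/s): noiseless errors 0.4% (SWS) and 0.5% (PR);
at SNR 10, ≤ 2.7% and ≤ 2.3% over seeds. Halving the voxel size changes the
ROI-mean SWS by < 1%.

## 3. PET SUV (`petsuv`)

`SUV = A·W/(ID·d)` with `d = 2^(−Δt/T½)`, T½ = 109.77 min. The decay
factor divides the denominator, i.e. corrects the injected dose to the
scan start; kBq/MBq and kg/mL cancel under the standard 1 g/mL
tissue-density convention. Only physical decay is corrected; residual-dose
corrections are out of scope.

## 4. Statistics (`capstats`)

* Row-wise z-scoring (each metabolic function to mean 0, SD 1; constant
  rows map to zeros with a warning), then agglomerative clustering with
  Euclidean distance and average linkage, tree cut at k = 2. Distance and
  linkage are documented package defaults.
* The normality gate is a deterministic quantile–quantile criterion: ordered
  values against normal quantiles at plotting positions
  (i − 0.375)/(n + 0.25), a least-squares probability-plot reference line,
  and pointwise bands `±1.96·slope/φ(zᵢ)·√(pᵢ(1−pᵢ)/n)` from the asymptotic
  order-statistic standard error; a sample is "normal" iff ≥ 95% of points
  fall inside. The OLS line (rather than a quartile line) keeps the gate
  calibrated at the study's group sizes (false non-normal rate ≈ 0.2% at
  n = 10) and agrees with a Shapiro–Wilk oracle on the seeded reference
  samples in the test suite.
* Two-sample comparisons use the unpaired two-sided t-test when both groups
  pass the gate, otherwise the Mann–Whitney rank-sum test — a signed-rank
  test is undefined for unequal independent groups. Two identical constant
  groups return p = 1, flagged degenerate.
* Pearson r with a two-sided t-distributed p, OLS slope/intercept and 95%
  confidence bands for the mean response.
* Stiff/soft split at SWS 1.6 m/s, boundary values assigned stiff — the
  inclusive rule is the one consistent with a 10/9 split of the packaged
  cohort, which contains one animal at exactly 1.60 m/s.
* No multiple-testing correction anywhere; every report states that its
  p-values are raw.

## 5. The synthetic cohort (`synthcohort`) — what it does and does not show

Proteomes: i.i.d. log-normal abundances per enzyme (mean-preserving
parameterisation, common CV) around cluster means; the two metabolic
clusters are multiplicative pathway-level shifts (default ±20% — cluster 1
up in fatty-acid uptake/turnover, β-oxidation, ketogenesis and VLDL export,
down in gluconeogenesis, lipogenesis and cholesterol synthesis, cluster 2
mirrored). Inter-animal abundance CV is a free design parameter (default
0.1; no published value exists for it). Samples alternate between clusters.

Wave fields: superpositions of damped plane waves with prescribed SWS(f)
and PR plus complex white Gaussian noise at a stated power SNR — the same
local model the inversion assumes, by design: the phantoms test the
estimator chain, not the physics. Default geometry mirrors the in vivo
setup: two opposed drivers (propagation ±x), 48×48 voxels at 2 mm (a
~10 cm abdominal field of view), five frequencies 40–80 Hz, 8 phase
offsets. No reflections, mode conversion, compressional contamination,
breathing motion or realistic organ geometry are simulated, so the recovery
bounds established here are upper bounds on real-data accuracy, not
estimates of it.

PET: uniform or user-shaped activity phantoms with known dose/weight/delay;
SUV recovery from them is exact by construction and only validates the
formula plumbing.

Cohort bundles: per-animal true SWS/PR/SUV/weight/glucose drawn around the
published cohort moments (SWS 1.59 ± 0.10, PR 0.99 ± 0.11, SUV 2.72 ± 0.27,
weight 3.23 ± 0.26 kg, glucose 153 ± 24 mg/dl); PET restricted to a
10-animal subset as in the study design; optionally the PR means of the two
metabolic clusters are separated by a configurable number of PR standard
deviations, tying viscosity to metabolism so the statistical layer's power
can be measured (with a 2-SD separation and groups of 9/10, the unpaired
comparison detects the difference at p < .05 in ≈ 98 of 100 replicates).

## 6. Problem sizes and determinism

Default problem sizes — 19 samples × 19 grid points for the kinetic stage
(≈ 0.7 s), 48×48×2 voxel fields at five frequencies for the inversion
(≈ 0.1 s per animal), 100 replicates for power estimates — keep a full
synthetic study under a minute on one core. All randomness flows through
`numpy.random.default_rng(seed)`; pipeline outputs embed the config hash
and seed, and re-running a config reproduces every artifact byte for byte.

## 7. Known limitations

* The lumped network's capacities are realistic in magnitude but not
  sample-accurate against any deposited proteome; analyses that need the
  full molecular-resolution liver model are out of scope.
* The exact membership of the published 16-capacity panel is not fully
  enumerable from study summaries (13 are named); β-hydroxybutyrate
  production, glycogen storage and lactate exchange complete the panel here
  as a documented choice.
* PR estimation assumes locally one dominant wave per wedge; media with
  strong standing-wave patterns would lose PR coverage (masked voxels)
  rather than degrade silently.
* The qq normality gate is a calibrated reimplementation of a visual
  procedure; borderline samples (mild tail outliers at n ≈ 10) pass it
  that a formal Shapiro–Wilk test would reject.
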