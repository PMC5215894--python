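# Methods

This note records the package's scientific and numerical choices: the models
it implements, the defaults and why, what the synthetic-data generator does
and does not emulate, and the known limits of what the tests demonstrate.

## Stoichiometric model

The packaged network describes central energy metabolism of a mammalian cell
driven by one glucose input: glycolysis (G1–G10, with GAPDH as G6),
pyruvate→acetyl-CoA processing (PYP), the TCA cycle (TCA1 = citrate synthase
… TCA9 = malate dehydrogenase, TCA10 = aspartate transaminase), the oxidative
and non-oxidative pentose phosphate pathway (PPP1–PPP8), a five-step electron
transport chain (complexes I and II, III, IV, ATP synthase) with explicit
ubiquinone/ubiquinol, FAD/FADH₂, cytochrome-c and matrix/intermembrane proton
pools, anaplerosis (pyruvate carboxylase, alanine transaminase), lactate
dehydrogenase, and a lumped glutaminolysis step. Water, free cytosolic
protons and elemental/charge balance are deliberately omitted: the matrix
encodes pathway stoichiometry, not elemental bookkeeping, and the ETC proton
counts are coarse pump ratios rather than measured stoichiometries.

Roles: *internal* metabolites are pathway intermediates balanced at steady
state in the exemplar LPs; *external* metabolites are net substrates/products
whose accumulation the network does not balance — glucose, O₂, CO₂, ammonia,
lactate, the amino-acid pools (Glu, Gln, Asp, Ala), the CoA pool, phosphate,
and both nucleotide redox/energy couples that exchange with processes outside
the model (ATP/ADP, NADP⁺/NADPH). Classifying ATP/ADP and NADP⁺/NADPH as
external reflects that most of their turnover (biosynthesis, transport,
glutathione recycling) happens outside central carbon metabolism; holding
them internal would force the LP to balance them with the few reactions
present and suppress realistic pathway use.

Reduction to a measured panel: rows for unmeasured *external* metabolites are
dropped (nothing can be said about them); unmeasured *internal* rows
(1,3-bisphosphoglycerate, the 6-phosphogluconolactone intermediate) are kept
with accumulation constrained to zero, preserving pathway connectivity; ETC
carriers are kept, constrained to zero, and given the lowest weight, because
the cell tolerates very little net change in these membrane-bound pools yet
their balance is the least data-supported part of the model. All reaction
columns survive reduction. With the packaged measurable panel the reduced
matrix plus one synthesis column is 48 x 39 with full column rank, so the
weighted BVLS has a unique minimizer.

## Synthesis columns

A biosynthetic product is represented as a single irreversible column that
consumes precursors and produces nothing inside the network. For proteins,
every residue is assigned to the biosynthetic family of its carbon skeleton:
Ser/Gly/Cys → 3-phosphoglycerate; Ala/Val/Leu → pyruvate; Glu/Gln/Pro/Arg →
α-ketoglutarate; Asp/Asn/Thr/Met/Lys → oxaloacetate; Ile half pyruvate, half
oxaloacetate. Phe/Tyr/Trp/His derive from chorismate/PRPP routes outside
these four precursors and are skipped with a reported count. The mapping is
a plain table and can be replaced wholesale by passing `mapping=`.
Coefficients default to fractions summing to one ("ratiometric" composition);
a per-molecule raw count option exists. Only relative proportions shape the
LP profile, and the unit scale keeps the LP's v ≤ 1 cap meaningful.

The packaged FASTA contains **synthetic stand-in sequences** (filename
`synthetic_pcm_proteins.fasta`): 400-residue sequences drawn once from
composition profiles typical of collagen II (Gly-/Pro-rich), collagen VI,
aggrecan (Ser/Thr/Glu-rich) and albumin (Glu/Lys/Leu-rich). They are
surrogates with realistic amino-acid composition, not database sequences;
swap in real FASTA records (`--product fasta:<file>`) for real work.

## Accumulation, variance, weights

Rates use replicate group centers; the default center is the median, which at
n = 4–5 blunts single outliers (the mean is available and is what the
noise-free round-trip uses, since medians of symmetric noiseless replicates
coincide anyway). The variance attached to a rate is the Welch variance of
the mean difference divided by (t₁−t₀)²; pairing the median center with the
mean-based variance is a documented approximation rather than a
median-specific estimator. Weights are reciprocal variances. Two
conventions worth noting:

* The weight multiplies the *row* (S_i and Δ_i), so squared residuals carry
  w², i.e. 1/σ⁴ — stronger-than-GLS emphasis on precise rows. This is the
  procedure implemented deliberately; argmin is invariant to rescaling all
  weights, and tests assert that invariance.
* Zero sample variances are snapped to exact zero when they sit at
  floating-point noise level (identical replicates can yield var ≈ (x·ε)²,
  which would otherwise produce absurd 10²⁵-scale weights). A zero-variance
  row's weight is capped at the largest finite measured weight by default; a
  table where *every* variance is zero is degenerate and raises, except in
  the sensitivity pipeline where uniform unit weights are substituted so a
  noise-free table flows through and reproduces itself exactly.

The ANOVA screen (per metabolite, duration as the factor, default
α = 0.15 — a deliberately permissive screen) uses one-way ANOVA on one group,
or a two-factor time x group model on request; metabolites with no intensity
variation take p = 1 by convention. The α = 0.15 default trades false
positives for sensitivity, appropriate for selecting metabolites to visualize
rather than for inference.

## BVLS solver

`scipy.optimize.lsq_linear(method="bvls")` solves the box-constrained convex
problem; tolerance 1e-10, iteration cap 10·(#variables)². Optimality is
certified by a KKT check (free gradients ≈ 0, bound gradients with the
correct sign), and tests compare against an exhaustive active-set enumeration
oracle on small instances. Hard zero-accumulation (the stricter reading of
"constrained to zero") is available via an equality-constrained QP
(trust-constr with exact derivatives); conjugate carrier pairs make the
equality block rank-deficient, so an SVD-derived full-rank basis of the
constraints is passed instead. The default remains soft rows at the median
measured weight, which keeps the problem a pure BVLS.

## Exemplar linear programs

min cᵀv with c = −1 at the synthesis column, subject to S_I v = 0, v_i ≥ 0
for irreversible reactions, v ≤ 1. Reversible reactions also receive a
symmetric lower cap of −1: the one-sided formulation leaves reversible loops
unbounded below, so the symmetric cap is required for well-posedness and is a
documented deviation. Degenerate optima are resolved deterministically by a
secondary LP minimizing ‖v‖₁ at the fixed optimal objective — output is
solver-independent, at the cost of preferring the most parsimonious optimal
route. One visible consequence on the packaged network: both protein and
lipid exemplars satisfy their precursor demands through amino-acid entry
points (glutaminolysis, pyruvate carboxylase) rather than running the full
TCA loop, so "TCA evenness" comparisons between products hold only weakly
(both spreads are zero). The family structure is robust, though: the four
protein exemplars sit within relative distance ≈ 0.14 of each other while
each is ≥ 0.22 from the lipid exemplar.

## Synthetic data generator

The generator emulates the target study design: groups {control, compressed},
times {0, 15, 30} min, 4–5 replicates, ~40 measurable metabolites, baselines
lognormal(ln 10⁴, σ = 1) to span intensity decades, multiplicative replicate
noise (sd = cv × center) because LC-MS intensity noise scales with signal —
which also exercises the inverse-variance weighting nontrivially. Cell
centers follow baseline + (S v)·t for a feasible ground-truth flux v
(exemplar-derived or a random LP vertex consistent with all constraints), so
at zero noise the accumulation estimator returns S v exactly and the solver
recovers v to machine precision — the end-to-end identity every other test
builds on.

Flux magnitude: with an explicit `flux_scale` the generator errors if any
center is driven non-positive; the default scale is chosen automatically so
the largest cumulative drawdown uses 25% of that metabolite's baseline —
strictly positive centers for every seed, and pool changes of the order seen
in short-term stimulation experiments.

Not emulated: chromatographic drift, batch effects, missingness, detector
saturation, and per-metabolite response factors (intensities are treated as
consistent abundance units across the S v coupling, as the flux model itself
assumes). Recovery results on these tables therefore validate the estimation
machinery under the stated noise model, not robustness to acquisition
artifacts.

### Flux identifiability at realistic noise

A caveat quantified by the package's own recovery experiment
(`chondroflux.recovery_experiment`): with baselines spanning decades, a 5%
replicate CV, n = 5 and the 48 x 39 matrix, the per-row rate uncertainty
σ_Δ ≈ cv·baseline·√(2/n)/Δt is large relative to |S v| for most rows, and the
estimate-vs-truth correlation concentrates far below 1 (median r ≈ 0.2 at the
default signal scale). This is not a solver deficiency — an oracle weighted
fit using the *true* variances reaches only r ≈ 0.4–0.8 across plausible
signal scales — but an identifiability limit of the design: per-reaction
fluxes at this noise level are determined mostly by the handful of
low-variance rows. The randomization-ensemble correlation (stability of the
estimate against replicate noise, the quantity the sensitivity analysis
reports) is much higher (median ≈ 0.9) and decreases monotonically with
noise, because it measures reproducibility of the estimator, not closeness
to truth. Interpret single-interval flux maps at pathway level, not
per-reaction level, unless the design's SNR is verified.

## Sensitivity and clustering

Randomized data sets redraw every (group, time, metabolite) cell from
N(mean, SE) truncated by counted rejection to the 95% CI of the mean; a
zero-variance cell has a point CI and reproduces its data exactly.
Identical seeds give bit-identical streams. Each randomized set is pushed
through the identical accumulation → weights → BVLS pipeline per interval;
solver failures are counted, never silently dropped. Flux–metabolite
correlation maps are Pearson correlations across the ensemble, hierarchically
clustered with Euclidean distance; undefined entries (constant series) are
reported as 0 with a flag. Sample clustering z-standardizes each sample's
intensity profile and uses 1 − r as the distance with average linkage by
default (single/complete/ward available); the linkage choice is a
convention, not a claim.

## Degenerate inputs and tie-breaks, summarized

* t₁ ≤ t₀, empty measured sets, unknown residues/metabolites: errors naming
  the offender.
* Rank-deficient BVLS instances: the solver returns a minimizer; uniqueness
  is only asserted (and tested) for the full-column-rank packaged matrix.
* LP ties: ℓ₁-minimal optimum.
* Correlation of a constant series: 0 with a flag (clustering), exclusion
  with a warning (zero-variance samples).
* All-zero-variance tables: error by default, unit weights inside the
  sensitivity pipeline.

## Problem sizes used by the test and acceptance runs

Oracle comparisons use ≤ 6x4 instances (exhaustive enumeration stays exact
and instant); the recovery experiment runs 100 simulated studies at the full
48 x 39 size; sensitivity checks use 8–100 randomized sets per run. These
sizes keep the whole suite at well under a minute per module while exercising
the full-size matrix everywhere it matters; the CLI defaults remain at
production scale (10000 randomized sets).
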