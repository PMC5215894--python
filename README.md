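# chondroflux

Average reaction-flux inference for mammalian central energy metabolism from
replicate targeted-metabolomics intensity tables.

Chondrocytes (and other mammalian cells) respond to mechanical and chemical
stimuli on the minutes scale by shifting flux through glycolysis, the pentose
phosphate pathway, and the TCA cycle. Targeted LC-MS measures metabolite
*pools* at a few time points, not reaction *rates*; this package bridges that
gap for experimentalists and modelers who want pathway-level flux estimates
from a small replicate time-course design (e.g. two groups x three time points
x 4–5 replicates) without kinetic parameters or isotope labeling.

## The model

A stoichiometric matrix **S** (metabolites x reactions, consumed negative,
produced positive) links the flux vector **v** to net accumulation:
**S v = Δ**. Per metabolite *i* and interval [t₀, t₁], the accumulation rate
is estimated from replicate group centers (mean, or median for small n):

    Δᵢ = (a₁ − a₀) / (t₁ − t₀)

Its variance follows the Welch form for a difference of means,
σᵢ² = s₁²/n₁ + s₂²/n₂ (divided by (t₁−t₀)² for the rate), and the row weight
is wᵢ = σᵢ⁻². The average flux over the interval solves the weighted
bounded-variable least-squares (BVLS) problem

    min‖diag(w) (S v − Δ)‖₂   subject to  vᵢ ≥ 0 for irreversible reactions,

a convex program solved to its global optimum. Unmeasured internal
metabolites are constrained to zero accumulation (soft weighted rows by
default, hard equalities on request); electron-transport-chain carriers
(ubiquinone, flavins, cytochrome c, gradient protons) are held at zero with
the lowest weight.

Hypothesis profiles come from a linear program: maximize flux through a
biosynthetic column (precursor demand computed from a protein's amino-acid
composition: 3-phosphoglycerate, pyruvate, α-ketoglutarate, oxaloacetate;
acetyl-CoA for lipid) subject to steady state of internal metabolites
(S_I v = 0), irreversibility, and a unit flux cap. Robustness is quantified
by re-solving fluxes on data randomized within each cell's 95% confidence
interval and correlating with the original profile, plus correlation-distance
clustering of samples and flux–metabolite correlation maps.

The packaged network covers glycolysis (G1–G10), pyruvate processing (PYP),
the TCA cycle (TCA1–TCA10), the pentose phosphate pathway (PPP1–PPP8), the
electron transport chain (ETC1–ETC5), anaplerosis (pyruvate carboxylase,
alanine transaminase), lactate dehydrogenase and glutaminolysis: 52
metabolites x 38 reactions in full, and 48 x 39 (full column rank) after
reduction to the measurable panel plus one synthesis column.

## Worked example

Simulate a study-shaped experiment with a known protein-synthesis-like ground
truth, then estimate fluxes and run the full pipeline:

```sh
chondroflux simulate --mode protein_like --noise-cv 0.05 --replicates 5 --seed 7 --out sim
chondroflux solve --table sim/table.csv --group compressed --t0 0 --t1 15 --out flux.csv
chondroflux run --table sim/table.csv --out run --n-sets 50 --seed 17
```

The solve step prints

```
objective 0.243865, converged=True -> flux.csv
```

(the weighted residual norm at the optimum) and `flux.csv` begins

```
reaction_id,pathway,flux,at_bound
G1,G,10.9024885092,0
G2,G,24.1346374907,0
G3,G,0,1
```

— fluxes in intensity units per minute; `at_bound=1` marks an irreversible
reaction pinned at zero (its unconstrained optimum would have been negative).
The pipeline's sensitivity summary (`run/sensitivity_summary.csv`) reads

```
 t0  t1  n_sets  median_correlation  fraction_above_0.5
  0  15      50            0.893054                   1
 15  30      50            0.845184                   1
  0  30      50            0.763014                   1
```

i.e. fluxes re-estimated from 50 randomized data sets correlate with the
original profile with median r ≈ 0.89 over the first interval, and every
randomized profile stays above r = 0.5 — the estimate is stable against
replicate-level noise. `chondroflux exemplar --product collagen2` prints
`synthesis flux 0.3`: the maximal collagen-II synthesis flux the capped
network supports, against which empirical profiles are compared.

The same machinery is available as a library; the solver is a scikit-learn
style estimator:

```python
import chondroflux as cf
net = cf.default_reduced_network("collagen2")
est = cf.FluxBVLS(lower_bounds=0.0).fit(X, y, sample_weight=w)  # generic BVLS
profile = cf.solve_flux(cf.assemble_problem(net, accumulation))  # full pipeline
```

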