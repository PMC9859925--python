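# Methods

## The problem

Four per- and polyfluoroalkyl substances (PFOA, PFOS, PFNA, PFHxS) repress
the recombination-activating genes *RAG1* and *RAG2* in Namalwa human B
cells in a concentration-dependent way. To rank the compounds, each
endpoint's RT-qPCR fold-change data are fitted jointly across compounds
with a benchmark-concentration (BMC) model, and relative potency factors
(RPFs) are derived against PFOA as the index compound. This package
implements that pipeline end to end — from raw quantification cycles (Cq)
to the BMC/RPF report — together with a synthetic-data generator so that
every stage can be validated without laboratory data.

## qPCR quantification

Relative quantities are obtained by the standard-curve method: Cq is
regressed on log10(relative dilution) of a pooled-cDNA serial dilution
(ordinary least squares; `scipy.stats.linregress`), giving a slope in
cycles per decade and an amplification efficiency `10^(-1/slope) - 1`.
A perfect doubling per cycle corresponds to slope −3.3219 and 100%
efficiency. Quantities are relative throughout; absolute copy numbers are
never needed because only fold changes propagate downstream.

Per sample, the target-gene quantity is divided by the reference-gene
(GAPDH) quantity; fold change is this normalized quantity divided by the
*mean* normalized quantity of the solvent-control group, so the control
group mean is exactly 1 (a group statement, not per well). Technical
replicates are averaged on the Cq scale before quantification — the
conservative convention, since averaging quantities would weight upward
outliers more. Each independent study is quantified against its own
controls. WST-1 viability readings are background-corrected (A450 − A630)
and expressed as percent of the solvent-control mean.

## Dose–response model

Fold changes follow the four-parameter exponential family standard in
benchmark-dose analysis of continuous data:

    y(x) = a · c^(1 − exp(−(x/b)^d))

- `a` — background response at concentration 0 (fold-change units, ≈ 1);
  allowed to differ between independent studies (study as covariate).
- `b` (µM) — potency; the only parameter carrying concentration units, so
  two curves sharing `c` and `d` differ exactly by a horizontal shift of
  `b`. Allowed to differ between compounds.
- `c` — plateau as a ratio to background (`c < 1` for a decreasing
  endpoint); shared across compounds ("parallel curves").
- `d` — steepness on the log-concentration scale; shared.

Replicate noise is modelled as lognormal with a single log-scale variance
`σ²` shared across all groups (homoscedastic on the log scale); the model
curve is the group geometric mean. Because the fitting input is summary
data (arithmetic mean m, SD s, size n per group), arithmetic moments are
converted by lognormal moment matching — `s2 = ln(1 + (s/m)²)`,
`μ̂ = ln m − s2/2` — which preserves both reported moments exactly; naive
`ln m` would bias the geometric mean upward by `s2/2`. Each group then
contributes the exact normal likelihood of a log-scale sample with those
sufficient statistics:

    −(n/2)·ln(2πσ²) − [(n−1)·s2 + n·(μ̂ − ln y(x))²] / (2σ²)

Whether the residual variance should itself differ by study is not
determinable from summary tables of this size; the shared-σ² choice is the
simplest consistent with parallel curves.

## Fitting and model selection

All positive parameters are optimized as logarithms (unconstrained smooth
problem; `c = exp(t)` can land on either side of 1, the direction being
read off the top-concentration data at initialization). Given the mean
structure, σ² has the closed form `Σ[(n−1)s2 + n(μ̂−μ)²]/Σn`, so it is
concentrated out of the objective and restored afterwards; it still counts
as a free parameter in `k`. Optimization is L-BFGS-B with gradient
tolerance 1e-6 and at most 2000 function evaluations per start;
initialization uses the geometric mean of the control groups for `a`, the
top-concentration/background ratio for `c`, the median nonzero
concentration for `b`, and `d = 1`, with 10 multiplicative U(0.5, 2)
jittered restarts derived deterministically from the seed. Fits are
bitwise reproducible for a fixed seed.

Three candidate configurations are compared by AIC (= 2k − 2ℓ; ties go to
fewer parameters, then listed order): the no-effect null (`y = a` per
study), a single curve shared by all compounds, and the parallel-curve
model (`b` per compound, `a` per study, `c`, `d` shared). The original
software compared an unnamed set of configurations; the candidate list is
therefore an argument, with these three as the default. RPFs require the
parallel configuration, so potency estimates always come from that fit
(with a log note if AIC preferred a simpler model).

## BMC and RPF

The BMC at critical effect size `ces` (here −0.1, i.e. a 10% decrease,
labelled BMR₁₀) solves `y(x) = a(1+ces)`:

    BMC = b · (−ln(1 − ln(1+ces)/ln c))^(1/d)

valid when the sign of `ces` matches the curve direction and the effect
lies strictly inside the plateau (`|ln(1+ces)| < |ln c|`). Under parallel
curves `BMC_index/BMC_i = b_index/b_i` identically, so RPF point estimates
do not depend on the chosen effect size.

Confidence bounds are profile-likelihood bounds at two-sided level 0.90:
the parameter of interest (a compound's CED, or an RPF via
`b_i = b_index/ρ_i`) is made explicit by reparameterization, all remaining
parameters are re-maximized at each fixed value, and the bounds are where
the profile log-likelihood has dropped `χ²₁(0.90)/2 = 1.35277` below its
maximum. The crossing is located by expanding search plus bisection on the
log scale to 1e-4 relative tolerance inside `[CED/10³, CED·10³]`; a
profile that never drops within that span yields a one-sided interval and
a warning. Because the bound is defined as the crossing of a monotone
profile, it is invariant to monotone reparameterization of the profiled
quantity. Whether the original analysis profiled the ratio or sampled it
is not recoverable; profiling is this package's declared choice.

## Synthetic data

The generator reproduces the study layout: four compounds with true
potencies defaulting to {PFOA 9.8, PFOS 11.7, PFNA 6.1, PFHxS 31.0} µM
(test-fixture magnitudes mirroring the published RAG1 estimates, not
claims about biology), shared `c = 0.2`, `d = 1.5`, backgrounds 1 in each
of two studies, triplicate wells, and two-fold concentration grids of 7
nonzero points up to 100 µM (33 µM for PFNA, the most potent and most
cytotoxic compound). Well noise is lognormal at constant natural-scale CV
(default 0.15) with the geometric mean adjusted so the *arithmetic* group
mean sits on the model curve, matching how the likelihood interprets the
summary statistics. The Cq-level simulator additionally emits a 5-point
two-fold dilution series per gene, a constant reference gene, and Gaussian
Cq noise (SD 0.1 cycles by default). One `numpy.random.default_rng(seed)`
drives everything; no global state.

What the generator does not emulate: cytotoxic dropout at high
concentrations, plate/batch effects beyond the study covariate, reference-
gene regulation, heteroscedastic or non-lognormal noise, and the weak
correlation induced by normalizing every well to the same observed control
mean. Passing recovery/coverage tests therefore demonstrate correctness of
the estimator under its own assumptions, not robustness to these
real-data features.

## Problem sizes and numerical choices

The recovery study uses 50 simulated replicates of the full design (the
median recovered RPF error is well under 10% per compound and the
parallel model wins every AIC comparison); interval calibration uses 200
replicates in the test suite and 100 in the acceptance script, with a
reduced 4-start multistart for the per-replicate refits — sizes chosen to
make the checks statistically meaningful while keeping a full run of the
suite comfortable on one CPU. Degenerate inputs are handled explicitly:
zero SD groups contribute only through their mean (the variance MLE guards
against exactly-zero total sum of squares with a 1e-300 floor), singleton
groups get SD 0 with a warning, and `ces` values at or beyond the plateau
raise rather than returning a complex number.

## Known limitations

- Summary-level fitting cannot recover information lost in summarization;
  with triplicates the χ² calibration of the profile bounds is asymptotic,
  and the coverage study shows it is adequate (≈ 88–92%) but not exact.
- The candidate-model list is deliberately short; richer covariate
  structures (e.g. variance by study, `c` by compound) are out of scope,
  as are Hill-family models and model averaging.
- No laboratory dataset is bundled; the pipeline reads the documented TSV
  layout, so published summary tables can be converted and fed to
  `run_bmd_only` directly.
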