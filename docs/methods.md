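# Methods

## The consumer-resource model

Nitrate utilization by a soil slurry is described by a single effective
nitrate-reducing biomass `x` consuming two non-substitutable resources with
Monod kinetics: nitrate `A` (the electron acceptor, mM) and a growth-limiting
carbon nutrient `C` (the electron donor, mM),

    dA/dt = -r_A x A/(A + K_A)
    dC/dt = -r_C x C/(C + K_C)
    dx/dt = gamma x [A/(A + K_A)] [C/(C + K_C)].

Because only nitrate is observed, the raw rates are not identifiable; the
rescaling x̃ = r_A x, C̃ = C r_A/r_C, K̃_C = K_C r_A/r_C leaves nitrate
dynamics governed by the rescaled system alone.  The two key quantities, both
rates in mM/day, are

* **x̃(0)** — indigenous biomass activity, the initial nitrate-reduction
  capacity of the community;
* **γC̃(0)** — available limiting nutrient, expressed as the extra
  nitrate-reduction rate the community gains once it has consumed `C`.

With small affinities the untreated arm follows
A = A0 − x̃(0)(e^{γt} − 1)/γ until growth stops at
t* = ln(min(A0, C̃(0))·γ/x̃(0) + 1)/γ, then declines linearly at
γC̃(0) + x̃(0) (when C̃(0) < A0).  The chloramphenicol-treated arm is the same
system with γ = 0: protein synthesis is arrested, so nitrate falls linearly
at x̃(0).  We integrate with LSODA (rtol 1e-8, atol 1e-9 mM), clip state at
zero, and use the exact Wright-omega solution for the growth-arrested arm
inside the fitting loop.

The closed-form approximation is exact only as K → 0.  At the package default
K = 0.01 mM its sup-norm error against the integrated system on the 10-point
measurement grid is 0.012–0.023 mM for the three regime-typical parameter
sets (largest in the nutrient-limiting case, where C̃(0) = 0.05 mM is only
five times the affinity), shrinking roughly tenfold per decade of K.  The
closed form is used for intuition and oracle cross-checks, never for fitting.

## Fitting

Each (soil, perturbed pH, replicate) condition supplies a *pair* of nitrate
time series (±chloramphenicol), fitted jointly by least squares over
{x̃(0), C̃(0), A0, A0c} with γ = 4.8/day and K_A = K̃_C = 0.01 mM fixed.
The loss is the mean squared error over all points of both arms; reported
errors (RMSE and per-point) are normalized by the 2 mM nitrate input.  The
optimizer is bounded trust-region-reflective least squares on
(log10 x̃(0), log10 C̃(0), A0, A0c) with box bounds [1e-4, 10] mM/day,
[1e-4, 10] mM and [0.5, 4] mM; one data-informed start (chloramphenicol-arm
slope for x̃(0), late untreated slope for γC̃(0)) plus eight log-uniform
random starts are screened by loss and the best three polished.  Fits are
deterministic given the seed.  Replicates are fitted separately and the
median parameters across the triplicate are the condition's reported values.

Fixing γ and the affinities is justified by a sensitivity scan: refitting
noiseless simulated curves from the three regimes with γ fixed anywhere in
2–6/day changes the normalized RMSE by < 5%, and mis-specifying both
affinities anywhere below 0.1 mM changes it by < 1%
(`scripts/acceptance.py` recomputes both numbers).

Identifiability limits worth knowing: in the acidic-death regime the total
signal (x̃(0) ≈ 0.01 mM/day over 3.8 days) is comparable to 2% measurement
noise, so per-replicate relative errors of x̃(0) approach 100% there; and
when C̃(0) > A0 the data bound C̃(0) only from below (nitrate runs out
first).  Across a study-scale panel the *median* triplicate-median error of
both key parameters is ≈ 5–6% at 2% noise.

## Regime classification

Conditions are classified from (x̃(0), γC̃(0)) with thresholds 0.05 and
1.5 mM/day: Regime I (acidic death) when both are low, Regime II
(nutrient-limiting) when x̃(0) is high, Regime III (resurgent growth) when
x̃(0) is low and γC̃(0) high.  The both-high quadrant carries no named regime
and is reported as II with an `ambiguous_quadrant` flag.  Thresholds live in
configuration; `threshold_from_distribution` re-derives them from fitted
panels (kernel-density valley between the two x̃(0) modes on the
log10(x + 0.01) scale; a tail quantile, default 0.9, for γC̃(0), whose
distribution has a dominant near-zero mode).

## Absolute abundance and folds

Two foreign-strain genomic-DNA spike-ins are added to every sample before
extraction; after merging their two ASVs into one reference vector, dividing
each ASV's counts by the per-sample spike total gives absolute abundance in
spike-DNA units and cancels sequencing depth.  Growth folds
g = ln(Abs⁻ + 1e-3) − ln(Abs⁺ + 1e-3) compare the untreated endpoint with the
growth-arrested endpoint (isolating growth-mediated change) and are clipped
at zero after taking the median over replicate pairs; survival folds compare
the growth-arrested endpoint with the initial community and are left
unclipped, since declines (death and relic-DNA loss) are the signal.  Natural
log throughout; the 1e-3 pseudocount is applied on the abundance scale.

## Replicate noise model and enrichment calling

Replicate scatter of an ASV with mean count n is modelled as Gaussian with
sd σ(n) = sqrt((c_frac·n)² + c0²), fitted per (soil, perturbed pH):
c_frac as the median absolute pairwise relative difference of ASVs above 50
counts scaled by 1.4826/√2 (a robust estimator of the per-replicate sd), and
c0 as the smallest value for which 67% of scaled replicate differences
|n1 − n2|/√2 fall within σ, found by bisection (the scaling makes the
one-sigma coverage target consistent with σ being a per-replicate sd).

Enrichment z-scores compare matched replicate pairs: counts plus a 0.5
pseudocount are spike-normalized, the abundance difference is mapped to the
chloramphenicol arm's count scale, and divided by the null sd of the
difference — the reference abundance's noise evaluated at each arm's own
spike depth, sqrt(σ(n⁺)² + (S⁺/S⁻)²σ(n⁺S⁻/S⁺)²), which reduces to √2·σ(n⁺)
at equal depths.  Evaluating the noise at the reference abundance keeps the
statistic standard normal under the null (so the Bonferroni critical value
z = Φ⁻¹(1 − α/2n_ASV) has its nominal meaning, with n_ASV the number of
non-zero ASVs in the pair) without penalizing large enrichments by their own
noise.  The median z over the three replicate pairs is assigned per ASV;
per-regime enriched sets are unions over that regime's conditions, minus the
ASVs enriched in the no-nitrate contrast (NNresponders, called at the
n_ASV = 2500 critical value from the unperturbed-pH controls and
extrapolated to all perturbation levels).  Measured on null synthetic tables
this caller yields ≈ 0.05 false positives per 2000-ASV table; planted
tenfold growers at mean count ≥ 50 are detected essentially always.

## Growth modes

Phylum-level clipped growth folds form a non-negative matrix G (40 phyla ×
conditions).  Rank-2 non-negative matrix factorization G ≈ W·H
(coordinate-descent, best of 10 random restarts, seeds derived from one
master seed) extracts two growth modes; variance retained is the Frobenius
fraction 1 − ‖G − WH‖²_F/‖G‖²_F.  On study-structured synthetic panels one
mode loads on Bacillota (basic perturbations) and the other on Pseudomonadota
and Bacteroidota (moderate pH), with ≥ 0.94 of the variation retained.

## Native-pH regression

Samples classified as resurgent growth are encoded as binary presence
(relative abundance above a threshold ∈ {0, 0.001, 0.005}) of the enriched
taxa at a chosen taxonomic level.  A LASSO linear model predicts the source
soil's native pH; the penalty is the 10-fold cross-validation minimum with
seed-pinned folds.  R² is computed on per-soil mean predicted vs observed pH
(and may be negative).  Out-of-sample quality uses leave-one-soil-out
refitting.  Significance uses a soil-level permutation null (all samples of
a soil move together), refitting in-sample 1,000 times, with the smoothed
p = (1 + #{perm R² ≥ observed})/(1 + n_perm).  Because the CV-minimum LASSO
often selects nothing under permuted labels, permuted R² values pile up at
zero; the p-value is therefore conservative (super-uniform) under the null
rather than exactly uniform, which is the property the package's tests
assert.

## Synthetic data

The generators emulate the study design: 10 soils with native pH 4.7–8.3,
13 perturbed pH levels from 3 to 9, triplicates, the 10-point 91-hour
sampling grid, 2 mM nitrate input and 2% multiplicative nitrate measurement
noise.  Regime truth parameters are drawn from the three anchor points
(x̃(0), C̃(0)) = (0.01, 0.005), (0.1, 0.05), (0.001, 2), jittered ±50%
(Regime II draws are kept above the 0.05 mM/day classification threshold so
planted labels remain consistent with planted parameters); the perturbed-pH
regime boundaries shift linearly with native pH so that more acidic soils
enter the death regime after smaller acidic perturbations.

Count tables draw reads in proportion to DNA: community biomass (log-normal
ASV weights with per-soil modulation) against a fixed spike quantity set so
the baseline spike share is 8.9% of reads — growth dilutes and death enriches
the spike share, as with a real internal standard.  Library depth varies
strongly between condition/arm groups (different runs) and mildly within a
replicate trio; count noise is the analysis's own truncated-Gaussian
σ(c_frac = 0.21, c0 = 4.5) model, rounded and floored at zero.  Planted
structure: the dominant Bacillota ASVs grow 100× in resurgent-growth
conditions, dominant Pseudomonadota/Bacteroidota ASVs 10× in
nutrient-limiting conditions (with several additional phyla growing
moderately there, matching the breadth of the study's phylum growth
vectors); survival drops below pH 4 for all phyla except Bacillota; two
dominant-phylum ASVs grow regardless of nitrate (the planted NNresponders);
and Bacillota grower families occupy native-pH windows so the taxonomic
identity of the resurgent growers encodes the source soil's pH.  Grower
folds were set to reproduce the magnitude of the study's phylum-level growth
folds (up to ~4–5 natural-log units), which also yields the ~0.95
two-factor variance retention the real growth matrix shows.

What the generators do not emulate: taxonomic mis-assignment, chimeras,
16S copy-number variation, compositional correlations between taxa,
overdispersed (beyond-Gaussian) count noise, nitrite/ammonium dynamics, and
pH drift during incubation.  Passing recovery tests therefore demonstrate
the pipeline's correctness under its own statistical assumptions, not
robustness to violations of them.

## Problem sizes in the test suite

The packaged tests run the full pipeline at reduced sizes chosen to keep the
suite quick while preserving the study's structure: gradient-panel recovery
uses 5 soils × 13 pH levels × 3 replicates; enrichment calibration uses 200
null tables of 2,000 ASVs; the NMF and regression checks run at the full
10-soil scale.  All stochastic tests fix their seeds.

## Known limitations

* Point estimates only; no uncertainty quantification of the fitted
  parameters (consistent with the analysis the package reproduces).
* The enrichment caller's noise model is fitted from three replicates;
  c_frac is a single robust spread estimate and carries sampling error of
  order 20%.
* The closed-form solution is an intuition-and-oracle device; at K = 0.01 mM
  its error near the growth-arrest kink reaches ~0.02 mM (see above).
* `fit_amendment_ratio` holds all base parameters fixed and fits only the
  stoichiometric ratio r_A/r_C; it does not propagate uncertainty from the
  base fit.
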