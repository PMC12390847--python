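# soilregimes

Functional-regime analysis of soil microbiome nitrate metabolism under pH
perturbation.

Soil microbial communities reduce nitrate anaerobically, and how fast they do
so after an acid or base perturbation falls into three qualitatively distinct
regimes: an **acidic death** regime with little activity, a
**nutrient-limiting** regime with constant reduction rates, and a
**resurgent growth** regime where rare taxa grow exponentially on released
nutrients until nitrate is gone.  `soilregimes` implements the quantitative
machinery behind this picture for microbial ecologists and biogeochemists
working with soil-slurry microcosms:

* a two-parameter **consumer-resource model** fitted jointly to paired
  ±chloramphenicol nitrate time series (the treated arm arrests growth,
  separating pre-existing enzyme activity from growth);
* **regime classification** from the fitted biomass activity x̃(0) and
  limiting-nutrient term γC̃(0);
* **spike-in absolute abundance** from 16S count tables with internal
  standards, growth and survival folds;
* an empirical **replicate-noise model** σ(n) = √((c_frac·n)² + c0²) and
  Bonferroni-corrected z-score **enrichment calling** with no-nitrate
  responder filtering;
* rank-2 **NMF growth modes** of the phylum × condition growth matrix;
* a **LASSO regression** predicting a soil's native pH from presence/absence
  of its resurgent-growth taxa, with leave-one-soil-out evaluation and a
  soil-level permutation test;
* a **synthetic-data module** that generates study-structured microcosm
  panels (metabolite curves and spike-in count tables) with known planted
  truth, so every stage is testable end to end.

The model: biomass x reduces nitrate A and consumes a growth-limiting carbon
nutrient C, each with Monod kinetics, and grows at rate γ gated by both
resources.  After rescaling, nitrate dynamics depend on two key rates:
x̃(0), the indigenous biomass activity, and γC̃(0), the available limiting
nutrient expressed as a nitrate-consumption rate.  Mathematical details are
in [docs/methods.md](docs/methods.md).

## Worked example

Fit one condition's paired time series and classify its regime:

```python
from soilregimes import CRMParams, NitrateCRM
from soilregimes.regimes import classify
from soilregimes.synthetic import synth_nitrate_pair

truth = CRMParams(x0_tilde=0.1, C0_tilde=0.05, A0=2.0, A0c=2.0, gamma=4.8)
pair = synth_nitrate_pair(truth, noise_sd=0.02, seed=7,
                          soil_id="soil06", perturbed_ph=5.4, replicate=0)
res = NitrateCRM(pair).fit(seed=0)
print(res.summary())
print("regime:", classify(*res.key_params).label)
```

```
Consumer-resource nitrate fit
==============================================
soil soil06  perturbed pH 5.40  replicate 0
points: 10 (chl-) + 10 (chl+)
----------------------------------------------
x~(0)   biomass activity       0.11877 mM/day
C~(0)   limiting nutrient     0.045364 mM
gamma*C~(0)                    0.21775 mM/day
A0 / A0c initial nitrate     1.998 / 2.012 mM
fixed: gamma=4.8/day  K_A=0.01 mM  K~_C=0.01 mM
----------------------------------------------
loss (MSE)        0.000386 mM^2
RMSE / 2 mM       0.982 %
max |err|/2 mM    1.967 %
converged         True  (starts used: 9)
regime: II
```

The true parameters were x̃(0) = 0.1 mM/day and γC̃(0) = 0.24 mM/day: at 2%
measurement noise the fit recovers both within ~10–20% for a single
replicate (the packaged panel analyses report medians of triplicates), the
fit error per data point stays under 2% of the 2 mM nitrate input, and the
condition lands in the nutrient-limiting regime (x̃(0) ≥ 0.05,
γC̃(0) < 1.5), as planted.

A full synthetic study — fit → classify → abundance/folds → enrichment →
NMF → regression — runs with:

```sh
soilregimes run --out results/demo
```

`NitrateCRMResults.plot_fit()` draws the data and both fitted arms for a
quick visual check.

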