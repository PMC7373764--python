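# phenokin

Kinetics analysis for phenol-degrading batch cultures: extract specific
growth and degradation rates from time-courses, fit the Haldane
substrate-inhibition model to both, and derive the quantities that actually
characterize a strain — the critical substrate concentration and the true
maximum rate.

## Who this is for

Environmental microbiologists and bioprocess engineers characterizing
phenol (or other self-inhibitory substrate) degraders in shake-flask batch
experiments: a sweep of initial substrate concentrations S₀, sampled
periodically for biomass (OD600 → dry mass) and residual substrate
(colorimetric assay), triplicated.

## The model

Growth on an inhibitory substrate follows the Haldane law

    μ(S) = μ* · S / (Ks + S + S²/Ki)

and substrate depletion is first-order with a Haldane-shaped specific rate
q(S) with its own triple (q*, Ks′, Ki′). Each batch yields one (S₀, rate)
point via the slope of ln(X/X₀) (growth) or −ln(S/S₀) (degradation) against
time; nonlinear least squares over the S₀ sweep gives the parameter triple,
from which

    Sm = √(Ks·Ki)        (rate peaks here, mg/L)
    μmax = μ* / (1 + 2√(Ks/Ki))   (true maximum, h⁻¹)

Note μmax < μ* always: the fitting parameter μ* overestimates the
attainable rate (by 55% for the reference parameter set below), a
distinction the reporting layer keeps explicit.

A seeded batch-culture simulator (`phenokin.simulate`) generates synthetic
experiments with the same design — S₀ grid 41–1117 mg/L, 12-h sampling,
120-h horizon, lag phase at toxic S₀, multiplicative measurement noise — so
the entire pipeline validates by parameter recovery. A small literature
table of published Haldane triples for phenol degraders ships in
`phenokin.reference`.

## Worked example

Run the full pipeline on a simulated experiment (seed 1, 5% measurement
noise, rates generated at substrate level to isolate the fitting stage):

```python
from phenokin.config import PipelineConfig
from phenokin.simulate import SimulationScenario
from phenokin.reporting import run_pipeline

cfg = PipelineConfig(seed=1, output_dir="demo", rate_source="direct",
                     scenario=SimulationScenario(seed=1))
bundle = run_pipeline(cfg)
print(open(bundle["paths"]["report"]).read())
```

prints

```
# tool: phenokin 0.1.0
# seed: 1
# config: 7f1e0f1629bfdb4a

Haldane substrate-inhibition fits
================================================
branch: growth
           rate_star: 0.57
                  ks: 19.87
                  ki: 269.07
                 s_m: 73.12
            true_max: 0.37
                  r2: 1.0
  overestimation_pct: 54.4

branch: degradation
           rate_star: 1.234
                  ks: 9.111
                  ki: 513.517
                 s_m: 68.402
            true_max: 0.975
                  r2: 0.995
  overestimation_pct: 26.6
```

The generating parameters were (μ*, Ks, Ki) = (0.574, 20.29, 268.1) and
(q*, Ks′, Ki′) = (1.244, 9.152, 517.5): with 5% noise the fit recovers them
to a few percent, and the derived columns show the headline numbers — the
growth rate peaks at Sm ≈ 73 mg/L phenol with a true μmax ≈ 0.37 h⁻¹, far
below the fitted μ* = 0.57. Growth tables round to 2 decimals, degradation
to 3; `summary.json` in the output directory keeps full precision, and
every output carries the seed and a config hash so reruns are
byte-identical.

The same pipeline is available from the shell:

```sh
phenokin dump-config > config.yaml     # all defaults, editable
phenokin run -c config.yaml -o out/    # simulate -> rates -> fit -> report
phenokin simulate -c config.yaml -o curves.csv
phenokin rates -c config.yaml -i curves.csv -o rates.csv
phenokin fit -c config.yaml -i rates.csv -o fit.csv
```

Real data enter as the same CSV schema (`time_h, s0_mg_per_l, replicate,
od600|biomass_mg_per_l, a500|phenol_mg_per_l`) via `input_csv` in the
config; raw absorbances are converted through the built-in phenol standard
curve (A = 0.002447·C + 0.1423) and a user-supplied OD600 → dry-biomass
coefficient.

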