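# reefspawn

Where and when do reef fish spawn? Fishery-independent surveys off the
southeastern U.S. Atlantic shelf collect mature females by trap and longline
and determine histologically whether each fish was within ~48 hours of a
spawning event. `reefspawn` turns such per-fish spawning-condition records,
together with gridded bathymetry, into spatially explicit predictions of
spawning habitat: it computes seafloor-terrain covariates, fits and selects a
mixed-effects logistic spawning model, validates it by cross-validation and a
permutation spuriousness test, maps peak-spawning probability as Z-scores,
and delineates multispecies and multi-year spawning areas. A synthetic-data
module emulates the survey end to end, so every stage is testable against a
known generative truth.

## The model

For fish *i* caught in gear set *s(i)* during year *j(i)*, the binary
spawning-condition flag is modelled as

```
y_i ~ Bernoulli(p_i),    logit(p_i) = x_{s(i)}' beta + u_{j(i)},
u_j ~ N(0, sigma^2)
```

a logit-linked binomial GLMM with a year random intercept and fixed effects
for gear, habitat, month, bottom temperature, latitude, depth, a signed
lunar-luminosity covariate, latitude interactions, and buffer-summarised
terrain statistics (mean/max of slope, aspect, curvature and broad- and
fine-annulus bathymetric position index, BPI). Continuous predictors other
than temperature and lunar luminosity are quantile-binned and treated as
factors. The marginal likelihood is maximised directly, integrating the year
intercept by adaptive Gauss–Hermite quadrature (Laplace fallback for many
years).

Model building is two-staged: survey covariates are forward-selected by AIC
under an |r| > 0.60 correlation screen; terrain covariates are then offered
to the stage-1 winner and retained only if they lower AIC *and* do not
degrade 10-fold cross-validated utility (pooled ROC AUC, with the
classification threshold maximising TPR + TNR). Because many terrain
candidates are screened, a permutation test (500 replicates by default)
estimates the probability that the retained terrain term is spurious.
Prediction maps fix month/temperature/lunar phase at their fitted peak and
standardise the probability surface to Z-scores; independent validation
points over cells with Z > 0 count as supporting the model.

## Worked example

```python
import numpy as np
import reefspawn as rs

cfg = rs.SimulationConfig(seed=42, n_years=8, n_sets_per_year=60)
bathy = rs.generate_bathymetry(cfg)
stack = rs.compute_terrain(bathy)               # slope/aspect/curvature/BPI
survey = rs.generate_survey(cfg, bathy, stack)

sets = survey.records.drop_duplicates("set_id").set_index("set_id")
buffers = rs.summarize_buffer(stack, sets[["x", "y"]])   # 381.8 m buffer

builder = rs.DesignBuilder(survey.records, buffers=buffers, restrict_temp=True)
fit = rs.fit_glmm(builder.build(("month", "temp_c", "lunar3", "mean_bpi_broad")))
cv = rs.crossvalidate(fit.design, k=10, seed=0)
grid = rs.build_grid_covariates(bathy, stack, fit.design)
pm = rs.predict_map(fit, grid)
```

prints (via the obvious `print` statements):

```
3042 examined females, 1088 in spawning condition
random-intercept SD: 0.384  (simulated truth: 0.5)
temperature coefficient: 0.275  (truth: 0.3)
10-fold CV: AUC 86.0% (good), FPR 24.8%, FNR 17.1%
peak settings: {'month': '6', 'temp_c': 29.53, 'lunar3': -0.999990565231069}
prediction grid: (32, 32), Z mean 1.65e-15, SD 1.00
```

The fitted year-intercept SD and temperature slope recover the generative
truth to within sampling error; cross-validated AUC of 86% grades as "good";
the auto-selected peak is June, warm water, just before the new moon
(negative lunar luminosity); and the Z-surface is standardised to mean 0,
SD 1 over valid cells by construction.

A thin CLI covers the file-based stages:

```
reefspawn simulate --config cfg.yaml --out sim/
reefspawn terrain --bathy sim/bathymetry.asc --points sets.csv --out buffers.csv
reefspawn areas --collections sim/collections.csv --out areas/
```

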