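# nutriphylo

Comparative nutritional ecology asks whether the diets that maximise a
life-history trait — here, the protein-to-carbohydrate (P:C) ratio that
maximises lifespan — are shared among related species. The raw material is
scattered across published Geometric Framework studies as contour-plot
figures of *performance landscapes*: surfaces of lifespan over (protein,
carbohydrate) intake space. `nutriphylo` turns those figures back into
analysable surfaces, summarises each optimum with Nutrigonometry trade-off
metrics, and estimates the phylogenetic signal of the optima across
species.

The package is aimed at researchers in nutritional ecology and comparative
biology who want a tested, reproducible route from published landscape
figures (or raw intake data) to phylogenetic-signal estimates, plus
synthetic-data generators that make every stage checkable against ground
truth.

## What it computes

**Landscape reconstruction.** A banded contour image is segmented into
colour clusters (z-bands); each band is assigned its legend value; pixels
are calibrated into intake coordinates; the ladder-like discretised z-axis
is broken with Normal(0, 0.25) jitter; stray mis-segmented pixels are
filtered; and a penalised thin-plate spline f minimising

    sum_i (z_i - f(P_i, C_i))^2 + lambda * J(f)

(J = bending energy, lambda chosen by generalised cross-validation) is
fitted and evaluated on a grid clipped to the data hull.

**Nutrigonometry.** The optimum is the centroid of the peak region (grid
cells in the top 5% of predicted performance). Its P:C ratio is P/C; the
*hypotenuse* h = sqrt(P² + C²) measures total diet quantity; and for two
optima (e.g. female f and male m) the signed angle

    theta = arctan(P_f / C_f) - arctan(P_m / C_m)   (degrees)

measures the trade-off in nutrient balance, negative exactly when the
female optimal P:C ratio is below the male one. Percentile bootstrap over
the reconstructed points gives 95% confidence intervals, and a paired
bootstrap of (delta theta, delta hypotenuse) between an original and a
reconstructed landscape gives the validation verdict ("consistent" when
both CIs contain zero).

**Phylogenetic signal.** For species-level traits on a rooted tree with
Brownian covariance C: Blomberg's K = (MSE0/MSE) / E[MSE0/MSE] with a
tip-permutation p-value (K = 1 under Brownian motion), and Pagel's lambda
from a Gibbs-sampled Gaussian phylogenetic mixed model

    y = mu + u_species + u_study + e,   u_species ~ N(0, s2_p * C)

with inverse-gamma (V, nu) variance priors, computed per posterior sample
as lambda = s2_p / (s2_p + s2_e), summarised by its mean and 95% HPD
interval, with Gelman–Rubin R-hat diagnostics, a nu prior-sensitivity
sweep, and a phylogenetic regression of optimal on self-regulated P:C
ratio.

## Worked example

`examples/reconstruct_landscape.py` renders a known synthetic landscape
(peak at P = 2, C = 4 intake units) as a six-band contour image, runs the
full extraction, and validates the result:

```
extraction log: {'n_layers': 6, 'n_pixels_segmented': 23028, 'n_points_after_filter': 23028,
                 'n_points_fitted': 400, 'smoothing': 1e-06, 'jitter_sd': 0.25, 'seed': 0}
reconstructed optimum centroid: P=1.93, C=3.90 (truth: 2.0, 4.0)
optimal P:C ratio 0.495 (truth 0.5)
hypotenuse 4.35 intake units

validation verdict: consistent
  delta theta 0.21 deg, 95% CI [-2.54, 3.01]
  delta hypotenuse 0.12, 95% CI [-0.34, 0.30]
```

The reconstructed optimum sits within 2% of the true peak's P:C ratio, and
both difference CIs contain zero: the landscape extracted from the image
places its optimum where the original data do. The other examples cover
landscape simulation (`simulate_landscape.py`), sex-specific trade-offs
(`tradeoff_metrics.py`: theta = −15.1° for a female 1:3 vs male 1:1.5
optimum) and signal estimation (`phylogenetic_signal.py`: K and the lambda
posterior on a 50-species simulated tree).

A thin CLI wraps the same functions for shell use:

```bash
nutriphylo simulate -o runs/demo --seed 1
nutriphylo reconstruct -o runs/demo --seed 1
nutriphylo signal -o runs/demo --seed 1
```

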