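# mesoproj

Statistical analysis of brain-wide axonal projection patterns for
two-group animal studies.

Anterograde tracer experiments quantify, for every brain region, the
*projection fraction*: the share of a region's voxels containing detected
axonal fluorescence from a single injection site. Comparing these
animal × region matrices between an experimental and a control group is
confounded by injection volume and by the exact stereotaxic position of
each injection. `mesoproj` implements a complete, tested pipeline for this
comparison:

1. **Thresholding** — regions whose mean projection fraction across
   animals is below 0.1% carry unreliable signal and are removed.
2. **Injection-volume normalization** — the total projection
   ∑PF of an animal scales as a power law, ∑PF = A·InjVol<sup>n</sup>
   (no intercept: an empty injection produces no signal). The exponent is
   fitted by OLS in log–log coordinates and all values are divided by
   InjVol<sup>n</sup>.
3. **Per-region GLM** — after scaling every region to unit mean, each
   region *j* is modelled as

   PF<sub>ij</sub> = β<sub>j</sub> + kx<sub>j</sub>·x̃<sub>i</sub> +
   ky<sub>j</sub>·ỹ<sub>i</sub> + kz<sub>j</sub>·z̃<sub>i</sub> +
   kc<sub>j</sub>·c<sub>i</sub>

   where x̃, ỹ, z̃ are mean-centered injection-centroid distances
   (medial–lateral from the midline, anterior–posterior from the anterior
   commissure, depth from the pia, µm) and c<sub>i</sub> = +1 (control) /
   −1 (treated). The mean condition coefficient μ<sub>kc</sub> =
   mean<sub>j</sub> kc<sub>j</sub> summarizes the brain-wide group effect.
4. **Bootstrap test** — each group is resampled with replacement R times
   (default 50) at its own size; all R² cross pairings are refitted
   (covariates re-centered per resample) and the one-tailed p value is the
   fraction of pairings with μ<sub>kc</sub> in the non-claimed tail,
   floored at 1/R².
5. **Multiscale clustering** — regions are clustered on the positive part
   of their Pearson correlation matrix by maximizing continuous-time
   Markov stability r(t) = Σ<sub>clusters</sub> Σ<sub>i,j</sub>
   [(Πe<sup>−tL</sup>)<sub>ij</sub> − π<sub>i</sub>π<sub>j</sub>] over a
   grid of Markov times (Louvain-style optimization, full matrix
   exponential).
6. **Leave-one-out classification** — animals are classified from
   geometry-residualized (and optionally cluster-compacted) features by a
   LogitBoost stump ensemble; the error count gets an exact binomial
   p value at chance 0.5.

Because studies of this kind rarely release the imaging-derived matrices,
the package ships a first-class synthetic-cohort generator
(`mesoproj.synthetic`) with known ground truth — log-normal baselines
spanning several orders of magnitude, power-law volume scaling, realistic
injection-centroid spread, and configurable condition-effect schemes —
so every stage of the pipeline is testable end to end.

## Worked example

```python
import mesoproj as mp

cohort, truth = mp.generate_cohort(mp.CohortDesign(), seed=11)
thresholded, removed = mp.threshold_regions(cohort)
fit = mp.fit_volume_exponent(thresholded)
unit = mp.unit_mean_normalize(mp.normalize_by_volume(thresholded, fit.exponent))
glm = mp.fit_region_glm(unit)
boot = mp.bootstrap_condition_test(unit, R=50, tail="positive", seed=11)
rep = mp.loocv_classify(unit, rounds=100, depth=1)
```

printing the pieces gives:

```
regions retained: 191 of 293 (102 below 0.1%)
power law: n = 0.208, A = 4.706, R^2 = 0.725
mu_kc = 0.0171
bootstrap: 2500 comparisons, p = 0.0004
LOO classification: 54% (13 errors of 28), binomial p = 0.425
```

The default generator plants small heterogeneous condition effects with a
positive mean on a 28-animal cohort: the fitted exponent lands near the
generative 0.216, μ<sub>kc</sub> comes out positive, the bootstrap
resolves the planted brain-wide mean shift, and per-animal classification
stays near chance because individual region effects are small relative to
the biological noise — exactly the regime the per-region model and the
bootstrap of the mean are designed for.

The same chain is available from the shell:

```sh
mesoproj simulate --seed 11 --out work/sim
mesoproj threshold --values work/sim_values.csv --metadata work/sim_metadata.json \
    --ontology work/sim_ontology.csv --out work/th
mesoproj run --out work/full   # end-to-end with the default config
```

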