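# wingmorph

Outline-based geometric morphometrics of insect wing elements, built
for species-discrimination studies on mosquito wings and wing cells
(wing contour, second submarginal cell, first and third posterior
cells).  Landmark-based morphometrics needs intact wings with
identifiable vein junctions; when specimens are damaged, the closed
outline of a single wing cell still carries taxonomic signal.
`wingmorph` provides the full analysis chain for such outlines: elliptic
Fourier shape quantification, a first-harmonic size variable,
permutation statistics, cross-validated classification with
chance-corrected accuracy, and UPGMA shape trees — plus a seeded
synthetic contour generator with known ground truth for validating
every step.

## The method

A closed contour traced by arc length `t ∈ [0, T)` decomposes into
elliptic Fourier harmonics, each with four coefficients:

    x(t) = A0 + Σₙ aₙ cos(2πnt/T) + bₙ sin(2πnt/T)
    y(t) = C0 + Σₙ cₙ cos(2πnt/T) + dₙ sin(2πnt/T)

For polygons of pseudo-landmarks the integrals have an exact closed
form; no resampling is involved.  The first harmonic traces an ellipse
whose semi-major axis `E` (in mm) is the global **size** variable.
Normalized (NEF) coefficients — invariant to size, rotation,
translation and starting point — are obtained by rotating each harmonic
by the start-point phase, removing the ellipse orientation, and
dividing by `E`; the retained **shape** vector is `(d₁″, a₂″, …, d_K″)`
with `d₁″` the signed width-to-length ratio of the first ellipse.

Downstream, shape vectors go through PCA (covariance matrix, components
retained to 99% of variance), canonical discriminant analysis, pairwise
Mahalanobis distances `D(i,j) = √((μᵢ−μⱼ)ᵀ W⁻¹ (μᵢ−μⱼ))` with
label-permutation tests (1000 replicates, Bonferroni correction),
leave-one-out (jackknife) reclassification, and UPGMA trees on the
group distance matrix.  Classification accuracy is chance-corrected:

    κ = (Po − Pe) / (1 − Pe),   Pe = Σᵢ (nᵢ/N)²

— Cohen's kappa with the chance expectation taken from group
proportions, reported as the "adjusted total assignment accuracy"
percentage.  Size-based classification uses a one-dimensional Gaussian
maximum-likelihood rule under the same jackknife.

Quality control covers digitizing **repeatability** (intraclass
correlation across replicate digitizations; measurement error
`ME% = 100·(1−R)`) and **allometry** (multivariate `r²` of shape PCs
regressed on size).

## Worked example

Simulate a four-group dataset at study scale (n = 30/41/35/22 specimens,
third-posterior-cell size distributions, two digitizations per
specimen) and run the full analysis:

```python
import dataclasses
from wingmorph import synthetic
from wingmorph.pipeline import RunConfig, run_full_analysis, aggregate_report

cfg = dataclasses.replace(synthetic.default_config(seed=42), replicates=2)
table, truth = synthetic.simulate_dataset(cfg)
run_full_analysis(RunConfig(seed=42, outdir="demo", replicates=1000),
                  table=table)
print(aggregate_report("demo").to_string(index=False))
```

prints

```
        element  n_specimens  harmonics_K  pcs_retained  anova_F  anova_p  size_adjusted_percent  shape_adjusted_percent  allometry_r2_percent  measurement_error_percent
third_posterior          128            9            17 8.416167 0.000999                      5                      39                  13.7                        6.4
```

Reading the row: 9 Fourier harmonics cover 99.99% of contour power and
17 principal components cover 99% of shape variance; group sizes differ
significantly (permutation ANOVA, p = 1/1001) but size alone classifies
barely above chance (adjusted accuracy 5%), while shape reaches 39%;
shape depends weakly on size (r² = 13.7%) and the digitizing error is
6.4% — both by construction of the generator's defaults.  The per-group
shape classification (`demo/third_posterior/shape_classification.csv`):

```
   group correct   n  percent
    sp_A      12  30    40.00
    sp_B      20  41    48.78
    sp_C      18  35    51.43
    sp_D      20  22    90.91
   Total      70 128    54.69
Adjusted                39.00
```

The planted outlier group D is recovered best (90.91%) and sits on the
longest branch of the UPGMA tree
(`(((sp_A:0.62,sp_B:0.62):0.35,sp_C:0.97):0.83,sp_D:1.80);`) — the
pattern reported for the most morphologically distinct species in real
wing-cell studies.

The same pipeline runs from the shell:

```sh
wingmorph simulate --out data --seed 42
wingmorph run --input data/contours.xy --seed 42 --outdir demo
wingmorph report --outdir demo
```

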