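# dmta — dental microwear texture analysis for dietary discrimination

`dmta` implements a complete dental microwear texture analysis (DMTA)
pipeline for tooth wear surfaces, built around the study design used to
discriminate diet in the sand tiger shark (*Carcharias taurus*): a captive
aquarium sample with a controlled fish-only diet, wild specimens with
increasing proportions of elasmobranch prey, repeated samples across one
tooth, and an unknown-diet specimen classified by projection.

It is aimed at researchers quantifying sub-micrometre 3D wear textures as a
dietary proxy — in sharks and other polyphyodont taxa where homologous-facet
sampling is impossible — and at anyone needing a reproducible, scriptable
alternative to point-and-click surface-metrology software.

## What it computes

**Surface processing.** Raw gridded height maps (Digital-Surf-style `.sur`,
ASCII matrix, or XYZ; heights in µm) are despiked (k·MAD gate against the
local 3×3 median), non-measured points are restored by harmonic (Laplace)
interpolation, gross tooth form is removed with a least-squares polynomial
of total degree 2, and a spline (or Gaussian) areal filter with nesting
index 0.025 mm separates roughness from waviness — yielding the mean-zero
*scale-limited surface* S on which texture parameters are defined.

**ISO 25178-2 texture parameters.** The 23 parameters used for dietary
discrimination, per surface:

- height: Sq, Sa, Ssk, Sku, Sp, Sv, Sz (moments and extremes of z);
- functional, from the areal material ratio (Abbott–Firestone) curve c(p):
  volumes Vmp, Vmc, Vvc, Vvv and the core family Sk, Spk, Svk, Smr1, Smr2
  via the minimum-slope 40%-width secant construction;
- spatial: autocorrelation length Sal and texture aspect ratio Str from the
  areal ACF threshold crossing (s = 0.2);
- hybrid: RMS slope Sdq and developed area ratio Sdr (%);
- feature: summit density Sds, mean summit curvature Ssc and ten-point
  height S5z, with prominence (Wolf) pruning at 5% of Sz.

**Statistical discrimination.** Per parameter: Shapiro–Wilk (advisory),
then one-way ANOVA switched to Welch's heteroscedastic ANOVA (Satterthwaite
df) when Bartlett's or Levene's test rejects homogeneity at α = 0.05;
Benjamini–Hochberg FDR control at 0.05 across the 23 tests; Tukey HSD
(Tukey–Kramer) pairwise comparisons; correlation-mode PCA on the union of
pairwise-differing parameters; projection of unknown-diet specimens into
the fitted component space; Spearman rank correlations of component scores
against ordinal diet rank and body length; and a subsampling robustness
check (aquarium teeth vs six randomly drawn wild teeth, repeated ten
times).

A synthetic generator produces both closed-form oracle surfaces and
stochastic wear cohorts (Gaussian random field background plus subtractive
scratches and pits whose density/depth encode diet level), so the entire
pipeline is testable without microscope data.

## Worked example

```python
import dmta
from dmta.iso25178 import compute_parameter_table
from dmta.stats_pipeline import StatsConfig

design = dmta.default_design(nx=96, ny=72, seed=42)   # study-mirror cohort
cohort = dmta.make_cohort(design)                     # 38 surfaces + truth
table = compute_parameter_table(cohort.surfaces)      # 23 parameters each
table = dmta.SpecimenTable(table.data.merge(
    cohort.truth[["sample_id", "diet_rank"]], on="sample_id", how="left"))
report = dmta.full_analysis(table, StatsConfig(seed=42))

print("PC1 explained: %.1f%%" % report.pca.explained_pct[0])
rs = report.spearman["PC1_vs_diet"]
print("PC1 vs diet rank: rs = %.3f, p = %.4f" % (rs["rs"], rs["p"]))
print(report.pc1_summary[["group", "n", "mean"]].round(2).to_string(index=False))
```

prints

```
PC1 explained: 90.3%
PC1 vs diet rank: rs = 0.958, p = 0.0000
group  n  mean
    1  6 -4.68
    2  6 -2.06
    3  6  1.99
    4  6  4.75
    5  6 -4.74
```

PC1 separates the cohorts in diet order (group 1, fish-only, lowest; group
4, most elasmobranch-rich, highest) and correlates strongly with diet rank.
The unknown-diet specimen ("5", generated here with a fish-dominated
texture) projects next to group 1 — the projection-based classification the
pipeline exists to support.

The same workflows are available from the shell:

```bash
dmta simulate --out cohort/ --seed 42          # surfaces + truth.csv
dmta params cohort/*.sur --out table.csv       # 23 parameters per surface
dmta analyze table.csv --out report/ --seed 1  # ANOVA/Tukey/PCA bundle
```

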