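# Methods

This note records the models, numerical choices and known limitations of
the `dmta` pipeline, in the order the method runs.

## Surface model and formats

A surface is a rectangular grid of heights z(x, y) in µm with lateral
spacing dx, dy (default 0.44 µm, the optical sampling of the instrument
class the pipeline emulates) and NaN for non-measured points. The default
field of view is 332 × 252 samples ≈ 146 × 111 µm. The grid convention is
row-major: row index ↦ y, column index ↦ x; one stated convention avoids
transposition errors in the anisotropy parameter Str.

The `.sur` writer/reader implements a minimal Digital-Surf-style layout:
one 512-byte header followed by int16/int32 height counts with a float32
z-scale and offset. Honoured header fields: signature, object type, bits
per point, stored min/max counts, grid dimensions, x/y/z spacing, x/y/z
offsets, and the non-measured-points flag (voids are stored two counts
below the stored minimum). Operator, timestamps and unit strings are
carried into metadata but not interpreted. Counts are quantized against
the float32-rounded scale, so round-trip error is bounded by one
quantization step ≈ range/2³¹ for 32-bit files. ASCII matrix files use a
`# nx ny dx dy x0 y0` header with `NaN` void tokens and `%.17g` heights
(byte-deterministic, lossless round-trip). XYZ files must form a complete
uniform lattice; an absent lattice point is an error unless
`fill_missing=True` converts it to a void — a documented dialect choice.

Parameter tables are CSV with ISO-symbol headers; a user-supplied
`column_map` adapts externally deposited tables whose column names and
units are not standardized, rather than guessing them.

## Preprocessing chain

Order: despike → restore voids → remove form → high-pass filter. Each step
records its settings in the surface's provenance list.

**Despiking** replaces the manual deletion of single-point measurement
spikes with a deterministic rule: a point is voided when its absolute
deviation from the local 3×3 median exceeds k × the global median absolute
deviation (default k = 10). The rule is scale-free and conservative: on
smooth analytic fixtures it removes nothing, and k = ∞ is the identity.

**Void restoration** solves the discrete Laplace equation on void pixels
with measured neighbours as Dirichlet data (sparse direct solve). Harmonic
in-fill reproduces linear fields exactly and obeys the maximum principle,
so restored values never exceed the surrounding data. Surfaces that are
≥ 50% voids are rejected as unmeasurable.

**Form removal** fits and subtracts a total-degree-≤ 2 bivariate
polynomial by least squares on centred, scaled coordinates (conditioning
on wide grids). Degree 2 removes the gross crown curvature of a tooth
while leaving wavelengths much shorter than the field essentially intact.

**Scale-limiting filter.** The waviness low-pass is applied spectrally on
a mirror-extended (reflective) grid — the 146 µm field is only ~6 nesting
indices wide, so end effects matter and wrap-around leakage must be
suppressed. Two transmission characteristics sit behind one interface:

- spline (default): amplitude 1/(1 + (λc/λ)⁴), tensor product over x and y;
- Gaussian: exp(−π(αλc/λ)²), α = √(ln 2/π) (the standard areal Gaussian
  filter), provided as an independent reference realisation.

Both transmit exactly 50% at the nesting index λc (default 0.025 mm =
25 µm) and are monotone in wavelength; `highpass_transmission` exposes the
curve for verification. The roughness surface is the complement,
mean-subtracted. No edge cropping happens by default; an optional crop of
λc/2 per side is recorded in provenance. Two caveats are inherent and
deliberate rather than hidden: (1) within about half a nesting index of
the edges the realised transmission deviates from nominal (tests measure
transmission on the central half of the field); (2) the chain is only
approximately idempotent — energy near the cutoff is attenuated again on a
second pass, so re-running the chain on its own output preserves Sq to
better than 1% only when the texture's correlation length is well below
the nesting index (ratio 0.992 at ℓ = 1 µm vs 0.93 at ℓ = 3 µm on a
56 µm field).

## Texture parameters

Heights enter mean-zero. Moments are area-weighted grid sums; a constant
surface flags Ssk/Sku as undefined.

The material ratio curve c(p) is the p-th upper quantile of the height
distribution, linearly interpolated between order statistics on a
2001-point uniform ratio grid. Volumes integrate the curve by the
trapezoid rule: Vm(r) = ∫₀ʳ (c(u) − c(r)) du/100 and symmetrically for
voids, evaluated at the ISO-default ratios p = 10%, q = 80% (the study
does not state them). The core construction finds the 40%-width secant of
minimum slope (ties resolve deterministically to the smallest starting
ratio, with a warning on degenerate two-level curves), extends its
equivalent line to p = 0 and 100, and derives Sk, Smr1, Smr2 and the
area-equivalent triangle heights Spk, Svk.

Sal/Str use the circular (FFT) areal autocorrelation, scanned radially in
360 directions with bilinear interpolation and sub-cell linear
interpolation of the first crossing below s = 0.2 (ISO default, unstated
in the study). Sal is the shortest decay distance; Str divides it by the
longest, with non-decaying rays capped at the half-size lag window. A
constant surface has no autocorrelation and flags both undefined.

Gradients are central differences (one-sided at edges); Sdq is the RMS
slope and Sdr the percent excess of developed over projected area.

Feature parameters fix a definition the legacy literature leaves loose:
summits are strict 8-neighbour local maxima (border ring excluded, since
the neighbourhood is incomplete there) whose topographic prominence —
computed by descending water-level flooding with union-find — is at least
5% of Sz (configurable). Sds is summit count per evaluation area (nx·dx ·
ny·dy); Ssc the mean of −(z_xx + z_yy)/2 over summits; S5z the mean of the
five highest summit heights plus the five deepest dale depths, dales being
summits of −z. Fewer than five extrema triggers a warning, not an error.

Two exact invariances hold and are tested: amplitude scaling (length and
volume parameters scale linearly; dimensionless, ratio and density
parameters are unchanged) and translation for every parameter that depends
only on the height multiset or the circular ACF. Sdq/Sdr (edge gradients)
and the feature parameters (border exclusion) are translation-invariant
only approximately; tests bound them at 5% under cyclic shifts.

## Statistical discrimination

The gates mirror standard practice for small multi-specimen designs. The
Welch trigger is Bartlett p < 0.05 OR Brown–Forsythe–Levene
(median-centred) p < 0.05 — deliberately conservative since the study
phrase "Bartlett and Levene tests revealed evidence" does not state the
conjunction; both gate p-values are recorded per parameter so replications
can be diffed. Welch's F uses weights nᵢ/sᵢ² and Satterthwaite fractional
denominator df (cross-checked against an independent implementation in the
tests). The classic path reports df (k−1, N−k) — (4, 27) for the five
groups of 6, 8, 6, 6, 6.

Benjamini–Hochberg is the standard step-up at FDR 0.05 over the 23
parameters. Tukey HSD uses the Tukey–Kramer studentized-range test for
unequal n (singleton groups excluded with a warning); it is applied
regardless of which ANOVA ran, matching the study's procedure.

PCA is on correlations: parameters standardized by training mean and
(n−1) SD, correlation matrix eigendecomposed, components ordered by
eigenvalue with the largest-|loading| entry of each component forced
positive (published figures may differ in sign; comparisons should use
magnitudes and variances). The parameter set entering the PCA is the union
of parameters with significant Tukey pairs — applied to the study's
encoded pairwise tables this rule yields its 14 parameters. Projection
standardizes new records with the *training* constants, never their own,
and does not modify the fitted model. Diet ranks are coded 1–4 in order of
increasing elasmobranch proportion; the within-tooth repeats ("2a") and
the unknown specimen carry no rank. PC1-score ANOVA runs across the five
individual specimens (unknown included, within-tooth repeats excluded),
mirroring the study's df (4, 25). Spearman correlations are tie-corrected
with t-approximation p-values by default (appropriate at n ≈ 24–30);
seeded permutation p-values are available. Correlations are computed per
tooth (n = 24), the study not stating whether it aggregated per specimen.

Subsampling draws k = 6 wild teeth without replacement, reruns the
two-group gated ANOVA + B–H, and repeats 10 times with an explicit seed.

## Synthetic data

The generator defines the conditions everything is tested under. The
background is a stationary isotropic Gaussian random field with ACF
exp(−r²/ℓ²), synthesized by circulant embedding and scaled so the sample
RMS equals the requested Sq exactly; ℓ defaults to 3 µm, a plausible
polish scale well below the 25 µm nesting index. Wear features are
subtractive only — wear removes material, which keeps the skewness of
pitted surfaces negative, as on real teeth. Scratches are Poisson-placed
line segments (length ¼–1 field diagonal) with Gaussian grooves (depth
0.30–0.75 µm, profile σ 1 µm); pits are Poisson-placed Gaussian
depressions (σ 1.5 µm). Density and depth increase monotonically with
diet level (base Sq 0.25 → 0.55 µm from level 1 to 4), enforcing "rougher
with diet" by construction — the texture map is validated for
monotonicity.

The study-mirror cohort is 6 aquarium teeth (level 1), 6 teeth each for
wild levels 2–4, eight within-tooth repeats taken as disjoint crops of one
larger parent surface sharing a single realisation (so their variance
reflects within-tooth heterogeneity only), and 6 teeth of an unknown-diet
specimen generated at level 1. Every generating parameter lands in a truth
table, which is the recovery oracle; tests never require the externally
deposited data.

Table-level cohorts (`make_parameter_table`) draw the 23 parameters
independently Gaussian at realistic locations/scales, with optional
per-group shifts in SD units. They isolate the statistics stage from the
metrology stage for error-rate and power studies. The designed-effect
condition (`designed_effect_table`) shifts the most elasmobranch-rich
group by 2.5 SD in five designated parameters (Sq, Sal, Vmc, Sk up; Sds
down, the direction real wear shows); 2.5 SD is conservative relative to
the F statistics strong dietary contrasts produce in real tables (noncentral
F ncp ≈ 30 at the study's sample sizes).

What the synthetic data does *not* emulate: instrument noise spectra,
anisotropic polish, spatially clustered features, correlated parameters in
table-level cohorts, and inter-individual biological variance beyond the
diet effect. Passing tests therefore demonstrate the pipeline's
correctness and statistical behaviour under controlled conditions, not the
biological conclusion itself.

## Problem sizes

Full-resolution processing (332 × 252) takes ~1.4 s per surface; cohort
properties are measured at 96 × 72 samples (≈ 42 × 32 µm), which keeps the
field ≥ 10 background correlation lengths and leaves all qualitative
behaviour intact. The false-flag-rate study uses 500 table-level null
cohorts; effect recovery uses 25 seeds; the within-tooth variance study
uses 5 surface-level cohorts of 32 surfaces.

## Known limitations

- The spline filter is the non-robust variant; outliers must be handled by
  the despike stage, not the filter.
- Smr1/Smr2 are reported in percent and Sds in µm⁻²; externally deposited
  tables may use other conventions and need a column/unit mapping.
- Tooth-within-specimen nesting is not modelled (no mixed effects),
  matching the study's analysis rather than improving on it.
- The `.sur` support is a compatible subset: multi-object files and
  compressed variants are out of scope.
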