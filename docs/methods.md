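# Methods

## Spectra and preprocessing

A `Spectrum` is an absorbance trace on a strictly monotonic wavenumber
grid, stored descending (instrument convention). Ingest accepts either
orientation and either of two text formats (two-column CSV; AFFN
JCAMP-DX in `XYDATA (X++(Y..Y))` or `XYPOINTS` form — the reader and
writer are implemented in-package and round-trip to 1e-9 AU). Spectra
narrower than 700–4000 cm⁻¹ are accepted with a logged warning; the full
variable set additionally needs coverage down to ~550 cm⁻¹ for the
phosphate ν₄ region, which diamond-ATR instruments provide (the synthetic
grid spans 4000–400 cm⁻¹).

Replicate fragments of one sample (four per coprolite by default) are
averaged pointwise after linear resampling onto the intersection of their
ranges at the coarsest step; linear interpolation is adequate at 4 cm⁻¹
resolution. Averaging happens before baseline correction by default
(`average_before_correction`), since both orders are defensible and the
choice is recorded in the run configuration.

Baseline correction offers two estimators:

* **rubberband** (default): the lower convex hull of the spectrum,
  linearly interpolated. Parameter-free and idempotent, but by
  construction it cannot follow locally concave drift; residuals up to
  roughly half the drift amplitude can remain under concave bumps.
* **asymmetric least squares** (Eilers-style Whittaker smoothing,
  `als_lambda` = 1e5, `als_p` = 0.01 by default): tracks smooth drift of
  either curvature; preferred when drift recovery matters more than
  having no tuning parameters.

Negative post-baseline values are clamped to zero so band surfaces are
non-negative. Spectra are then vector-normalized over the 700–1800 cm⁻¹
fingerprint window, because absolute ATR absorbance depends on crystal
contact pressure; the height ratios are scale-free regardless.

## Band variables

Eleven variables are computed per sample (windows in the README table;
the band library is a user-extensible CSV resource). A band *surface* is
the trapezoidal integral over the window after subtracting the local
linear baseline through the window endpoints, floored at zero. Three
windows are integrated above the global baseline instead of an endpoint
chord, because their bounds sit on canonical band maxima and a chord
through band maxima cancels the surface by construction: the phosphate
ν₄ window (560–600 cm⁻¹, doublet peaks at 559/600), the aliphatic C–H
massif (2850–2935 cm⁻¹, bands at 2850/2930), and the amide I window
(1631–1650 cm⁻¹, upper bound at the ~1650 cm⁻¹ maximum). The per-band
choice is stored in the band library (`local_baseline` column).

Windows are only a few resolution steps wide, so quadrature and maxima on
the native 4 cm⁻¹ grid would carry percent-level discretization error;
each window is therefore resampled with a cubic spline at ≤0.25 cm⁻¹
before integration or maximum-taking. Peak positions are refined by a
parabola through the three grid points around the discrete maximum.

Ratios use peak heights searched within ±8 cm⁻¹ (two resolution steps) of
the nominal positions (871/1017 and 1415/575 cm⁻¹). A ratio whose
denominator falls below 1e-4 of the spectrum maximum is flagged undefined
(NaN) rather than returned as a huge number; analyses drop such rows
listwise with a logged count. The conventional infrared splitting factor
(heights at 565 and 605 cm⁻¹ over the 590 cm⁻¹ valley) is computed
alongside as `irsf` for reference, since "crystallinity index" is used
for both quantities in the bone literature; the 1010–1030 cm⁻¹ surface is
the canonical CI here.

## Variable selection

Step 1 screens pairwise Pearson correlations of the full spectra (sample
similarity). Steps 2 and 3 run correlation-matrix PCA on the mineral and
organic candidate sets — once including the reference standards, once
coprolites only — and then discard, iteratively, the candidate with the
highest mean absolute correlation to the remaining candidates until three
survive. Exact ties discard the later-listed candidate, so canonical
variables listed first survive perfect redundancy. The rule is a concrete,
documented instantiation of "select few, weakly correlated variables";
`iterative_discard` is exposed separately so alternative rules can be
swapped in.

PCA is always on z-scored variables (correlation matrix), because the
set mixes areas and dimensionless ratios of different magnitudes.
Component signs are fixed by making the largest-magnitude loading of each
component positive; axes are defined purely by eigenvalue order.

## Classification

A fitted reference holds the selected six variables, their z-scaling,
per-species centroids, and a covariance pooled across species and shrunk
toward the identity with weight 0.1 (keeps the matrix well-conditioned
for species with few samples). Unknowns are assigned to the nearest
centroid by Mahalanobis distance; confidence is the softmin of distances.
Convex-hull membership in PC1–PC2 is reported separately — a sample can
be nearest to a centroid while falling outside every hull.

## The synthetic generator

Each spectral component (calcite, aragonite, bioapatite phosphate and
carbonate, protein, collagen, cholesterol, chitin, keratin-S) is a sum of
Gaussian bands at literature positions; widths default to 8–14 cm⁻¹
(FWHM) for mineral bands and ~25 cm⁻¹ for amides, wide enough to be
realistic and narrow enough that the 559/600 cm⁻¹ ν₄ doublet resolves at
4 cm⁻¹ resolution. A species is a weight vector over components with
log-normal sample-to-sample dispersion (σ = 0.25); each replicate adds a
degree-3 polynomial baseline drift scaled into [0, 0.05] AU and white
noise (σ = 0.01 AU). Four replicates per sample mirror the four analysed
fragments. Cohorts default to 12 samples per species, a compromise
between the real study's 2–9 per species and stable convex hulls.

The default weight profiles are qualitative encodings of the observed
compositions, not published quantities: spotted hyena mineral-dominant
with weak organics; striped hyena nearly as mineral-rich with roughly
1.75× the lipid weight (its domain then overlaps the spotted hyena's, as
observed); brown hyena an organic-leaning intermediate; aardwolf
chitin-dominant with a small positive phosphate weight (2% of the spotted
hyena's) so carbonate/phosphate ratios stay finite rather than undefined.
These simulated spectra share real data's additive-mixture structure,
replicate noise and drift, but not its diagenetic alteration, sediment
contamination (clay bands overlapping ν₃ PO₄), water-vapor lines, or ATR
penetration-depth effects — so passing tests demonstrate the workflow's
correctness and internal consistency, not field-condition robustness.

A second, feature-level "planted" mode draws the eleven variables
directly from a multivariate normal (means at typical magnitudes,
CV = 0.2) with a prescribed correlation matrix, used to benchmark the
selection procedure. The default targets embed the reported screen values
(CI–CO3 0.67, CI–PO4 0.56, CO3b–CO3PO4b 0.50, amide I–amide II 0.99)
plus construction-driven correlations among the remaining pairs — the
height-ratio numerators sit inside carbonate surface windows, the CI
window contains the 1017 cm⁻¹ ratio denominator, the two ratios co-vary,
the amide III proxy tracks both backbone amides, and chitin carries amide
bands of its own. With only the four reported values planted, the
candidates left after the obvious discards are mutually uncorrelated and
the final discard would be decided by sampling noise; the added structure
makes the population discard order deterministic, and the magnitudes were
fixed once, at design time, subject to positive-definiteness and to that
order being robust at n = 200.

## Numerical choices and degenerate inputs

* Grids: 1 cm⁻¹ for noise-free references, 4 cm⁻¹ for cohort spectra;
  analytic ground-truth features use a 0.5 cm⁻¹ grid.
* Duplicate or non-monotonic wavenumbers are rejected at ingest; baseline
  estimation requires ≥16 points; PCA requires ≥3 complete samples, ≥2
  variables, and errors on zero-variance variables (naming them).
* One- and two-sample species yield degenerate point/segment domains with
  zero area; hull containment uses a 1e-12 buffer for boundary points.
* All randomness flows through `numpy.random.default_rng` seeded
  generators; cohorts are reproducible bit-for-bit under a fixed seed.

## Known limitations

* The rubberband baseline under-corrects concave drift (see above).
* Surfaces floored at zero are not additive across components whose
  chord-subtracted integrand is negative (e.g. the chitin window on a
  mineral-rich spectrum); linearity holds for non-floored surfaces.
* The classifier is a nearest-centroid model on six variables; with
  strongly overlapping species (spotted vs striped hyena) misassignments
  between those two are expected and mirrored in their overlapping
  domains.
* Band assignments treat the 1030–1160 cm⁻¹ region as chitin/keratin-S
  even though phosphate ν₃ tails into it; the chord baseline suppresses
  most of that leakage but cannot remove it exactly.
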