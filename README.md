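# coprofir

ATR-FTIR chemometrics for identifying which hyaenid species produced a
coprolite (mineralized feces).

Coprolites of bone-eating carnivores are abundant in Pleistocene sites and
carry information about both the producer and its prey. The four extant
hyaenids differ sharply in diet — three bone-crushers (*Crocuta crocuta*,
*Hyaena hyaena*, *Parahyaena brunnea*) and the termite-eating aardwolf
(*Proteles cristatus*) — and that difference is written into the bulk
chemistry of their feces: bioapatite phosphate and carbonate from digested
bone, cholesterol-rich lipids, residual protein, and insect-cuticle
chitin. `coprofir` turns ATR-FTIR absorbance spectra of powdered fecal
matrix into a small set of quantitative band variables, screens them for
redundancy, ordinates samples by PCA, and classifies unknowns against
per-species reference domains. It is written for archaeozoologists and
taphonomists who want a reproducible, scriptable version of this workflow.

## The variables and the method

From each baseline-corrected, vector-normalized spectrum, eleven band
variables are measured (areas in AU·cm⁻¹ after local baseline
subtraction; ratios from peak heights):

| variable | definition |
|---|---|
| PO4 | surface 560–600 cm⁻¹ (ν₄ PO₄ of apatite) |
| CO3 | surface 860–880 cm⁻¹ (ν₂ CO₃) |
| CO3b | surface 1409–1425 cm⁻¹ (ν₃ CO₃) |
| CI | surface 1010–1030 cm⁻¹ (crystallinity index) |
| CO3PO4 | height(871)/height(1017) |
| CO3PO4b | height(1415)/height(575) |
| chitin | surface 1030–1160 cm⁻¹ (sugar-ring / keratin-S) |
| cholesterol | surface 2850–2935 cm⁻¹ (aliphatic C–H) |
| amideII | surface 1535–1556 cm⁻¹ |
| amideI | surface 1631–1650 cm⁻¹ |
| collagen | surface 1240–1310 cm⁻¹ (amide III proxy) |

A three-step selection then reduces these to a parsimonious model:
(1) full-spectrum pairwise correlation screen; (2) correlation-matrix PCA
of the six mineral variables (with and without reference standards) and
iterative discard of the variable with the highest mean |r| to the
remaining candidates until three survive; (3) the same for the five
organic variables. On the default synthetic benchmark this selects
**{CO3, PO4, CO3PO4b}** and **{chitin, cholesterol, amideI}**. Species
domains are convex hulls of sample scores in PC1–PC2; unknowns are
assigned to the nearest species centroid by Mahalanobis distance (pooled,
shrunk covariance) with a softmin confidence.

Because real hyaenid coprolite spectra are proprietary, the package ships
a synthetic generator with full ground truth: additive Gaussian band
mixtures of bioapatite, calcite/aragonite, protein, lipid and chitin
components, species-specific weight profiles, replicate-fragment
variability, polynomial baseline drift and white noise — plus a
feature-level mode that draws the eleven variables from a prescribed
correlation structure for controlled selection experiments.

## Worked example

```sh
coprofir run-all --seed 1 --out demo
```

simulates the default cohort (12 samples × 4 species × 4 replicate
fragments, plus reference standards), averages replicates, preprocesses,
computes features, runs selection and the five PCAs, builds domains, and
prints the run report:

```json
{
 "seed": 1,
 "selected_mineral": ["PO4", "CO3", "CO3PO4b"],
 "selected_organic": ["chitin", "cholesterol", "amideI"],
 "combined_explained_fraction": [0.625, 0.194, 0.149, 0.027, 0.005, 0.001]
}
```

PC1 (62.5% of variance) separates mineral-rich spotted/striped hyena
feces from the chitin-dominated aardwolf; the first line of
`demo/features.csv` shows the per-sample variables, e.g. a *Crocuta*
sample with `PO4 = 2.14`, `chitin = 0.0`, `CO3PO4b = 2.59`.
`demo/domain_overlaps.csv` records the hull topology: the *Hyaena* domain
overlaps *Crocuta*, while *Proteles* and *Parahyaena* are disjoint from
both. The library API (`coprofir.generate_cohort`, `compute_features`,
`select_variables`, `run_pca`, `build_domains`, `classify`) exposes each
stage separately; see `docs/methods.md` for the model details.

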