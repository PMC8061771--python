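# adductshift

MALDI imaging mass spectrometry (IMS) of tissue in positive-ion mode detects
most membrane lipids as cation adducts — [M+H]⁺, [M+Na]⁺ and [M+K]⁺.  The
relative intensities of the Na⁺ and K⁺ adducts of a lipid species track the
local tissue cation balance, so the **[Na⁺]/[K⁺] pair ratio**

```
f_Na = I_Na / (I_Na + I_K),   f_K = 1 − f_Na
```

is a spatial biomarker of ionic homeostasis: in healthy colon mucosa it sits
near 0.5:0.5 for every phosphatidylcholine (PC) species, and it shifts to
roughly 0.3:0.7 in adenomatous mucosa — in both the epithelium and the lamina
propria, and regardless of what happens to the species' total abundance.

`adductshift` is a tested, reusable pipeline for this analysis, aimed at
people working with high-mass-resolution lipid IMS:

* **lipid registry** — monoisotopic masses of PC/SM species computed from
  elemental formulas (PC *n*:*d* = C(n+8)H(2n−2d+16)NO₈P), cation masses
  corrected for the electron, ppm-tolerance candidate lookup.
* **synthetic tissue generator** — ground-truthed colon-mucosa rasters
  (crypt epithelium invaginating into stroma at 10 µm pixels) with
  configurable adduct partitions, crypt-axis abundance gradients, ppm mass
  jitter, intensity/TIC noise, chemical-noise peaks and instrument-style
  merging of unresolvable channels.
* **preprocessing** — per-spectrum TIC normalization, greedy-centroid peak
  alignment onto a common mass axis, relative-intensity filtering (0.5% of
  the base peak by default).
* **adduct deconvolution** — the core: the H⁺/Na⁺/K⁺ partition of each lipid
  class is estimated *per spectrum* from channels free of isobaric overlap,
  and every ambiguous channel (e.g. [PC 34:1+Na]⁺ vs [PC 36:4+H]⁺, 3.1 ppm
  apart and unresolvable at R₄₀₀ = 100,000) is split proportionally to each
  candidate's predicted contribution.  The split conserves intensity exactly
  and is exactly invertible at zero noise.
* **spatial analysis** — pixel-by-pixel adduct profiles along crypt paths,
  ROI summaries per tissue compartment, and subject-level healthy-vs-adenoma
  Student's *t* comparisons with stacked adduct proportions.

## Worked example

The `demo` subcommand reproduces the whole synthetic experiment — four
healthy and three adenomatous sections, each pushed through the full
pipeline and compared at the subject level:

```sh
adductshift demo --seed 7 --out report/
```

prints

```
healthy: epithelium Na:K pair ratio 0.50:0.50 (over 9 species)
adenoma: epithelium Na:K pair ratio 0.30:0.70 (over 9 species)
report written to report/
```

`report/summary.tsv` holds the per-species estimates (`mean_fK` is the mean
per-pixel K pair fraction over all epithelial or stromal pixels of the arm):

```
condition  compartment  species   mean_fK   sem_fK    pooled_fK  ...  n_pixels
healthy    epithelium   PC 32:0   0.499721  0.002175  0.500062        1360
healthy    epithelium   PC 34:1   0.500880  0.001194  0.501846        1360
...
```

and `report/comparison_fractions.tsv` the subject-level unpaired *t*-tests,
e.g. PC 32:0: healthy f_K 0.500 vs adenoma 0.696, p ≈ 1e-8 — the generator's
healthy (0.5:0.5) and adenomatous (0.3:0.7) worlds are recovered for every
species despite 20% intensity noise, 1.5 ppm mass jitter and two isobaric
channel overlaps.  The report also contains path-profile and stacked
adduct-proportion plots.

The same run is available in Python:

```python
from adductshift import RunConfig, run_demo
result = run_demo(seed=7, config=RunConfig())
print(result.summary.head())
```

Individual stages (`simulate`, `preprocess`, `deconvolve`, `profile`,
`compare`) are exposed both as library functions and as subcommands over a
plain-text dataset format (`spectra.tsv` + JSON sidecars).

## Acceptance script

`scripts/acceptance.py` reruns the full experiment from scratch at a given
seed and writes the headline quantities as JSON: the mean K pair fraction of
the PC panel in healthy epithelium, adenomatous epithelium and adenomatous
lamina propria, and the worst accepted assignment mass error in ppm:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
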