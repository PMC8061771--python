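# Methods

## The measurement model

A positive-ion MALDI-IMS experiment over m/z 480–1000 sees each lipid
species *s* at up to three m/z positions, one per cation adduct
a ∈ {H⁺, Na⁺, K⁺}:

```
mz(s, a) = M_s + m_a,      m_a = atomic mass of a − m_electron
```

with M_s the neutral monoisotopic mass computed from the species' elemental
formula (PC *n*:*d* → C(n+8)H(2n−2d+16)NO₈P; d-series SM *n*:*d* →
C(n+5)H(2n−2d+13)N₂O₆P).  Subtracting the electron mass matters: it is
~0.7 ppm at m/z 780, comparable to the accuracy of the instrument class
modelled here, and the package's 3 ppm anchor values are only reproduced
with cation (not atomic) masses.

The analysis assumes that within one lipid class the adduct partition
(f_H, f_Na, f_K), Σf = 1, is shared by all species of that class at a given
pixel, while it may vary between pixels and between tissue types.  This is
the identifying assumption for deconvolving isobaric overlaps, and it is the
reason ratios are estimated per individual spectrum rather than from the
dataset-average spectrum.

## Isobaric overlaps in the packaged panel

The colon panel (PC 32:0, 34:1, 34:2, 36:1, 36:2, 36:3, 36:4, 38:4,
SM d34:1) contains exactly two channel pairs closer than the instrument can
resolve at R₄₀₀ = 100,000 (FWHM ≈ 0.011 Da at m/z 780):

| pair | Δm/z | separation |
|---|---|---|
| [PC 34:1+Na]⁺ 782.5670 vs [PC 36:4+H]⁺ 782.5694 | 0.0024 Da | 3.1 ppm |
| [PC 36:1+Na]⁺ 810.5983 vs [PC 38:4+H]⁺ 810.6007 | 0.0024 Da | 3.0 ppm |

Both arise from the same arithmetic: adding 2 C and 3 double bonds changes a
neutral mass by 21.9843 Da, only 0.0024 Da above the Na⁺−H⁺ cation
difference (21.9819 Da).  Every other pair of panel channels is ≥ 0.05 Da
apart.  All 27 channels therefore collapse to 25 observed channels, two of
them ambiguous.

## Pipeline stages and their parameters

1. **TIC normalization** — each pixel spectrum is scaled to unit total ion
   current.  Zero-TIC pixels are excluded with a warning, not an error.
   The pair ratio is invariant to this (and any) global rescaling.
2. **Alignment** (tolerance 6 ppm default) — all observed m/z are pooled and
   sorted; a new reference channel opens when the next value lies more than
   the tolerance above the running intensity-weighted centroid of the
   current channel.  6 ppm comfortably covers the ±4–5 ppm spread of a
   1.5 ppm-jitter channel over ~2000 spectra while staying far below the
   ≥ 60 ppm spacing of distinct panel channels.  Alignment conserves each
   spectrum's total intensity exactly (re-addressed duplicates are summed).
3. **Intensity filter** (0.5% of the per-spectrum base peak) — removes the
   bulk of chemical-noise peaks; the base peak always survives.  Because the
   threshold is relative, filtering commutes with normalization (asserted,
   not assumed).  A dataset-global variant is deliberately not the default:
   processing is per spectrum throughout.
4. **Annotation** (tolerance 9 ppm, warning flag beyond 3 ppm) — every
   reference channel collects all registered (species, adduct) candidates
   within tolerance of its centroid; unmatched channels are excluded
   downstream.  Mass-accuracy QC is reported at the level of individual
   surviving peaks against their nearest candidate, since accuracy depends
   on peak intensity.
5. **Per-spectrum class ratios** — for each class, the H/Na/K intensities of
   its *complete* species (all three adducts unambiguous; 4 of the 8 PCs,
   and SM) are summed per adduct and renormalized.  Restricting to complete
   species matters: summing *all* unambiguous channels would drop only the
   overlapped adduct of a partially-ambiguous species from the class sums
   and bias the ratio (for the packaged panel, r_K would be inflated by
   ~0.03).  With complete species the estimator equals the generating
   partition exactly at zero noise.  If a class has no complete species the
   partial sums are used; if a spectrum has no class signal at all, the
   intensity-weighted mean ratio of its tissue stratum substitutes and the
   spectrum is flagged (`fallback_used`).
6. **Apportionment** — for an ambiguous channel, each candidate (s, a) gets
   a predicted contribution T_s · r_a, where T_s anchors the species' latent
   total on its unambiguous channels: T_s = Σ_{a′ unambig} I(s,a′) / Σ r_{a′}.
   The observed intensity is split proportionally to the predictions, so the
   parts always sum to the observation (intensity conservation holds to
   machine precision) and the split is order-independent.  A candidate with
   no anchor receives the mean anchored prediction (equal split when nothing
   is anchored) and is flagged low-confidence.  The procedure is single-pass;
   no iteration between ratio estimation and apportionment is performed —
   at zero noise the single pass is already exact, and under the default
   noise the residual bias on the recovered pair fractions is < 0.01.
7. **Spatial statistics** — the pair fractions f_Na, f_K are computed per
   pixel per species from the deconvolved Na and K intensities; pixels with
   I_Na + I_K = 0 are reported missing, never imputed as 0.5.  ROI summaries
   report per-pixel means ± SEM and the pooled (intensity-summed) fraction.
   Group comparisons run two-sided Student's *t*-tests on *subject-level*
   means (4 healthy vs 3 adenoma sections in the demo) to avoid
   pixel-level pseudo-replication; no multiple-testing correction by
   default, Benjamini–Hochberg behind a flag.  Path profiles are raw per
   pixel; an optional centered moving average (window 5) exists for
   plotting only.

## The synthetic world

The generator states the world the recovery experiments are scored against;
none of its parameters are fitted to anything.

* **Geometry** — U-shaped single-pixel-wide epithelial crypt bands in a
  lamina-propria field, 10 µm pixels; `crypt_axis` runs 0 (base) → 1 (top)
  monotonically along each arm, `mucosa_axis` likewise for the stroma.
  The default demo raster (48×48, 4 crypts) has ~340 epithelial and ~1590
  stromal pixels per section.
* **Adduct partitions** — healthy (f_H, f_Na, f_K) = (0.30, 0.35, 0.35) and
  adenoma (0.30, 0.21, 0.49), pinning the Na:K pair ratio at exactly
  0.5:0.5 and 0.3:0.7.  The H fraction is not a reported quantity; 0.30 is
  a free choice and the pair ratio is insensitive to it.  The same
  partition is used in both compartments, reflecting the observed
  compartment-independence of the shift.
* **Abundances** — per-species base intensities of 50–120 arbitrary units;
  in the adenoma arm PC 34:1 rises (×1.5) while PC 36:2/36:3 (×0.7) and
  PC 38:4 (×0.8) fall, exercising the claim that the ratio shift is
  independent of total-abundance changes.  Only PC 32:0 (slope −0.4) and
  PC 38:4 (+0.4) have crypt-axis gradients; all other species are flat.
* **Noise** — m/z jitter σ = 1.5 ppm (≈95% of peaks within 3 ppm);
  multiplicative lognormal peak noise with CV 0.2 (unit mean); per-pixel
  TIC factor with CV 0.3; 50 uniform-m/z chemical-noise peaks per spectrum
  with lognormal intensities (median 0.15 units, σ_log 1.2) — mostly, but
  not entirely, below the 0.5% filter.  The real instrument's absolute
  intensity scale and noise levels are not reported anywhere; these values
  are desk-scale stand-ins, chosen once, not claims about the hardware.
* **Resolution** — channels within one FWHM merge into an intensity-weighted
  centroid, with orbitrap-style decay R(mz) = R₄₀₀·√(400/mz); merging
  repeats to a fixed point, making it idempotent.
* **Randomness** — one seeded NumPy generator per dataset, consumed in a
  fixed vectorized order; subject seeds are derived from the root seed via
  `SeedSequence`.  Identical seeds give byte-identical serialized datasets.

What a green recovery test establishes: the estimator chain is unbiased and
precise enough to recover a stated partition within ±0.05 under this noise
model, including through engineered isobaric overlaps.  What it does not
establish: performance on profile-mode data, isotope envelopes, matrix
clusters, detector saturation, inter-section registration error, or real
biological heterogeneity of the partition within a compartment — none of
which the generator emulates.

## Numerical and design notes

* The alignment method of the original toolchain is cited but undocumented;
  greedy centroid clustering with an exposed ppm gap reproduces its
  functional contract (a shared axis).  Tolerance, like every stage
  parameter, is archived in the run configuration and the processing log,
  so a run is replayable.
* Degenerate inputs: empty spectra pass the filter unchanged; zero-TIC
  spectra are excluded at normalization; a single-pixel ROI reports SEM = 0
  by convention; paths must be ≥10 pixels, 8-connected and non-revisiting.
* Isotopologue (M+1, M+2) channels are not registered: the analysis
  annotates monoisotopic species only.  Negative-ion adducts, multiply
  charged ions and in-source fragments are out of scope.
* imzML import/export is not included: the environment this package targets
  pins the dependency set, and no imzML library is available there.  The
  plain-text internal format (`spectra.tsv` + JSON sidecars) round-trips
  losslessly and keeps fixtures human-readable.
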