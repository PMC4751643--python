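# Methods

This note documents the models, parameters and numerical choices behind
`cortiquant`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Image quantification

### Excess-red enhancement

DAB (3,3′-diaminobenzidine) reaction product is brown — red-dominant —
while the hematoxylin counterstain is blue-dominant and the slide
background is near white. The enhancement

    E = clamp(2R − B − G, 0, 255)

is computed in 32-bit signed integers before clamping, so no uint8
wrap-around can occur. `E` is exactly zero on any achromatic pixel
(`R = G = B`) and on any blue-dominant pixel, and grows with the red
excess of DAB. A consequence worth noting: on a DAB/hematoxylin section
the zero bin of `E` is *structural* — it collects essentially all
non-DAB content — so the histogram of `E` is a large zero spike plus one
stain mode.

### Maximum-entropy threshold

`entropy_threshold` implements the Kapur–Sahoo–Wong maximum-entropy
criterion on the 256-bin histogram of the raw 8-bit range: for each
candidate level `t` the two sub-histograms (`≤ t`, `> t`) are normalised
and their Shannon entropies summed; the returned level maximises this
sum. Conventions: empty bins contribute zero entropy (0·log 0 ≡ 0);
candidates leaving either class empty are invalid; ties break toward the
lowest maximising level, making the result deterministic. A constant
image has no valid split and raises a degenerate-histogram error. The
implementation is vectorised via cumulative sums but is mathematically
the exhaustive 256-candidate maximisation; the test suite checks exact
agreement with a naive pure-Python oracle on random and bimodal images.

### Segmentation and cleanup

`segment_cells` thresholds `E` at the entropy level and then applies the
two cleanup steps in order: a morphological opening with a disc
structuring element (default radius 1 px) and removal of 8-connected
components smaller than `min_object_area` (default 20 px²). Both
defaults are deliberately minimal — enough to remove staining specks and
dust below the size of a cell — and are CLI-configurable.

One safeguard addresses a documented failure mode of the entropy
criterion on spike-plus-one-mode histograms such as `E`'s: when the
stain mode is wide and covers more than roughly a quarter of the frame,
the criterion develops a second local maximum *inside* the stain mode
whose value can exceed the gap split by a few thousandths of a nat.
Splitting inside a noise mode produces salt with no spatial coherence.
The opening itself detects this: if it destroys more than half of the
thresholded pixels, `segment_cells` re-evaluates the criterion's local
maxima in decreasing order and uses the best level whose mask survives
the opening. On well-separated histograms the global maximum survives
and behaviour is the plain Kapur threshold; the fallback only engages in
the degenerate regime (observed for synthetic sections above ~29% DAB
coverage).

A section whose excess-red channel is constant zero carries no DAB
signal at all; that is a valid observation (density 0), so an empty mask
is returned with a logged warning rather than an error.

### Tissue mask and density

The total section area comes from the blue channel: Otsu's threshold
separates two classes, and the blue-rich class is taken as background
only if it is near white (mean blue ≥ 200); otherwise the frame is
judged fully covered by tissue. Holes (DAB-only regions, unstained
lumina) are filled. This rule assumes a bright, near-white background —
true of brightfield slide scans; it would misbehave on dark-field or
heavily vignetted images.

Cell density is `|cells ∩ tissue| / |tissue|`, dimensionless in [0, 1].
Cell pixels outside the tissue mask are not counted. Physical
calibration (default 0.46 µm/px — a documented package default, not a
scanner-derived constant) is used only to report tissue areas in mm².

## Follicle scoring and outcomes

Stages form the fixed vocabulary {primordial, transitional, primary,
secondary}. Transitional follicles are pooled with primordial for every
outcome; primary and secondary follicles are kept in the records but
excluded from the densities, since their numbers in cortical sections
are too low to analyse. A follicle is **degenerated** iff any of the
three morphology flags (disorganized granulosa, shrunken ooplasm,
pyknotic oocyte) is set — an exact logical OR, property-tested over all
eight combinations — and **proliferative** iff it has at least one
Ki-67⁺ granulosa cell.

Per fragment, the density of an outcome pools its qualifying sections as
`Σ counts / Σ areas` (total count over total area). Pooling, rather than
averaging per-section densities, is exact under unequal section areas
and invariant under splitting a section into parts — a property the
suite tests. Outcomes are analysed as `y = log10(X + 1)`; the base-10
convention is applied uniformly in the generator, the scoring and the
analysis, and `y = 0` iff the count is zero.

The three annotation-based outcomes are `total_primordial`,
`normal_primordial` and `proliferative_primordial` (the last computed on
the proliferation-scored sections). A fourth, `global_proliferation`, is
the pixel-based DAB⁺ area fraction supplied by the image pipeline on
proliferation sections, carried onto the same log10(X+1) scale; it is an
area fraction, not a count per mm², so its magnitude is not comparable
to the follicle densities.

## Mixed-effects analysis

For section-level observations `y_ijk` (cell *i* = arm × condition,
fragment *j*, section *k*):

    y_ijk = μ_i + b_j + ε_ijk,  b_j ~ N(0, σ_f²),  ε_ijk ~ N(0, σ²)

estimated by REML (statsmodels `MixedLM`) with a cell-means fixed part
and a random intercept per fragment. Sections are the analysis units:
the replicate sections within each punch are what identify the fragment
variance. Empty design cells are dropped with a logged warning (the
analysis uses the maximum data available); a strict mode raises instead,
naming the cell.

Inference uses Wald statistics referred to a *t* distribution with
containment degrees of freedom `df = n_fragments − n_cells`. For this
balanced nested design that is the classical reference for
between-fragment effects; a plain large-sample normal reference is
anticonservative at realistic fragment counts — with only `df` fragments
of information, rejecting at the normal critical value |z| > 2.576
carries true size P(|t_df| > 2.576), e.g. ≈ 0.013 at df = 50 and ≈ 0.011
at df = 200 instead of the nominal 0.010. When the design leaves no
spare fragments the reference falls back to the normal. Kenward–Roger and Satterthwaite corrections are out of
scope.

Contrast families mirror the study questions: within each arm,
consecutive conditions in the order F → F-T → D2 → D6 (the freezing
effect, then each culture interval); and between arms at each condition,
pairing each drug with its vehicle (S1P vs NaOH control, Z-VAD-FMK vs
DMSO control) when present, otherwise all arm pairs. The significance
level defaults to α = 0.01 — a deliberately conservative level that is
the analysis's only multiple-comparison control; flags are exactly
`p < α` and can be recomputed for another α without refitting.

## Synthetic data

### Images

`generate_ihc_image` paints, over a white (245, 245, 245) background, a
centred tissue disc covering `tissue_fraction` (default 0.7) of the
frame, `n_cells` filled discs of radius 4–6 px rejection-sampled
entirely inside the tissue (overlap allowed — it occurs in real sections
and stresses the segmentation), and `n_artifacts` (default 30) connected
specks of < 9 px² grown by short random walks. Colors are per-pixel
Gaussians clipped to [0, 255]: DAB mean (130, 85, 60), tissue mean
(70, 80, 150), both with σ = 10 per channel — hue separations of the
order seen in DAB/hematoxylin scans, with noise strong enough to make
thresholding non-trivial. One seeded NumPy generator drives the whole
call, so images are bit-reproducible. The ground truth records the cell
and tissue masks, cell centres and the exact painted density.

Not emulated: tissue texture, nucleus rendering, chromatic aberration,
stain variation across the slide, scanner compression. Passing the
density-recovery tests therefore shows the pipeline recovers areas under
honest color noise and artifacts, not that it is robust to every
property of scanned slides.

### Studies

`generate_follicle_dataset` reproduces the study layout: 4 arms (S1P,
NaOH control, Z-VAD-FMK, DMSO control) × 4 conditions (F, F-T, D2, D6) ×
6 punches, i.e. 24 punches per arm, each with 12 density-scored and 3
proliferation-scored sections of 3.1 mm² (the cross-section of a 2-mm
punch). Section counts follow the mixed model above on the log10(X+1)
scale — default cell means range from ~1.4–1.8 (fresh/frozen) down to
~0.16–0.96 at day 6, with the caspase-inhibitor arm retaining density,
magnitudes chosen to resemble sheep cortical primordial-follicle
densities; fragment SD 0.2 and residual SD 0.1 log₁₀ units. The linear
predictor is truncated at zero before back-transform and counts are
rounded to the nearest non-negative integer, so densities are always
valid; at the default 3.1 mm² section area the rounding grid is fine
enough that the induced bias is negligible against the cell-mean
standard errors (~0.03 log units at 50 punches per cell). Degeneration and
proliferation flags are Bernoulli draws with per-condition probabilities
(defaults: degeneration 0.25 → 0.75 from F to D6, proliferation peaking
at 0.40 on day 2); these are free parameters expressing the qualitative
pattern — follicle quality degrades with culture time, proliferation is
culture-induced — and are not calibrated to any published proportions.

## Validation design

* **Oracle equivalence**: the entropy threshold is compared for exact
  equality against a naive exhaustive implementation on 200 images.
* **Density recovery**: 50 synthetic sections spanning ~0.02–0.30 true
  coverage; the pipeline density must sit within ±0.02 of the painted
  truth with mask Jaccard ≥ 0.7 (measured: errors ≲ 0.003, Jaccard
  ≳ 0.98).
* **Parameter recovery**: 100 replicates of a 200-fragment study with
  known cell means (e.g. a −0.8 log-unit day-2 shift), fragment SD 0.2,
  residual SD 0.1; each true mean should fall in its 95% containment-*t*
  interval in ≥ 90 replicates. This is a stochastic check: with true
  coverage at the nominal ~95%, any fixed replicate stream still has a
  small probability of dipping below the bar for one cell.
* **Degeneracy**: with zero fragment variance the REML cell means must
  match the OLS group means to 10⁻⁶ (they coincide exactly on balanced
  designs).
* **Type-I calibration**: 1000 null studies (2 arms × 2 conditions × 100
  punches × 2 sections, all effects equal); the pooled per-contrast
  rejection rate at α = 0.01 must lie within the 99% binomial bounds.
* **Design fidelity**: the default simulated study must contain exactly
  24 punches per arm with 12 + 3 sections per punch.

Problem sizes (64×64 oracle images, 512×512 sections, 100/1000 Monte
Carlo replicates) are chosen so the whole validation runs in minutes on
a single core while keeping the Monte-Carlo error of each check well
below its tolerance.

## Known limitations

* The tissue mask assumes a near-white background; it is not a general
  foreground detector.
* The entropy-threshold coherence fallback is tailored to
  spike-plus-mode histograms; images with three or more genuine modes
  may still threshold suboptimally.
* `global_proliferation` is an area fraction, not a cell count per mm²;
  nucleus instance counting is out of scope, as are color deconvolution
  and stain normalisation.
* Degrees of freedom use the containment rule only; no Kenward–Roger or
  Satterthwaite adjustment.
* The generator draws independent per-channel Gaussian noise; correlated
  illumination noise, which partially cancels in 2R − B − G on real
  scans, is not modelled.
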