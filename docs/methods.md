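# Methods

`spheroquant` quantifies tumor spheroids grown one-per-microchamber in
hydrogel arrays, from 2D microscopy planes: segmentation of each spheroid's
sectional outline on bright field, per-spheroid fluorescence metrics, growth
and subpopulation analysis, shape/texture morphometry, matrix-invasion
migration distances, and a kinetic model for NONOate nitric-oxide donors.
Because the original image data for such experiments is proprietary, the
package ships a synthetic-field generator with full ground truth; every
analysis stage is validated against that truth and against closed-form worked
examples.

## Segmentation (`segment`)

Spheroids appear on bright field as dark-rimmed objects on a bright
background. ROIs are defined by Sobel edge detection: gradient magnitude →
threshold → morphological closing (disk, default 3 px) → hole filling →
connected components, filtered to a plausible sectional-area window
(default 500–50 000 µm²).

Numerical choices:

- **Edge threshold.** Otsu's method on the gradient magnitude, floored at
  mean + 3 SD of the gradient so that a plane containing only noise (no
  objects) yields no spurious components.
- **One-pixel erosion after filling.** The Sobel magnitude of a step edge is
  nonzero on both sides of the boundary, so the filled component is dilated
  by about one pixel relative to the object. Left uncompensated this inflates
  area by ≈ 2/r (5 % at r = 40 px); a single-pixel erosion removes the bias.
  With it, measured areas on synthetic ellipses agree with the analytic area
  to ≈ 0.1 %.
- **Coordinates.** 0-based pixel indices; physical position =
  (index + 0.5) × µm/px (pixel-center convention). Border-touching ROIs are
  kept but flagged.
- **Chambers and tracking.** Each ROI is assigned to the grid cell containing
  its centroid (boundary ties resolve toward the lower row/col index, a
  deterministic tie-break). Chamber walls immobilize spheroids, so identity
  across timepoints is the shared chamber index; a chamber with two ROIs at
  one timepoint is flagged ambiguous and excluded from tracks rather than
  guessed.

## Fluorescence metrics (`quantify`)

Per acquired plane, background is the mean of all pixels lying outside every
ROI, estimated independently per plane and subtracted with negative residuals
clipped to zero. The positivity threshold is expressed in
background-subtracted units (default 2 × the background SD; the original
analysis software's thresholding rule is not recorded), which makes the
metrics exactly invariant to a constant offset applied to a plane.

- **mean FI** — mean of the ROI's above-threshold pixels (0 if none).
- **area fraction** — percentage of ROI pixels at/above threshold; monotone
  non-increasing in the threshold.
- **pixel CV** — SD/mean over *all* background-subtracted ROI pixels, no
  threshold (the dye-heterogeneity statistic, e.g. TMRM CV).
- **TMRM ratio** — one spheroid's mean FI at t2 over t1; undefined and
  flagged when FI(t1) = 0.
- **Cutoff rules** — mean ± sample SD (n−1 throughout) of a control
  population; positivity is a strict `>` at the upper cutoff (the boundary
  value itself is negative; the convention at equality is a package choice).
- **Staining-homogeneity QC** — CV of per-focal-plane mean FI along z; pass
  at CV ≤ 0.08 by default, matching the ≈8 % homogeneity typical of uniformly
  stained spheroids.

## Morphometry and cellometry (`morphometry`)

- **Sphericity** S = m00² / (2π(µ20 + µ02)) from the mask's second central
  moments — the standard moment-based roundness: 1 for an ideal disk,
  2ab/(a²+b²) for an ellipse with semi-axes a, b; line-like masks give S → 0
  and are flagged degenerate. Computed by direct pixel summation (verified in
  tests against an independent loop/fsum oracle).
- **Texture** — Shannon entropy (natural log) of the ROI gray-level histogram
  over 64 equal-width bins spanning the ROI's own min–max, plus pixel SD and
  gray range. Because binning is relative, entropy values are comparative
  between populations, not calibrated constants.
- **Cellometry** — cells in these non-adherent cultures stay globular, so a
  projected area A gives a sphere-equivalent volume via r = √(A/π),
  V = (4/3)πr³ (1 pL = 1000 µm³). Cells per spheroid = spheroid
  sphere-equivalent volume / mean single-cell volume, rounded to the nearest
  integer (≥ 1). This sphere assumption reproduces the published worked
  examples (4900 µm² / 1.69 pL → 153 vs 154 cells; 4880 µm² / 2.79 pL → 92
  vs 94) within 2.5 %. Doubling time Td = dt·ln2 / ln(N2/N1), NaN when
  N2 ≤ N1.

## Growth subpopulations (`growth`)

GR = area(after)/area(before); percent change = 100·(GR − 1). A control
population's mean ± SD GR (e.g. 1.23 ± 0.20, n = 400 → cutoffs 1.43/1.03)
splits treated populations into high-proliferating (GR strictly above the
upper cutoff), low-proliferating (strictly below the lower) and mid classes;
strict inequalities are a package choice, the source analyses do not state
the boundary case. K-means (k-means++/Lloyd, n_init = 10, seeded) runs on
z-scored features because GR (≈1) and FI (≈1–15 au) differ in scale; labels
are renumbered by ascending first-feature center so identical seeds give
identical, interpretable assignments. GR histograms default to
Freedman–Diaconis binning.

## Invasion (`invasion`)

Migration distance d = √((X1−X2)² + (Y1−Y2)²) between a spheroid's ROI
centroids at two timepoints, in µm; invariant under rigid motion of the
field and symmetric in the timepoints. Shape change during invasion
(flattening) is reported through sphericity rather than a dedicated metric.

## NO-donor kinetics (`nokinetics`)

Donor decay D(t) = D0·2^(−t/t½) (DETA/NO: t½ = 24 h at pH 7.4/37 °C),
cumulative NO = ν(D0 − D(t)) with ν = 2. NO consumption in medium is modelled
as a single first-order sink k_c — a calibration parameter, not a mechanism —
fixed from one measured pair (100 µM donor ↔ 100 nM NO). The quasi-steady
level ν·k_d·D0/k_c is then exactly linear in dose (1 µM → 1 nM). Valid for
t ≪ t½, while donor depletion is negligible.

## Statistics (`report`)

Two-sample/paired t, one-way ANOVA, Wilcoxon signed-rank and Kruskal–Wallis
via scipy, with α = 0.05 and raw (unadjusted) p-values — no multiple-testing
correction is applied, matching the source analyses; results carry an
explicit `adjusted=False` flag. Zero-variance paired shifts (exact constant
difference) are reported as p = 0 rather than scipy's NaN. Normality is not
auto-tested; the design is the caller's choice (nonparametric tests are the
sensible default for small groups).

## Synthetic generator (`synthetic`): what it emulates, and what not

The generator states the experimental world: a grid of pitch-p chambers with
occupancy ≤ 1 spheroid each; day-2 sectional areas N(4900, 2450²) µm²
(rejection-truncated at a small floor, 200 µm² by default — the truncation
shifts the realized mean by well under one standard error at n = 200); GR
drawn from a weighted normal mixture (control component 1.24 ± 0.20, matching
the ≈23.7 % control area increase and the 1.23/0.20 cutoff-defining
population); per-channel positive-area fractions, per-spheroid intensities
and two-timepoint multiplicative factors; Rayleigh-distributed invasion
displacements with uniform angles (clipped at the field edge and flagged).
Spheroids render as ellipses (axis ratio per phenotype, 1.0 round → ~0.35
rough, exercising the sphericity metric) with a dark rim, mid-gray optionally
textured interior and additive Gaussian noise clipped at zero; intensities
are arbitrary floats stored as 16-bit TIFF. One RNG is seeded per simulation
and consumed in a fixed documented order, so outputs are bit-reproducible.

It does **not** model optics (PSF, defocus, vignetting), cell-scale internal
structure, chamber-wall artefacts, uneven illumination, or spheroid
merging/fragmentation. A green recovery test therefore establishes that the
measurement chain is correct on well-formed images with known truth — not
that segmentation is robust to every real-world artefact.

## Known limitations

- Chamber-index tracking assumes spheroids never hop chambers; in collagen
  (no walls) pairing must come from nearest-centroid matching, as in the
  invasion example.
- Entropy depends on bin count and ROI min–max; compare only within a fixed
  binning.
- The cell-count model assumes spherical spheroids and a single mean cell
  volume; both bias N for flattened spheroids or mixed cell sizes.
- The NO steady state is a one-parameter calibration; it cannot extrapolate
  to media with different NO scavenging.
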