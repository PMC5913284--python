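# Methods

## The measurement problem

A MEMA experiment asks which microenvironment components shift the
frequency of a marker-defined cell state. Each printed spot exposes
~10–40 cells to one condition (ECM backbone ± one soluble factor);
conditions are replicated 5–20 times across the slide. The response is
not a population mean shift but the *fraction* of cells above
positivity gates for AXL and cKIT, so the whole chain is built around
per-cell calls aggregated to per-spot binomial counts.

## Packaged design

The canonical combinatorial design has 4 ECM backbones (COL1, COL4,
LAM1, LAM1+LAM5) and 28 soluble factors, totalling 228 unique
conditions. The published component list does not by itself determine
how 228 arises (4 backbones alone + 4×28 single-factor pairs gives
116), and the original condition table was never released. The
packaged table is therefore a **declared reconstruction** built by a
fixed rule chosen to be consistent with the published component list,
printing concentrations and condition count: each backbone alone (4),
each backbone × factor at the catalogue concentration (112), and the
same pairs at a 10-fold dilution (112). Concentration variants carry
distinct condition ids (`COL1|OPN` vs `COL1|OPN@lo`). LAM1's two
printed concentrations are represented as 100 µg/ml in LAM1 backbones
and 80 µg/ml inside the LAM1+LAM5 composite. Analyses that depend only
on backbone level and factor identity (the GLM, gating, clustering)
are unaffected by how the 228 rows are reached; anything
concentration-sensitive should treat the dilution series as synthetic
structure, not transcription.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as the package's canonical study conditions:

| parameter | default | meaning |
|---|---|---|
| `baseline_logit` | −2.0 | log-odds a cell is AXL⁺/cKIT⁺ on the COL4 reference (π ≈ 0.12) |
| `component_effects` | COL1 +1.6, LAM1 +0.7, LAM5 −0.2, OPN +1.2, IL-8 +1.0, COL6A3 +0.9 | additive log-odds contributions; all other components 0 |
| `density_mean` | 25 cells/spot | Poisson mean before geometric packing |
| `intensity_params` | lognormal; negative log-mean ln 60, positive ln 600, log-sd 0.35 | per-cell mean marker fluorescence (a.u.) by state |
| `background_level`, `noise_sd` | 100, 10 a.u. | flat background + Gaussian read noise |
| `nucleus_radius_px` | 5 px | nuclei drawn as anti-aliased disks, amplitude 1200 |
| `min_separation_factor` | 2.2 | minimum center distance in units of nuclear radius |
| `overlap_fraction` | 0 | fraction of cells deliberately placed touching, to exercise watershed splitting |

Effects are additive on the logit scale because that is the scale on
which the downstream GLM decouples components; the planted COL1-vs-COL4
difference of 1.6 logits gives the recovery suites a known truth of
the same order as real ECM contrasts. Marker intensities are lognormal
(right-skewed, strictly positive, like real immunofluorescence); a
cell's drawn mean fills its footprint uniformly, so the rendered image
preserves the drawn value exactly at zero read noise (verified to 1%).
Cell placement is rejection sampling inside the spot disk; when the
requested density exceeds packing capacity the realized count caps at
the geometric limit (ground truth always records what was actually
placed, so no downstream comparison is biased).

What the generator does **not** emulate: optical PSF blur,
illumination gradients, autofluorescence, cytoplasmic marker
localization, cell-cycle intensity variation, spot-edge effects, or
segmentation-error-correlated intensity bias. Passing recovery suites
therefore demonstrate correctness of the computational chain under its
own assumptions — not robustness to real microscopy artifacts.

## Imaging chain

Background: the histogram mode is taken as background and the
threshold is twice the mode, then subtracted with clipping at zero.
For integer images the mode is the exact most-frequent value; float
images use 256 equal-width bins over [0, max] with ties broken toward
the lower bin (a conservative threshold). Segmentation markers are
local maxima of the Gaussian-smoothed (σ = 2 px) corrected nuclei
channel, at least `min_distance` (default: expected nuclear radius)
apart, restricted to the foreground; watershed floods the inverted
smoothed image; objects under `min_area` = 20 px are removed.
Intensities are measured on the background-subtracted images —
subtraction precedes all measurement, and the same scale feeds the
gates. Neighbor count uses centroid distance ≤ 3× the median
equivalent radius (the field reports "neighbors" without a standard
rule; this one is scale-adaptive and parameter-light).

Note on shape features: solidity of a rasterized disk is below 1
because the convex hull of pixel centers overestimates area at small
radii (≈0.93 at r = 10 px, ≈0.96 at r = 20 px); shape thresholds in
tests account for this discretization.

## Gating

Reference cells are those on COL4-alone spots (not COL4 + factor): the
premise is that COL4 suppresses both markers, so its cells estimate
the negative distribution. Gate = mean + k·SD with sample SD
(n−1) and k = 1 by default; k is a knob, and a
`col4_containing` selector is provided for the looser convention.
Positivity is strictly above the gate; ties are negative
(conservative). A minimum of 50 reference cells is enforced. Spot
summaries are per-spot; condition summaries are **unweighted** means
over usable (non-empty) spots — replicate spots, not cells, are the
exchangeable unit. Empty spots are counted and logged; conditions with
no usable spots yield flagged rows rather than disappearing.

## GLM and post-hoc contrasts

Per-spot (successes, failures) = (double-positive, rest) counts enter
a binomial GLM with logit link; the design matrix has one indicator
per ECM backbone level (reference COL4 dropped) and one per soluble
factor (baseline: absent). The binomial family fits a count-fraction
response and yields logit-scale coefficients of the size real ECM
contrasts show; a quasi-binomial dispersion (Pearson χ²/df) is
reported alongside so over-dispersion is visible rather than hidden.
Factors present on fewer than 2 spots are excluded with a warning.
Separation raises an explicit error pointing to the bias-reduced
fallback, a Firth/Jeffreys-penalized scoring iteration implemented
here (penalized score `U + hᵢ(½ − μᵢ)` with hat diagonals `hᵢ`).

Pairwise ECM contrasts use a **single-step max-|z| adjustment**:
adjusted `pᵢ = P(max⁡ⱼ |Zⱼ| ≥ |tᵢ|)` with `Z` multivariate normal under
the estimated contrast correlation, evaluated by 100,000 seeded Monte
Carlo draws (deterministic given the fixed internal stream). This is
the standard generalization of Tukey's HSD beyond balanced Gaussian
ANOVA, where the exact studentized-range law does not apply. The same
adjustment runs over the factor family in `rank_factor_effects`.
Calibration is verified by simulation: the family-wise false-positive
rate over 4 equal levels sits near the nominal 0.05.

`compare_lines` reports two documented statistics rather than one
guessed "coefficient of variance": the variance of per-condition
fraction differences between lines, and a likelihood-ratio test for a
line × ECM-class interaction in the joint spot-level GLM.

## Clustering and embedding

Condition × feature matrices are z-scored per feature (constant
features dropped with a warning), clustered with Euclidean distance
and average linkage (rows pre-sorted by condition id, so leaf order is
deterministic), and embedded with t-SNE (perplexity 30 by default,
PCA initialization, 1000 iterations, exact method below 200 points,
single-threaded, fixed seed → bitwise-reproducible coordinates). The
feature vector order is fixed: double-positive fraction, subpopulation
AXL/cKIT means, ungated AXL/cKIT means, cell count per spot,
eccentricity, solidity.

## Assays

ΔΔCt uses the arithmetic mean of control-gene Ct within each sample;
the control sample's folds are exactly 1 by construction, and folds
are invariant to adding any constant to all Ct values. The 4PL fit
runs in log-dose with initialization a = min y, b = max y,
c = geometric-mean dose, d = 1, Levenberg–Marquardt least squares and
up to 3 perturbed restarts; flat data are flagged degenerate rather
than fitted silently. At the midpoint dose the curve passes through
(a+b)/2 exactly, which is what makes c the IC50. EdU analysis is
percentage of positive cells per replicate with a Welch t-test
against the control condition's replicates.

## Problem sizes

The recovery and calibration suites run at sizes chosen to make the
statistical checks decisive on a single CPU: contrast recovery uses
200 simulations of 10 spots × ~200 cells per condition (estimate SE
≈ 0.08, so the ±0.2 recovery band is a > 2σ margin); family-wise
calibration uses 500 null simulations; the end-to-end run renders the
full 228-condition array at 5 replicates and ~25 cells per 64-px spot
(~17,000 cells), enough that the three planted factors separate from
25 nulls by > 4 SE. The acceptance script uses the same structure at
50/200 simulations.

## Known limitations

- The packaged 228-row design is a reconstruction (above); per-condition
  concentrations in it are conventions, not measurements.
- Gating assumes the reference condition truly suppresses both markers;
  if it does not, gates inflate and fractions compress toward zero.
- Gate-based calls carry misclassification, and nondifferential
  misclassification attenuates logit contrasts toward zero; end-to-end
  estimates therefore sit below the planted (or true) effects, with the
  attenuation set by how well the gate separates the two intensity
  distributions and how precisely the reference moments are estimated
  from the finite pool of reference-spot cells.
- The GLM treats spots as independent binomials; slide-level or
  print-run random effects are out of scope, and over-dispersion is
  only reported, not modeled.
- Watershed parameters are tuned for round, mildly touching nuclei;
  densely clumped or highly aspherical nuclei will under-segment.
- t-SNE coordinates are for visualization; distances between distant
  clusters are not quantitatively meaningful.
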