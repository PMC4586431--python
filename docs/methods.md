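# Methods

This note documents the models, parameter choices and numerical decisions
behind `nucspark`, and what the synthetic-data validation does and does not
demonstrate.

## Detection model

Localized Ca²⁺ signals are detected with the classical threshold-and-fit
scheme used by spark-analysis tools:

1. **Baseline.** F₀ is the per-pixel 20th temporal percentile, which is
   unaffected by sparse bright transients as long as a pixel is event-free
   in at least ~20% of frames. The noise SD map is estimated from temporal
   residuals: a MAD-based robust scale first, then the plain SD of residuals
   within 3 robust-σ of their median, so event frames do not inflate it.
   Recorded line scans need events to be temporally sparse for the same
   reason; the line-scan generator therefore defaults to 10 s records.
2. **Threshold.** Candidate pixels satisfy F > F₀ + c·SD with c = 3.6, the
   conventional spark threshold coefficient. Candidates are grouped with
   26-connectivity over (t, y, x), which merges in-plane 8-neighbours and
   any components overlapping across consecutive frames into one event,
   reported at its peak frame.
3. **Spatial filter.** A component must contain ≥ 10 suprathreshold pixels
   in its peak frame. The published parameter ("spatial filter threshold
   10") is interpreted as a pixel count; it is configurable so a
   physical-size reading can be tested.
4. **Gaussian fit filter.** Each surviving component is fitted with an
   elliptical 2-D Gaussian plus offset on the (F − F₀)/F₀ image in a padded
   window; the fit's coefficient of determination must reach 0.5.
   FWHM = 2√(2 ln 2)·√(σₓσᵧ); amplitude is the fitted peak (the raw
   suprathreshold maximum is stored alongside). Degenerate fits — center
   outside the window, runaway width — are rejected.

Amplitude is ratio-based, not offset-invariant: adding a camera offset to
every pixel raises F₀ but not F − F₀, so (F − F₀)/F₀ drops. This is tested
explicitly. No correction is applied for amplitude underestimation at slow
frame rates.

**Known limitation.** Event count is monotone non-increasing in the
threshold coefficient over its operating range (≳3). Far below that, noise
pixels bridge suprathreshold components and the Gaussian-fit filter rejects
the merged blobs, so counts can *drop* as the threshold is lowered. The
monotonicity test therefore covers c ∈ [3, 12].

For line scans, FDHM is measured on the temporal profile through the
event's spatial center: width at half of (peak − F₀), linearly interpolated
between samples. An event still above half maximum at either record edge is
flagged as a lower bound.

## Nucleus segmentation and distances

Nuclei are bright regions of the smoothed DNA-dye frame above an Otsu
threshold (data-driven, hence invariant to positive intensity rescaling),
hole-filled, with components below 20 μm² discarded as debris. In
membrane-dye mode the image is inverted first, detecting nuclei as
stain-free voids — a lower-confidence proxy. Hand-drawn outlines can be
substituted via `masks_from_labels`, since any automated segmentation is a
proxy for expert outlining.

Point-to-nucleus distance is the Euclidean distance to the nearest nucleus
*boundary* (distance transform of the complement, sampled at the query
pixel), zero inside the mask with boundary pixels counting as inside.
Boundary distance — rather than centroid distance — keeps the 2 μm
perinuclear rule independent of nucleus size. Distances are exact to pixel
quantization (verified against brute-force minimization); queries are
resolved at the containing pixel, so sub-pixel positions carry a ≤ half-
pixel uncertainty. Ties between nuclei break deterministically to the
lowest nucleus id.

The peripheral/central nucleus label is a heuristic: a nucleus is
peripheral when its centroid lies closer to the fiber boundary than its own
minor semi-axis.

## Classification

* NLCS ⇔ centroid inside a nucleus mask; PLCS ⇔ outside but within
  `plcs_distance_um` (2 μm, inclusive); CLCS otherwise. The three labels
  partition every event list; with no nuclei supplied all events are CLCS
  (infinite distance) with a warning.
* NGCS has no published operational definition, so one is constructed here:
  a maximal run of ≥ 2 frames where the mean nucleus (F − F₀)/F₀ reaches
  0.2 **and** ≥ 80% of nucleus pixels are individually above that level.
  The coverage gate separates a genuine whole-nucleus rise from a bright
  localized event inside the nucleus. Two or more runs in one record mark
  the trace oscillatory. All three parameters are exposed.
* Axial containment: with d_m = ½(r_ax,A + Δr_ax,A + r_ax,B + Δr_ax,B), an
  event is `verified` when Otsu-positive DNA pixels overlap its footprint
  in ≥ 1 plane at z ≥ plane + d_m and ≥ 1 plane at z ≤ plane − d_m;
  `indeterminate` when the stack does not span both offsets. Verification
  is monotone in d_m by construction.

## Resolution estimation

Beads are local maxima above background + 5 SD (stack median and MAD-based
scale), deduplicated within one estimated lateral FWHM. Per bead, 1-D
Gaussians with free offset are fitted along x, y, z. Numerical safeguards,
each of which measurably removed a bias on synthetic stacks:

* profiles are averaged over the perpendicular 3×3 neighborhood — for a
  separable Gaussian this only rescales the amplitude while suppressing the
  narrowing bias of fitting through a noise-selected maximum voxel;
* the profile center is recentered on the local intensity centroid;
* fits use a local window (2× the lateral-FWHM guess) so neighboring beads
  on the same line cannot corrupt the single-Gaussian model;
* a per-axis R² ≥ 0.5 gate skips non-Gaussian profiles (false peaks,
  clipped beads), counted as QC skips with a warning.

Lateral FWHM is the mean of the x and y fits (anisotropy > 20% warns);
aggregates are mean ± S.E.M. across beads (S.E.M. 0 for a single bead).
Clustered, unresolved beads inflate the apparent FWHM — tested as a
directional property. d_m is reported rounded half-up to two decimals, full
precision retained.

## Statistics

Frequencies are n/(area·duration)·1000 in events/(1000 μm²·s); nucleus
frequency uses summed nucleus areas, cytosol uses fiber-minus-nuclei area,
so the cell numerator is the sum of the compartment numerators. A unit
(fiber or nucleus) "responds" with a class if it has ≥ 1 event of that
class — duplicate events change nothing; INCS responders are the union of
NLCS and NGCS responders. Report fractions are rounded half-up to whole
percent, raw values retained. Per-fiber cellular frequencies normalized to
the control-condition mean use the fiber area × analyzed duration
definition. Agreement between algorithmic and manual responder sets is
|A ∩ M| / |M| — units flagged only by the algorithm do not enter the
denominator, because the manual annotation is the reference. No inferential
testing between conditions is performed.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the acquisition geometry of the analysis —
512×512 px frames at ~0.2 μm/px and 0.82 s/frame (8-bit), line scans at
0.063 μm/px and 800 lines/s — with rectangular or elliptical fibers,
elliptical nuclei (ellipsoids in z), sparks as isotropic 2-D Gaussian
increments of configurable FWHM/amplitude/duration (rectangular temporal
profile by default, optional linear decay), whole-nucleus NGCS rises, 3-D
Gaussian bead stacks, and nucleus z-stacks blurred by the axial PSF. Noise
follows the standard confocal model: Poisson on expected counts, then
additive Gaussian read noise. Pixel centers sit at (i + 0.5)·pixel_size;
all geometry is in μm. A config plus its seed determines every output bit.

No quantitative noise levels were published for the original recordings, so
the defaults (baseline 30 counts, read noise SD 2, shot noise on; DNA
nucleus interior at 4× background) are fixture choices, not claims about
the data. Test SNRs are set explicitly where a property depends on them:
detector sensitivity at SNR 5 (peak increment/noise SD), resolution
recovery at SNR 10. The SNR-10 bead fixture uses a background of 100 counts
so that read noise does not clip at zero — physical detectors sit on a
positive offset; clipping would bias the fitted offset and hence the FWHM.

Not emulated: photobleaching, fiber contraction and shrinkage artifacts,
sarcomeric banding, dye kinetics, chromatic shifts, satellite cells.
Passing tests therefore demonstrate correctness of the algorithms under
the stated noise model and geometry — not robustness to every property of
real recordings; in particular events restricted by nuclear boundaries
(non-Gaussian shapes) are harder to detect in practice, which is why the
optional manual-annotation path exists.

## Problem sizes and determinism

The bundled end-to-end fixture uses two 256×256 px, 50-frame fibers with
40 events in total — the acquisition pixel size and timing at a reduced
field of view, chosen so a complete run takes seconds and the full pipeline
(simulate → average/drift-QC → segment → detect → classify → summarize)
stays exercised end to end. Runs are byte-deterministic for a fixed config
and seed; stochastic tests are seeded, hypothesis properties derandomized.
Stage failures abort with the stage name and leave partial outputs next to
a `FAILED` marker.
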