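# Methods

## The quantification model

A mid-oogenesis *Drosophila* oocyte imaged in a single confocal plane shows
a closed plasma-membrane contour with an antero-posterior intensity
asymmetry for polarity proteins such as PAR3.  The pipeline quantifies that
asymmetry from three manual anchor points: `a1` and `a2` flanking the
anterior membrane (the oocyte/nurse-cell interface) and `p` at the middle
of the posterior membrane.

1. **Anchor snapping.**  Each click is moved to the brightest pixel within
   `snap_radius` (default 5 px), i.e. onto the membrane intensity ridge.
   Ties on flat-topped ridges resolve to the candidate nearest the click,
   then lexicographically by (row, col), so snapping is deterministic and
   does not drag anchors along a uniform band.

2. **Perimeter tracing.**  The membrane band is segmented by intensity and
   the oocyte outline extracted as a closed, 8-connected pixel chain
   (Moore-neighbour boundary tracing), oriented counter-clockwise and
   starting at `a1`.  Because membrane domains can differ several-fold in
   brightness, a single global threshold is fragile: the default
   `threshold_method="auto"` collects the class boundaries of three- and
   four-class Otsu splits of the histogram (plus midpoints between
   neighbouring boundaries, since sparse membrane classes leave the
   cytoplasm/membrane boundary unsampled), tries them brightest-first, and
   keeps the first candidate whose largest connected component (a) forms a
   closed ring — hole-filling must add more area than the band itself —
   and (b) passes within `snap_radius` of all three anchors.  The filled
   blob is then eroded by half the estimated band thickness (capped at
   3 px) so the boundary rides the intensity ridge rather than the band's
   outer edge.  A fixed-percentile threshold (`"percentile"`, default 75th)
   remains available for images that are mostly background, and
   `densify_polygon` accepts a hand-drawn vertex list as a manual escape
   hatch.

3. **Arc length.**  A raw 8-connected chain with step weights 1 (axial) and
   √2 (diagonal) overestimates the length of smooth digitized curves by
   ~5–6 % — the classic staircase bias (on digital disks of radius 40–80 px
   we measure +5.4 %).  The default `arc_rule="smoothed"` therefore
   measures per-step lengths on a periodically Gaussian-smoothed copy of
   the chain (σ = 3 vertices), which tracks analytic circle and ellipse
   perimeters to better than 1.3 %.  The raw rule is kept as
   `arc_rule="chain"`; it is exact for axis-aligned polygons but should not
   be used for perimeters of smooth cells.  Segment lengths always sum to
   the perimeter exactly because they partition the same per-step table.

4. **Four-domain partition.**  Anterior is the arc between `a1` and `a2`
   not containing `p`.  The posterior domain is an arc of length
   `posterior_fraction × (perimeter − anterior length)` centred by arc
   length on `p`; the two remaining arcs are lateral 1 (adjacent to `a1`)
   and lateral 2.  The boundary placement between lateral and posterior
   membrane is not biologically sharp; a fixed arc fraction (default 0.20)
   is the simplest stage-independent convention and is exposed in the
   configuration.  A posterior arc that would reach into the anterior arc
   is rejected as a configuration error.

5. **Measurement.**  Each domain's intensity is sampled in a band of
   `band_width` pixels (default 3, odd) normal to the trace, giving an
   along-membrane profile (one band-averaged value per trace point) whose
   grand mean is the domain mean.  The **quantity** of a domain is
   mean × arc length — the band-integrated signal, which is additive across
   domains.  The cytoplasm is the trace interior farther than `margin`
   pixels (default 6, required ≥ band_width/2) from the trace, optionally
   minus a nucleus mask; the region is built from a hole fill plus a
   Euclidean distance transform, which makes it exactly equivariant under
   90° image rotation (a scanline polygon fill is not).

6. **Nurse-cell anterior correction.**  The anterior interface carries the
   oocyte membrane plus the apposed nurse-cell membrane, unresolvable at
   confocal resolution.  The user measures the mean intensity of a *simple*
   and a *double* nurse–nurse membrane; their difference is the net signal
   of one membrane with the diffuse background cancelled, and is subtracted
   from the anterior band mean (`nurse_correction="difference"`, default).
   Subtracting the raw simple-membrane mean (`"simple"`) is also provided
   for comparison but double-counts the diffuse background.  Corrected
   means are clamped at 0 with a warning, since grey levels cannot be
   negative.

7. **Normalization.**  Quantities are divided by the oocyte total
   (anterior + lateral + posterior + cytoplasm) to give **fractions**,
   cancelling expression level and acquisition settings; membrane fractions
   are further divided by their arc length to give **densities**,
   cancelling membrane growth between stages.  Cortical densities do not
   sum to 1 by construction.  The two readouts are the **posterior
   exclusion ratio** (lateral density / posterior density; above 1 the
   protein is excluded from the posterior membrane, below 1 it accumulates
   there) and the **asymmetry ratio** (anterior density / posterior
   density).  A posterior density of exactly 0 yields flagged `+inf`
   ratios rather than an exception so batch tables stay rectangular.

## Colocalization

Pearson's r is computed over a boolean region of interest only.  Manders
coefficients are the thresholded fractions: m1 is the share of
above-threshold channel-1 signal lying on above-threshold channel-2
support (and symmetrically m2); this matches the "fraction of signal
overlapping" reading, while the classic intensity overlap coefficient is
available separately since the two are often conflated.  Per-channel
thresholds default to Otsu on the masked histogram — deterministic and
parameter-free.  A coefficient whose channel has no above-threshold signal
is reported as undefined, not 0.  The negative control rotates channel 2
and the mask by 90° and recomputes Pearson's r on the overlap of original
and rotated masks (on non-square frames the full frame rotates and the
statistic is taken on the common region); only chance colocalization
survives.  The control is blind to patterns that are themselves 90°
rotation-symmetric, which a dedicated test documents.

## FRAP

A recovery acquisition carries `n_prebleach` frames (6 by default, the
standard protocol) before the bleach.  The trace and partition are built
once on the first frame and reused — no drift correction, appropriate for
immobilized egg chambers over ~20 min.  Per-frame anterior and posterior
quantities are then normalized two ways: *rebased* (bleach-frame value
subtracted; the curve starts at exactly 0 and its sign reads as gain or
loss) and *pre-bleach normalized* (divided by the domain's own pre-bleach
mean; 1.0 is the unbleached level).  Recovery is summarized by the mean of
the last three frames and the sign of the rebased tail — no curve fitting
by default, since plateau and sign are the robust readouts; a
saturating-exponential fit (`fit_recovery`) is available when a rate is
wanted.  No correction for acquisition photobleaching is applied; a
reference-region correction can be layered on by the caller.  The bleach
frame is normally declared from the acquisition; when absent it is
detected as the largest single-step fractional drop of the anterior
quantity (> 20 %).

## Group statistics

Per-oocyte metrics are compared with the two-sided Mann-Whitney U test:
exact null distribution when the combined sample size is ≤ 16 and there
are no ties, otherwise the normal approximation with tie and continuity
corrections; the method used is always recorded.  Summaries report
mean ± SEM (SD with n−1 denominator; SEM set to 0 and flagged at n = 1),
median, type-7 linearly interpolated quartiles, and Tukey whiskers (most
extreme points within 1.5 IQR of the hinges).  p-values map to the usual
star labels (p < 0.05 *, < 0.01 **, < 0.001 ***, < 0.0001 ****).  No
multiple-testing correction is applied.

## The synthetic-data generator

Real egg-chamber images cannot be redistributed, so every routine is
validated against `oopolar.synthetic`:

* **Oocyte images** — an elliptical membrane band (default semi-axes
  80 × 50 px, width 3 px) whose anterior (±35°), lateral and posterior
  (±25°) arcs carry programmed mean grey levels (defaults 200/100/100 over
  cytoplasm 30 and background 5), with the nurse compartment on the
  anterior side: the apposed oocyte + nurse membranes are painted as one
  line carrying the sum of both intensities (default nurse membrane 60),
  and one simple and one double nurse membrane line (values b + m and
  b + 2m over nurse cytoplasm b = 30) give the background estimator
  something to measure.  Because each domain is painted with a uniform
  mean, the programmed density ratios reduce to intensity-mean ratios,
  which is what recovery tests assert.  Noise is optional Poisson (shot)
  followed by Gaussian (read, default σ = 5); the detector model of any
  particular microscope is not emulated.
* **Punctum pairs** — `round(n·f)` of n channel-1 puncta share centres with
  channel-2 puncta; the rest are kept > 4σ from every channel-2 punctum so
  their supports are disjoint.  Gaussian blobs (σ = 1.5 px, amplitude 100)
  plus read noise.
* **FRAP stacks** — pre-bleach frames at the programmed means, then the
  anterior membrane follows a saturating-exponential recovery toward a
  plateau fraction of its pre-bleach level while the posterior declines
  exponentially to a floor.  The nurse compartment is omitted so the
  anterior quantity is purely the oocyte membrane.

Everything is deterministic in (spec, seed); ground truth (anchor
positions, per-domain masks, analytic arc lengths, true fractions,
densities and ratios, and the posterior arc fraction that reproduces the
painted posterior domain) is computed before noise.

**What passing tests do and do not show.**  The generator exercises the
geometry, normalization and statistics of the pipeline against known
truth.  It does not contain follicle cells, a point-spread function,
out-of-focus light, irregular (non-elliptical) oocyte outlines,
intra-domain intensity gradients, or stage-to-stage morphology changes;
accuracy on real images therefore still depends on sensible anchor
placement and on the tracer finding the membrane, for which the polygon
escape hatch exists.

## Problem sizes used in the automated checks

The acceptance script regenerates everything at run time: 100 randomized
oocytes for the conservation check, 20 seeds per ratio setting
(asymmetry 5 / exclusion 2, and an isotropic control), 5 nurse-corrected
oocytes, 20 punctum pairs per programmed fraction, all ~2,000 tie-free
rank arrangements with n1 + n2 ≤ 10 against a full enumeration oracle plus
10,000 null draws at n = 8 vs 8, and 20 noiseless FRAP stacks of 20
frames.  These sizes give stable medians and sub-percent Monte-Carlo error
on the reported rates while keeping a full run under a minute on one core.

## Known limitations

* The four-domain boundary convention (fixed posterior arc fraction) is a
  package convention, not a biological boundary; recovered exclusion
  ratios depend on it when lateral and posterior intensities differ, so
  comparisons should hold it fixed.
* Band measurement at domain boundaries mixes neighbouring domains over
  ~2–3 px, biasing strong programmed ratios (e.g. 5 recovers as ~4.6);
  the bias is shared between conditions being compared.
* Single-plane analysis only; no 3-D membrane surfaces.
* Raw quantities are not comparable across acquisitions with different
  settings; only the normalized fractions, densities and ratios are.
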