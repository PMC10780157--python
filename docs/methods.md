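# Methods

## Problem and scope

The package measures inter-rater accuracy of sulcus identification on 2D
endocast views.  Input is one set of colour-coded label images per rater
(five anatomical views: anterior, superior, posterior, lateral-left,
lateral-right) plus one reference set of the same views holding the sulci
extracted from the subject's brain segmentation.  Every coloured stroke is
isolated into a binary pixel mask that preserves its position and size in
the view frame, so all comparisons happen in the raster coordinates of the
view (distances are in pixels; images of one cohort must share a common
resolution, which is enforced rather than resampled away).

## Similarity model

For a drawn stroke *A* and reference sulcus *B* in the same view frame:

* **Dice**: `2|A∩B| / (|A|+|B|)`, on the full-width stroke.  It is 1 iff
  the pixel sets are equal and 0 iff they are disjoint, and carries no
  information once the stroke misses the reference entirely.
* **Centroid streamline**: raters draw with different pen widths, so the
  distance measure uses a width-free summary of the stroke.  The
  independent axis is the axis along which the stroke's bounding box is
  longer (ties favour horizontal); a regression of the transverse on the
  independent coordinate is fitted to the stroke's pixels and evaluated at
  every occupied independent integer, rounded half-away-from-zero and
  clipped to the bounding box — exactly one streamline point per occupied
  independent coordinate.  The default smoother is an AdaBoost ensemble of
  fully grown regression trees (`random_state` fixed, so extraction is
  deterministic); with one feature a fully grown tree predicts the
  per-coordinate transverse mean, which keeps the streamline centred inside
  the stroke while the ensemble damps resampling noise.  A direct
  per-coordinate transverse mean is available as `smoother="mean"` and is
  the automatic fallback for degenerate clouds with fewer than four
  distinct independent coordinates.  References keep all their pixels — no
  centroid — because reference sulci branch and curve too much for a single
  streamline.
* **MMED**: for each streamline point, the Euclidean distance to the
  nearest reference pixel (KD-tree query); the MMED is the mean of these
  minima.  It is directed (drawing → reference) and deliberately so: it
  asks "is what the rater drew near the true sulcus", not whether the rater
  covered the sulcus' full extent (that is Dice's job).
* **Normalization and SISS**: `MMEDn = 1 − MMED/θ` for `MMED < θ`, else 0,
  with threshold θ = 100 px by default; `SISS = (Dice + MMEDn)/2`.  An MMED
  at or beyond the threshold corresponds to a stroke so far from the
  reference that no similarity is left, and mapping it to 0 (rather than
  carrying the raw value through) keeps SISS inside [0, 1] and the
  normalization continuous and non-increasing.  The threshold is a
  parameter everywhere it appears.  A structural consequence used as a
  pipeline-wide invariant: `SISS ≤ 0.5 + Dice/2`, so SISS > 0.75 requires
  Dice > 0.5 — scores above 0.75 demand near-complete overlap, not just
  proximity.

## Labels, merging, correction

The nomenclature table has 42 numbered entries.  Three merge rules pool
fine-grained variants that cannot be told apart on an endocast: the central
sylvian variant into the central sulcus `S.C`; the five pre-central
branches into `S.Pe.C` (a derived canonical entry with no table number);
and the retro-central transverse ramus into `F.I.P.Po.C.inf`.  After
merging, 36 canonical labels remain.  Occipital variants that raters add on
their own initiative are registered as extras and pooled under the single
canonical `Occipital` label, since the reporting has one occipital row.

Corrections are declarative input (a CSV), keyed by rater, view, hemisphere
and drawn label: each entry lists one or more true labels (the drawing is
duplicated and scored once per label when it plausibly matches two adjacent
sulci) or the sentinel `NONE` (the mark corresponds to no real sulcus and
is dropped).  The correction key includes the hemisphere because non-lateral
views contain both hemispheres and a hemisphere-free key would be
ambiguous.  Scoring without corrections is the *raw* analysis (how well do
raters name what they see); with corrections it is the *corrected* analysis
(how well do raters perceive grooves at all).

## Aggregation and zones

Scores are averaged per (canonical label, hemisphere, view) cell,
unweighted over the raters who drew that cell; per-hemisphere marginals are
unweighted means over the view cells that exist.  Cells nobody drew are
missing, never zero — zero is a valid (bad) score, absence is not.
Identification rate is the fraction of the *full* cohort that drew a cell
(not of per-view participants), configurable.  The zone classification uses
each label's best *qualifying* view — a view where the identification rate
strictly exceeds 20 % — and assigns green for mean SISS strictly above 0.5,
yellow for (0.4, 0.5], red otherwise or when no view qualifies.  The strict
boundaries are a package convention; the sources of the thresholds leave
the boundary cases unspecified.

Drawings whose (view, hemisphere, canonical label) has no reference sulcus
are excluded from the tables and listed in a separate unmatched report:
they represent marks with no underlying sulcus, a phenomenon worth counting
but not averaging into sulcus reliability.

## Synthetic cohort generator

The generator exists because the expert drawing data are not
redistributable.  It emulates the statistical structure the analysis
assumes, with interpretable knobs, not the anatomy itself:

* **References**: splines through a few control points, rasterized as
  function graphs (one pixel per independent coordinate) and dilated to a
  width of 2–5 px on a 600 × 600 frame.  The packaged layout provides 12
  sulci across all five views, including adjacent confusable pairs
  (central/pre-central, intermediate/superior frontal,
  parieto-occipital/occipital), without stroke crossings.
* **Rater noise** (per drawing, seed-deterministic): a rigid offset of
  magnitude `displacement_px` in a uniformly random direction; a smooth
  random warp (Gaussian-filtered white noise along the stroke, amplitude
  `smooth_deform_amp`, correlation length `smooth_deform_scale`); blending
  toward the straight chord by `rectilinear_bias` (the habit of drawing the
  textbook shape of a sulcus rather than the observed groove); truncation
  of `truncation_frac` of the points from a random end; re-rasterization at
  the rater's pen width (1–7 px); omission with probability `p_omit`; and
  label swapping within a designated confusable pair with probability
  `p_mislabel` (a swap keeps labels unique within a view, and pixels always
  follow the *true* reference — only the name is wrong).  The truth log
  records every perturbation, so the correction file for the corrected
  analysis is derived mechanically from it.
* **Offset magnitude is deterministic, not Gaussian.**  With a Gaussian
  magnitude the realised noise level of a finite cohort is itself random —
  a "far displaced" cohort can contain drawings that happen to land on the
  reference, and the saturation regime is never certain.  Fixing the
  magnitude makes the knob equal the realised positional error, which is
  what parameter-recovery checks need: cohort mean SISS is 1.0 at zero
  noise (width-1 strokes), decreases monotonically in each noise knob, and
  saturates to 0 when the offset far exceeds the MMED threshold.
* **Default noise levels** (`displacement_px=4`, `smooth_deform_amp=3`,
  `p_omit=0.2`, `p_mislabel=0.15`, `rectilinear_bias=0.2`,
  `truncation_frac=0.1` in the CLI) were chosen once to land cohort mean
  SISS in the 0.4–0.6 band with a visible raw-vs-corrected gap — the regime
  the reliability tables are designed to resolve.
* **What it does not model**: real anatomy (branching sulci, view-dependent
  foreshortening of a 3D surface), rater-specific systematic bias fields,
  spurious marks with no underlying sulcus, or disagreement about the
  reference itself.  Passing tests therefore validate the *pipeline* —
  scoring, merging, correction, aggregation — not any claim about how
  accurately real experts read real endocasts.

One cohort seed deterministically derives per-rater seeds; a fixed seed
reproduces the full fixture tree byte-for-byte, PNGs included.

## Numerical and I/O choices

* Rounding half-away-from-zero for streamline pixels; scores kept at full
  precision internally, rounded to 2 decimals only at serialization.
* PNG raster I/O (RGB; alpha ignored).  Anti-aliased edge pixels are
  assigned to the nearest palette colour within Euclidean RGB distance 30,
  else treated as background; unmapped colours are an error in strict mode
  and a logged warning otherwise.  A label drawn as several disconnected
  strokes in one view is one mask (pixel union) — scoring is per sulcus per
  view, not per stroke.
* Composite view PNGs paint strokes label-by-label, so crossing strokes
  would lose the overwritten pixels of the earlier label; the packaged
  reference layout avoids crossings.
* Synthetic palette colours come from a 5-level RGB grid with near-white
  colours excluded, guaranteeing ≥ 64 pairwise separation.
* Problem sizes in the test suite (3-reference recovery fixtures, cohorts
  of 1–8 raters for simulation-based checks, 14 raters where the cohort
  size itself is the property) keep full-suite runtime around two minutes
  while leaving every property measurable.

## Known limitations

* The centroid streamline is single-valued along the independent axis, so
  loops or strongly U-shaped strokes collapse; the bounding-box axis choice
  handles ordinary oblique strokes but not pathological ones.
* MMED's direction means a tiny, accurately placed stroke scores high on
  MMEDn however little of the sulcus it covers; Dice is the counterweight,
  and SISS should always be read with both components available (the score
  objects and CSVs keep all four values).
* The zone classifier inherits the arbitrariness of its thresholds; they
  are parameters, and the defaults simply follow the established 0.4/0.5
  and 20 % conventions.
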