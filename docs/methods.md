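# Methods

## Model and assumptions

`eitzones` operates on reconstructed relative-impedance image sequences,
one per PEEP step of an incremental trial. The method assumes (i) pixel
impedance change is monotone in regional air content, so an averaged
end-expiratory image maps end-expiratory aeration and the
end-inspiration-minus-end-expiration (tidal) image maps regional
ventilation; (ii) all frames are referenced to a common low-impedance
baseline for the whole trial, so end-expiratory levels are comparable
across steps; and (iii) the subject's breathing is regular enough that
the final breaths of a step represent its steady state.

Lung regions are defined relative to each image's own maximum — pixels
strictly above 25 % of the end-expiratory maximum, and strictly above
20 % of the tidal maximum. Relative thresholds make every mask invariant
under positive scaling of the impedance values, which is essential for a
modality that carries no absolute calibration. The end-expiratory
threshold is 5 % higher than the tidal one because end-expiratory images
are noisier than difference images. The functional categories are set
differences of those two masks (overinflated, cyclic) or of the
end-expiratory masks of two steps (recruited against a reference step).
A pixel may legitimately be both recruited and overinflated; counts are
reported per category without de-duplication.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `ee_frac` | 0.25 | fraction of image max | end-expiratory lung-region threshold |
| `tidal_frac` | 0.20 | fraction of image max | tidal lung-region threshold; 5 % below `ee_frac` |
| `breaths` | 5 | breaths | averaging depth at the end of each step, suppresses frame noise by ≈ √5 |
| `reference_peep_cmH2O` | 6 | cmH2O | recruitment reference; low enough to precede recruitment, high enough that end-expiratory images are above baseline noise |
| `rebase_mode` | `"none"` | — | input frames are assumed already baseline-referenced (see below) |
| `min_breath_s` | 1.0 | s | minimum extremum spacing; admits rates up to 60/min |
| `min_prominence_frac` | 0.15 | of dynamic range | rejects cardiac ripple and noise bumps |
| smoothing window | 0.25 | s | moving average before peak picking; preserves respiratory extrema, attenuates cardiac frequencies |

Percentages divide by the end-expiratory lung size at the *highest*
PEEP step, recomputed per trial; this makes the reported fractions far
less sensitive to the lung-definition threshold than raw pixel counts.

## Baseline re-referencing

`rebase` subtracts the frame with the minimal global pixel sum
(earliest frame on ties) from every frame. `analyze_trial` defaults to
`rebase_mode="none"` because device output is already relative
impedance against a trial-wide baseline. A `"global"` mode redoes that
referencing against the minimum-sum frame of the whole trial, which is
what removes a common offset when raw sequences are supplied.
`"per_step"` re-references each step to its own minimum-sum frame; note
that this subtracts the step's own end-expiratory level and therefore
destroys exactly the information the end-expiratory threshold needs —
it is provided for inspecting tidal-only signals, never for the full
classification.

## Breath detection

The global waveform is smoothed (0.25 s moving average), peaks and
troughs are picked with a prominence of 15 % of the smoothed dynamic
range and a spacing of at least `min_breath_s`, and every mark is
snapped to the raw-signal extremum within the smoothing window so
averaging uses genuinely recorded frames. A recording that starts or
ends exactly at an extremum contributes a boundary mark only when it
reaches the typical trough depth (or peak height) of the interior
extrema, within 25 % of the mean excursion; a recording that starts
mid-breath therefore contributes no spurious first mark. The breath
count is the number of matched peak/trough pairs; fewer than one pair,
or a constant signal, is a detection error. All criteria are relative,
so detection is invariant under positive affine transforms of the
signal.

## The phantom

The generator emulates, per pixel and PEEP level,
`a(PEEP) + b(PEEP)·w(t) + ε(t)`: an end-expiratory aeration level `a`,
a tidal amplitude `b` modulated by a raised sinusoid `w ∈ [0, 1]` at the
set respiratory rate (30/min), and i.i.d. Gaussian sensor noise
(SD 0.05 = 10 % of the default tidal amplitude), optionally plus a small
cardiac sinusoid. Archetypes set `a` and `b` per pixel: normal
(aerated, ventilated), overdistending (ventilation ceases at an onset
pressure while aeration persists), recruitable (airless below an
opening pressure), cyclically collapsing (ventilated but airless at
end-expiration below its opening pressure) and non-lung. The default
map places two elliptical lungs in a 32×32 supine thorax with a smooth
centre-to-edge amplitude falloff and grades the opening/onset pressures
with gravitational depth (onsets 7–22 cmH2O ventrally, openings
8–28 cmH2O dorsally), so counts evolve monotonically with PEEP as in a
lavage-injured lung; the deepest cyclic row keeps cycling throughout
the studied range, so no category is empty at any analyzed PEEP. Steps
last 20 s (ten breaths) — the analysis consumes only the final five
breaths, so longer recordings add nothing but volume. Ground truth
applies the classifier's own definitions to the noiseless `a`/`b`
maps; transitions are hard switches by default precisely so that this
ground truth is unambiguous (a sigmoid mode exists for stress-testing,
its truth defined by thresholding the same noiseless maps).

What the phantom does *not* emulate: reconstruction blur and electrode
artefacts, cardiac-synchronous perfusion signals confined to a heart
region, breath-to-breath variability, drift, or body-position change.
Passing recovery tests therefore demonstrates the correctness and noise
robustness of the classification logic, not performance on recorded
animals or patients.

## Numerical choices

* Thresholds use strict inequality (">"), so boundary-valued pixels are
  reproducibly excluded.
* The image maximum is taken over the whole image, artefacts included;
  no artefact masking is attempted.
* The minimum-sum baseline frame tie-breaks to the earliest index,
  making `rebase` idempotent.
* Negative tidal pixels (paradoxical motion) are excluded naturally by
  the positive threshold and reported per step as a QC count.
* An image with no positive pixel raises a dedicated error pointing at
  baseline re-referencing; inside a trial such a step is flagged failed
  and the trial continues, unless it is the reference or highest-PEEP
  step, which the trial cannot do without.
* Dice overlap of two empty masks is defined as 1.0.
* Rendering precedence for overlapping categories is overinflated >
  cyclic > recruited (overinflation is the safety-critical finding);
  the yellow outline traces the union of the end-expiratory and tidal
  lung regions and is painted only over unclassified pixels, so
  category pixels remain auditable. Both are display decisions; counts
  are unaffected.
* No established test yields a single group-level p-value for a set of
  per-subject correlation coefficients; the package reports per-subject
  exact-t p-values and the group mean ± SD, with an optional, clearly
  labelled one-sample t-test on Fisher-z-transformed r.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full pipeline on
11-step, 20 s, 32×32 phantom trials (8 800 frames per trial), 1000
random 8×8 images for the enumeration equivalence check, 1000
Monte-Carlo replicates for the correlation expectation, and a 60 s
sinusoid for breath detection — a few seconds end to end on one CPU.

## Known limitations

* The classification inherits the threshold sensitivity of any
  relative-maximum definition: a single hot artefact pixel rescales
  both lung masks. Raising the end-expiratory threshold can only
  shrink the overinflated and recruited regions (asserted as a
  property), but absolute counts do depend on the chosen fractions.
* Recruitment is only defined relative to the chosen reference step;
  with a high or post-recruitment-manoeuvre reference, fewer pixels
  are called recruited.
* The breath detector is a documented stand-in for whatever selection
  the acquisition device performs; it assumes quasi-periodic breathing
  and makes no attempt at apnoea or artefact classification.
* No optimal-PEEP recommendation is derived or intended; the output is
  regional information to be weighed with oxygenation and mechanics.
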