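"""Status images and pixel classification into functional lung regions.

The classification works on three averaged images per PEEP step:

* ``end_insp`` — mean of the selected end-inspiratory frames,
* ``end_exp``  — mean of the selected end-expiratory frames,
* ``tidal``    — their pixel-wise difference (the tidal-variation image).

Lung regions are defined by thresholds relative to each image's own maximum:
pixels *strictly above* 25 % of the end-expiratory maximum form the
end-expiratory lung region (aerated lung), and pixels strictly above 20 % of
the tidal maximum form the tidal lung region (ventilated lung).  The
end-expiratory threshold is 5 % higher because end-expiratory images carry
more noise than tidal (difference) images.

From these two masks the functional categories follow by set algebra:

* **overinflated** — aerated at end-expiration but not ventilated tidally
  (``lung_ee \\ lung_tidal``);
* **cyclic** (tidally recruited/derecruited) — ventilated tidally but not
  aerated at end-expiration (``lung_tidal \\ lung_ee``): alveoli that
  collapse and reopen within each breath;
* **recruited** — aerated at end-expiration at the current PEEP but not at a
  reference PEEP (``lung_ee \\ lung_ee_ref``).

Thresholds are relative, so every mask is invariant under positive scaling
of the impedance values.  A pixel may simultaneously be recruited and
overinflated: the definitions are independent and counts are reported per
category without de-duplication (rendering precedence is a display concern
only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breath import BreathMarks
from .errors import NoPositiveSignalError, ValidationError
from .io import FrameSequence

#: Default threshold fractions.  End-expiration: 25 % of image maximum;
#: tidal: 20 % of image maximum.
DEFAULT_EE_FRAC = 0.25
DEFAULT_TIDAL_FRAC = 0.20


@dataclass(frozen=True)
class Thresholds:
    """Relative threshold fractions for lung-region identification."""

    ee_frac: float = DEFAULT_EE_FRAC
    tidal_frac: float = DEFAULT_TIDAL_FRAC

    def __post_init__(self) -> None:
        for name, value in (("ee_frac", self.ee_frac), ("tidal_frac", self.tidal_frac)):
            if not 0 < value < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {value}")


@dataclass(frozen=True)
class StatusImages:
    """Averaged end-inspiratory, end-expiratory and tidal images of one step."""

    end_insp: np.ndarray
    end_exp: np.ndarray
    tidal: np.ndarray

    def __post_init__(self) -> None:
        if not (self.end_insp.shape == self.end_exp.shape == self.tidal.shape):
            raise ValidationError("status images must share one shape")


@dataclass(frozen=True)
class ZoneMasks:
    """Boolean pixel masks of one classified PEEP step.

    ``recruited`` is ``None`` until a reference step is supplied.
    """

    lung_ee: np.ndarray
    lung_tidal: np.ndarray
    overinflated: np.ndarray
    cyclic: np.ndarray
    recruited: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.lung_ee, self.lung_tidal,
                                    self.overinflated, self.cyclic)}
        if self.recruited is not None:
            shapes.add(self.recruited.shape)
        if len(shapes) != 1:
            raise ValidationError("zone masks must share one shape")
        if np.any(self.overinflated & self.cyclic):
            raise ValidationError("overinflated and cyclic masks must be disjoint")


def status_images(seq: FrameSequence, marks: BreathMarks) -> StatusImages:
    """Average the marked end-inspiratory and end-expiratory frames.

    No thresholding is applied here; the tidal image is simply the
    end-inspiration minus end-expiration average, and may contain negative
    (paradoxical) pixels.
    """
    for idx in (marks.end_insp_idx, marks.end_exp_idx):
        if idx.size == 0:
            raise ValidationError("breath marks are empty")
        if idx.max() >= seq.n_frames or idx.min() < 0:
            raise ValidationError("breath mark index out of range")
    end_insp = seq.frames[marks.end_insp_idx].mean(axis=0)
    end_exp = seq.frames[marks.end_exp_idx].mean(axis=0)
    return StatusImages(end_insp=end_insp, end_exp=end_exp, tidal=end_insp - end_exp)


def lung_mask(image: np.ndarray, frac: float) -> np.ndarray:
    """Pixels strictly above ``frac`` times the image maximum.

    The maximum is taken over the entire image.  Raises
    :class:`NoPositiveSignalError` when the image has no positive pixel,
    since a non-positive threshold would make the mask meaningless —
    usually a symptom of missing baseline re-referencing.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite values")
    if not 0 < frac < 1:
        raise ValidationError(f"threshold fraction must lie in (0, 1), got {frac}")
    peak = image.max()
    if peak <= 0:
        raise NoPositiveSignalError(
            "no positive signal; check baseline re-referencing"
        )
    return image > frac * peak


def classify_step(status: StatusImages, thresholds: Thresholds | None = None) -> ZoneMasks:
    """Classify one step's pixels into lung, overinflated and cyclic regions."""
    th = thresholds or Thresholds()
    lung_ee = lung_mask(status.end_exp, th.ee_frac)
    lung_tidal = lung_mask(status.tidal, th.tidal_frac)
    return ZoneMasks(
        lung_ee=lung_ee,
        lung_tidal=lung_tidal,
        overinflated=lung_ee & ~lung_tidal,
        cyclic=lung_tidal & ~lung_ee,
    )


def recruited_mask(current_lung_ee: np.ndarray, reference_lung_ee: np.ndarray) -> np.ndarray:
    """Pixels aerated at the current PEEP but not at the reference PEEP."""
    if current_lung_ee.shape != reference_lung_ee.shape:
        raise ValidationError(
            f"mask shapes differ: {current_lung_ee.shape} vs {reference_lung_ee.shape}"
        )
    return current_lung_ee & ~reference_lung_ee


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks; 1.0 when both are empty."""
    if a.shape != b.shape:
        raise ValidationError("mask shapes differ")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total
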