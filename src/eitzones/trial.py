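"""Orchestration of a full incremental-PEEP trial.

For every PEEP step: optional baseline re-referencing, breath detection on
the global waveform, selection of the final breaths (default five), status
images, and pixel classification.  Recruitment is computed against the
reference step (default 6 cmH2O — low enough to precede recruitment, high
enough to stay clear of baseline noise), and all percentages share a single
denominator: the size of the end-expiratory lung region at the *highest*
PEEP step.  Steps at or below the reference are processed for quality
control but withheld from the primary result table.

Input frames are expected to be relative impedance already referenced to a
trial-wide baseline (what an EIT device emits).  ``rebase_mode`` offers
``"global"`` to redo that re-referencing against the minimum-sum frame of
the whole trial, or ``"per_step"`` to re-reference each step to its own
minimum-sum frame — note that per-step re-referencing subtracts the step's
own end-expiratory level and therefore destroys the end-expiratory
information this method relies on; it exists for inspecting tidal-only
signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eit_io
from .breath import detect_breaths, global_signal, select_last_n
from .errors import ConfigError, NoPositiveSignalError, ValidationError
from .io import FrameSequence
from .zones import StatusImages, Thresholds, ZoneMasks, classify_step, recruited_mask, status_images

SCHEMA_VERSION = 1

#: Mask names serialised per step.
_MASK_NAMES = ("lung_ee", "lung_tidal", "overinflated", "cyclic", "recruited")
#: Categories whose counts are expressed as percentages of total lung pixels.
CATEGORIES = ("overinflated", "cyclic", "recruited")

REBASE_MODES = ("none", "per_step", "global")


@dataclass(frozen=True)
class TrialConfig:
    """Parameters of a PEEP-trial analysis."""

    reference_peep_cmH2O: float = 6.0
    thresholds: Thresholds = field(default_factory=Thresholds)
    breaths: int = 5
    rebase_mode: str = "none"
    min_breath_s: float = 1.0
    min_prominence_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.rebase_mode not in REBASE_MODES:
            raise ConfigError(f"rebase_mode must be one of {REBASE_MODES}")
        if self.breaths < 1:
            raise ConfigError("breaths must be at least 1")


@dataclass(frozen=True)
class StepResult:
    """Classification outcome of one analyzed PEEP step."""

    peep_cmH2O: float
    masks: ZoneMasks | None
    counts: dict[str, int]
    percentages: dict[str, float]
    qc: dict
    failed: bool = False


@dataclass(frozen=True)
class TrialResult:
    """Per-step masks, counts and percentages of one incremental PEEP trial."""

    subject_id: str
    reference_peep_cmH2O: float
    total_lung_pixels: int
    steps: tuple[StepResult, ...]
    reference_lung_ee: np.ndarray
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.total_lung_pixels <= 0:
            raise ValidationError("total_lung_pixels must be positive")

    def step(self, peep: float) -> StepResult:
        for s in self.steps:
            if s.peep_cmH2O == peep:
                return s
        raise KeyError(f"no analyzed step at PEEP {peep}")


def analyze_trial(
    sequences: list[FrameSequence], config: TrialConfig | None = None
) -> TrialResult:
    """Run the full per-step classification over an ordered PEEP trial.

    ``sequences`` must contain a step at the reference PEEP and at least one
    other step; PEEP labels must be unique.  A step whose end-expiratory
    image has no positive signal is flagged failed and the trial continues,
    except for the reference and highest-PEEP steps, whose masks are needed
    for recruitment and for the percentage denominator respectively.
    """
    cfg = config or TrialConfig()
    if len(sequences) < 2:
        raise ConfigError("a trial needs at least two PEEP steps")
    peeps = [s.peep_cmH2O for s in sequences]
    if len(set(peeps)) != len(peeps):
        raise ConfigError(f"PEEP labels must be unique, got {peeps}")
    if cfg.reference_peep_cmH2O not in peeps:
        raise ConfigError(
            f"reference PEEP {cfg.reference_peep_cmH2O} cmH2O not among steps {sorted(peeps)}"
        )
    subjects = {s.subject_id for s in sequences}
    if len(subjects) != 1:
        raise ConfigError(f"sequences mix subjects: {sorted(subjects)}")

    ordered = sorted(sequences, key=lambda s: s.peep_cmH2O)
    if cfg.rebase_mode == "per_step":
        ordered = [eit_io.rebase(s) for s in ordered]
    elif cfg.rebase_mode == "global":
        ordered = _rebase_global(ordered)

    per_step: dict[float, tuple[ZoneMasks | None, dict, str | None]] = {}
    for seq in ordered:
        per_step[seq.peep_cmH2O] = _classify_one(seq, cfg)

    ref_masks, _, ref_err = per_step[cfg.reference_peep_cmH2O]
    if ref_masks is None:
        raise ConfigError(
            f"reference step ({cfg.reference_peep_cmH2O} cmH2O) failed: {ref_err}"
        )
    highest = ordered[-1].peep_cmH2O
    top_masks, _, top_err = per_step[highest]
    if top_masks is None:
        raise ConfigError(f"highest PEEP step ({highest} cmH2O) failed: {top_err}")
    total_lung_pixels = int(top_masks.lung_ee.sum())

    steps: list[StepResult] = []
    for seq in ordered:
        if seq.peep_cmH2O <= cfg.reference_peep_cmH2O:
            continue
        masks, qc, err = per_step[seq.peep_cmH2O]
        if masks is None:
            steps.append(
                StepResult(seq.peep_cmH2O, None, {}, {}, {**qc, "error": err}, failed=True)
            )
            continue
        masks = replace(masks, recruited=recruited_mask(masks.lung_ee, ref_masks.lung_ee))
        counts = {
            "lung_ee": int(masks.lung_ee.sum()),
            "lung_tidal": int(masks.lung_tidal.sum()),
            "overinflated": int(masks.overinflated.sum()),
            "cyclic": int(masks.cyclic.sum()),
            "recruited": int(masks.recruited.sum()),
        }
        pct = {c: 100.0 * counts[c] / total_lung_pixels for c in CATEGORIES}
        steps.append(StepResult(seq.peep_cmH2O, masks, counts, pct, qc))

    return TrialResult(
        subject_id=ordered[0].subject_id,
        reference_peep_cmH2O=cfg.reference_peep_cmH2O,
        total_lung_pixels=total_lung_pixels,
        steps=tuple(steps),
        reference_lung_ee=ref_masks.lung_ee,
        height=ordered[0].height,
        width=ordered[0].width,
    )


def _rebase_global(sequences: list[FrameSequence]) -> list[FrameSequence]:
    """Subtract the minimum-global-sum frame of the whole trial from every frame."""
    best_val, best_frame = np.inf, None
    for seq in sequences:
        sums = seq.frames.reshape(seq.n_frames, -1).sum(axis=1)
        i = int(np.argmin(sums))
        if sums[i] < best_val:
            best_val, best_frame = sums[i], seq.frames[i]
    return [replace(s, frames=s.frames - best_frame) for s in sequences]


def _classify_one(seq: FrameSequence, cfg: TrialConfig):
    """Classify one step; returns (masks-or-None, qc dict, error-or-None)."""
    marks = detect_breaths(
        global_signal(seq),
        seq.sample_rate_hz,
        min_breath_s=cfg.min_breath_s,
        min_prominence_frac=cfg.min_prominence_frac,
    )
    marks = select_last_n(marks, cfg.breaths)
    status = status_images(seq, marks)
    qc = {
        "n_breaths_used": int(min(marks.end_insp_idx.size, marks.end_exp_idx.size)),
        "shortfall": bool(marks.shortfall),
        "negative_tidal_pixels": int((status.tidal < 0).sum()),
    }
    try:
        masks = classify_step(status, cfg.thresholds)
    except NoPositiveSignalError as exc:
        return None, qc, str(exc)
    if not masks.lung_ee.any():
        return None, qc, "empty end-expiratory lung region"
    return masks, qc, None


def percentages(result: TrialResult) -> pd.DataFrame:
    """Per-step table of category percentages (of total lung pixels)."""
    rows = []
    for s in result.steps:
        row = {"peep_cmH2O": s.peep_cmH2O}
        for c in CATEGORIES:
            row[f"{c}_pct"] = s.percentages.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=["peep_cmH2O"] + [f"{c}_pct" for c in CATEGORIES])


# ---------------------------------------------------------------------------
# serialisation

def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (row-major; first run counts zeros)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    runs: list[int] = []
    value = False
    i = 0
    while i < flat.size:
        j = i
        while j < flat.size and flat[j] == value:
            j += 1
        runs.append(j - i)
        value = not value
        i = j
    return {"shape": list(mask.shape), "runs": runs}


def rle_decode(encoded: dict) -> np.ndarray:
    """Invert :func:`rle_encode`."""
    shape = tuple(encoded["shape"])
    out = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for run in encoded["runs"]:
        if value:
            out[pos:pos + run] = True
        pos += run
        value = not value
    if pos != out.size:
        raise ValidationError(f"run lengths sum to {pos}, expected {out.size}")
    return out.reshape(shape)


def _step_to_json(s: StepResult) -> dict:
    doc = {
        "peep_cmH2O": s.peep_cmH2O,
        "failed": s.failed,
        "counts": s.counts,
        "percentages": s.percentages,
        "qc": s.qc,
        "masks": None,
    }
    if s.masks is not None:
        doc["masks"] = {
            name: rle_encode(getattr(s.masks, name))
            for name in _MASK_NAMES
            if getattr(s.masks, name) is not None
        }
    return doc


def _step_from_json(doc: dict) -> StepResult:
    masks = None
    if doc["masks"] is not None:
        decoded = {name: rle_decode(enc) for name, enc in doc["masks"].items()}
        masks = ZoneMasks(**{name: decoded.get(name) for name in _MASK_NAMES})
    return StepResult(
        peep_cmH2O=float(doc["peep_cmH2O"]),
        masks=masks,
        counts={k: int(v) for k, v in doc["counts"].items()},
        percentages={k: float(v) for k, v in doc["percentages"].items()},
        qc=doc["qc"],
        failed=bool(doc["failed"]),
    )


def export_results(result: TrialResult, out_dir: str | Path) -> dict[str, Path]:
    """Write ``summary.csv``, ``trial.json`` and per-step ``masks_<peep>.json``.

    The JSON document is versioned (``schema_version``) and stores boolean
    masks run-length encoded; :func:`load_results` inverts it exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for s in result.steps:
        row = {"peep_cmH2O": s.peep_cmH2O, "failed": s.failed}
        for c in ("lung_ee", "lung_tidal", *CATEGORIES):
            row[f"{c}_count"] = s.counts.get(c, np.nan)
        for c in CATEGORIES:
            row[f"{c}_pct"] = s.percentages.get(c, np.nan)
        row.update({f"qc_{k}": v for k, v in s.qc.items()})
        rows.append(row)
    columns = (
        ["peep_cmH2O", "failed"]
        + [f"{c}_count" for c in ("lung_ee", "lung_tidal", *CATEGORIES)]
        + [f"{c}_pct" for c in CATEGORIES]
        + ["qc_n_breaths_used", "qc_shortfall", "qc_negative_tidal_pixels"]
    )
    summary = pd.DataFrame(rows, columns=columns)
    summary_path = out_dir / "summary.csv"
    summary.to_csv(summary_path, index=False)

    doc = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": result.subject_id,
        "reference_peep_cmH2O": result.reference_peep_cmH2O,
        "total_lung_pixels": result.total_lung_pixels,
        "height": result.height,
        "width": result.width,
        "reference_lung_ee": rle_encode(result.reference_lung_ee),
        "steps": [_step_to_json(s) for s in result.steps],
    }
    trial_path = out_dir / "trial.json"
    with open(trial_path, "w") as fh:
        json.dump(doc, fh)

    paths = {"summary": summary_path, "trial": trial_path}
    for s in result.steps:
        p = out_dir / f"masks_{s.peep_cmH2O:g}.json"
        with open(p, "w") as fh:
            json.dump(_step_to_json(s), fh)
        paths[f"masks_{s.peep_cmH2O:g}"] = p
    return paths


def load_results(trial_json: str | Path) -> TrialResult:
    """Load a :class:`TrialResult` written by :func:`export_results`."""
    with open(trial_json) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported trial schema version {doc.get('schema_version')}"
        )
    return TrialResult(
        subject_id=doc["subject_id"],
        reference_peep_cmH2O=float(doc["reference_peep_cmH2O"]),
        total_lung_pixels=int(doc["total_lung_pixels"]),
        steps=tuple(_step_from_json(s) for s in doc["steps"]),
        reference_lung_ee=rle_decode(doc["reference_lung_ee"]),
        height=int(doc["height"]),
        width=int(doc["width"]),
    )
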