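"""Reading, writing and baseline re-referencing of EIT frame sequences.

A frame sequence is one PEEP step's worth of reconstructed relative-impedance
images (default 32×32 pixels at 40 frames/s).  On disk a sequence is a plain
comma-delimited matrix — one row per frame, ``height*width`` columns in
row-major order, row 0 of each image being the ventral (anterior) edge in the
supine display convention — accompanied by a JSON metadata sidecar.  An
optional per-step physiology table (PaO2/FiO2, PAWP, MAP, CVP, HR, Pplat, VT,
Crs) is a CSV with one row per PEEP step.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, ValidationError

PIXEL_ORDER = "row-major-ventral-first"

_SIDECAR_KEYS = ("subject_id", "peep_cmH2O", "sample_rate_hz", "height", "width")

#: Recognised columns of the ancillary physiology table.  ``peep_cmH2O`` is
#: mandatory; everything else is optional.
ANCILLARY_COLUMNS = (
    "subject_id",
    "peep_cmH2O",
    "pao2_fio2",
    "pawp_mmHg",
    "map_mmHg",
    "cvp_mmHg",
    "hr_bpm",
    "pplat_cmH2O",
    "vt_ml_per_kg",
    "crs_ml_per_cmH2O",
)


@dataclass(frozen=True)
class FrameSequence:
    """Time-ordered stack of relative-impedance images for one PEEP step.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``; relative impedance in arbitrary units,
        values may be negative.
    sample_rate_hz
        Frames per second (> 0).
    subject_id
        Free-text subject label.
    peep_cmH2O
        Non-negative PEEP label of this step.
    """

    frames: np.ndarray
    sample_rate_hz: float
    subject_id: str
    peep_cmH2O: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValidationError(f"frames must be T×H×W, got ndim={frames.ndim}")
        if frames.shape[0] < 1:
            raise ValidationError("a frame sequence needs at least one frame")
        if not np.all(np.isfinite(frames)):
            raise ValidationError("frames contain non-finite values")
        if not self.sample_rate_hz > 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.peep_cmH2O < 0:
            raise ValidationError("peep_cmH2O must be non-negative")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate_hz


def read_frames(path: str | Path, sidecar: str | Path) -> FrameSequence:
    """Read a delimited-text frame matrix plus its JSON metadata sidecar.

    Raises
    ------
    ConfigError
        If a required sidecar key is missing.
    FormatError
        If a row has the wrong number of cells or a cell is not numeric; the
        message names the offending (1-based) row.
    """
    path, sidecar = Path(path), Path(sidecar)
    with open(sidecar) as fh:
        meta = json.load(fh)
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise ConfigError(f"sidecar {sidecar} is missing metadata keys: {missing}")
    height, width = int(meta["height"]), int(meta["width"])
    n_pixels = height * width

    try:
        frames = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        _diagnose_matrix(path, n_pixels)  # raises FormatError with row context
        raise
    if frames.shape[1] != n_pixels:
        raise FormatError(
            f"{path}: row 1 has {frames.shape[1]} cells, expected "
            f"{n_pixels} (= {height}×{width})"
        )
    if not np.all(np.isfinite(frames)):
        bad = int(np.argwhere(~np.isfinite(frames).all(axis=1))[0, 0]) + 1
        raise FormatError(f"{path}: non-finite value in row {bad}")

    return FrameSequence(
        frames=frames.reshape(-1, height, width),
        sample_rate_hz=float(meta["sample_rate_hz"]),
        subject_id=str(meta["subject_id"]),
        peep_cmH2O=float(meta["peep_cmH2O"]),
    )


def _diagnose_matrix(path: Path, n_pixels: int) -> None:
    """Locate the first malformed row of a frame matrix and raise FormatError."""
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if len(row) != n_pixels:
                raise FormatError(
                    f"{path}: row {i} has {len(row)} cells, expected {n_pixels}"
                )
            for j, cell in enumerate(row, start=1):
                try:
                    float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell at row {i}, column {j}: {cell!r}"
                    ) from None


def write_frames(seq: FrameSequence, path: str | Path, sidecar: str | Path) -> None:
    """Write a sequence so that :func:`read_frames` inverts it exactly.

    The matrix is written with 17 significant digits, which round-trips IEEE
    double precision.
    """
    flat = seq.frames.reshape(seq.n_frames, -1)
    np.savetxt(path, flat, fmt="%.17g", delimiter=",")
    meta = {
        "subject_id": seq.subject_id,
        "peep_cmH2O": seq.peep_cmH2O,
        "sample_rate_hz": seq.sample_rate_hz,
        "height": seq.height,
        "width": seq.width,
        "pixel_order": PIXEL_ORDER,
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def rebase(seq: FrameSequence) -> FrameSequence:
    """Re-reference a sequence against its minimum-global-sum frame.

    The frame whose pixel sum is smallest (earliest frame on a tie) is
    subtracted pixel-wise from every frame, so the global signal of the result
    attains exactly 0 at the baseline index.  Idempotent.
    """
    sums = seq.frames.reshape(seq.n_frames, -1).sum(axis=1)
    baseline = int(np.argmin(sums))  # argmin returns the first minimum
    return replace(seq, frames=seq.frames - seq.frames[baseline])


def read_ancillary(path: str | Path) -> pd.DataFrame:
    """Read a per-PEEP-step physiology table.

    Validates that ``peep_cmH2O`` is present and unique (per subject when a
    ``subject_id`` column exists), that pressures are finite and that
    PaO2/FiO2 is positive where present.
    """
    df = pd.read_csv(path)
    if "peep_cmH2O" not in df.columns:
        raise FormatError(f"{path}: ancillary table lacks a peep_cmH2O column")
    unknown = [c for c in df.columns if c not in ANCILLARY_COLUMNS]
    if unknown:
        raise FormatError(f"{path}: unrecognised ancillary columns {unknown}")
    group = df.groupby("subject_id") if "subject_id" in df.columns else [(None, df)]
    for sid, sub in group:
        if sub["peep_cmH2O"].duplicated().any():
            raise ValidationError(
                f"{path}: duplicate PEEP levels" + (f" for subject {sid}" if sid else "")
            )
    pressure_cols = [
        c for c in ("peep_cmH2O", "pawp_mmHg", "map_mmHg", "cvp_mmHg", "pplat_cmH2O")
        if c in df.columns
    ]
    if not np.all(np.isfinite(df[pressure_cols].to_numpy(dtype=float))):
        raise ValidationError(f"{path}: non-finite pressure value")
    if "pao2_fio2" in df.columns:
        vals = df["pao2_fio2"].dropna()
        if (vals <= 0).any():
            raise ValidationError(f"{path}: PaO2/FiO2 must be positive")
    return df
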