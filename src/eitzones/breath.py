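"""Global impedance waveform and breath (end-inspiration/end-expiration) detection.

The global signal — the per-frame sum over all pixels — oscillates with tidal
ventilation.  ``detect_breaths`` smooths it with a short moving average,
locates alternating maxima (end-inspiration) and minima (end-expiration) whose
peak-to-trough excursion is a configurable fraction of the signal's dynamic
range, and maps every mark back to the nearest raw-signal extremum so that
downstream averaging uses genuinely recorded frames.  Detection is invariant
under positive affine transforms of the signal because all thresholds are
relative.

Boundary extrema (a recording that starts or ends exactly at end-expiration)
are kept only when they reach the typical trough depth / peak height of the
interior extrema; a recording that starts mid-breath therefore does not
contribute a spurious first mark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import DetectionError, ValidationError
from .io import FrameSequence

#: Moving-average smoothing window, seconds.  Short enough to preserve
#: respiratory extrema at rates up to 60/min, long enough to suppress cardiac
#: oscillations (~1.5–2 Hz) from dominating peak picking.
SMOOTH_WINDOW_S = 0.25

#: Fraction of typical peak-to-trough amplitude within which a boundary
#: extremum must lie to be accepted as a genuine mark.
_BOUNDARY_TOL = 0.25


@dataclass(frozen=True)
class BreathMarks:
    """Frame indices of end-inspiratory peaks and end-expiratory troughs.

    Indices are strictly increasing within each list and the merged sequence
    alternates peak/trough.  ``shortfall`` is set by :func:`select_last_n`
    when fewer breaths were available than requested.
    """

    end_insp_idx: np.ndarray
    end_exp_idx: np.ndarray
    shortfall: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        insp = np.asarray(self.end_insp_idx, dtype=int)
        exp = np.asarray(self.end_exp_idx, dtype=int)
        for name, idx in (("end_insp_idx", insp), ("end_exp_idx", exp)):
            if idx.ndim != 1:
                raise ValidationError(f"{name} must be one-dimensional")
            if idx.size > 1 and not np.all(np.diff(idx) > 0):
                raise ValidationError(f"{name} must be strictly increasing")
        merged = sorted(
            [(int(i), "I") for i in insp] + [(int(e), "E") for e in exp]
        )
        for (i0, k0), (i1, k1) in zip(merged, merged[1:]):
            if i0 == i1:
                raise ValidationError("a frame cannot be both peak and trough")
            if k0 == k1:
                raise ValidationError(
                    "marks must alternate between end-inspiration and end-expiration"
                )
        object.__setattr__(self, "end_insp_idx", insp)
        object.__setattr__(self, "end_exp_idx", exp)

    @property
    def n_breaths(self) -> int:
        """Number of detected breaths: matched end-inspiration/end-expiration pairs."""
        return int(min(self.end_insp_idx.size, self.end_exp_idx.size))


def global_signal(seq: FrameSequence) -> np.ndarray:
    """Per-frame sum over all pixels (length-T relative impedance waveform)."""
    return seq.frames.reshape(seq.n_frames, -1).sum(axis=1)


def detect_breaths(
    signal: np.ndarray,
    sample_rate_hz: float,
    min_breath_s: float = 1.0,
    min_prominence_frac: float = 0.15,
) -> BreathMarks:
    """Locate end-inspiratory and end-expiratory frames in a global waveform.

    Parameters
    ----------
    signal
        Raw (unsmoothed) global impedance waveform.
    sample_rate_hz
        Sampling rate of ``signal`` in frames per second.
    min_breath_s
        Minimum spacing between same-type extrema, seconds.  The default of
        1.0 s admits respiratory rates up to 60/min.
    min_prominence_frac
        Required peak prominence as a fraction of the smoothed signal's
        dynamic range, in (0, 1).

    Returns
    -------
    BreathMarks
        Marks referring to indices of the *unsmoothed* signal (the raw
        extremum nearest each smoothed extremum).

    Raises
    ------
    DetectionError
        For a constant signal (zero dynamic range) or when fewer than one
        complete breath is found.
    """
    signal = np.asarray(signal, dtype=float)
    if not 0 < min_prominence_frac < 1:
        raise ValidationError("min_prominence_frac must lie in (0, 1)")
    if signal.size < 2 * min_breath_s * sample_rate_hz:
        raise DetectionError(
            f"signal of {signal.size} samples is too short for breaths of "
            f"{min_breath_s} s at {sample_rate_hz} Hz"
        )

    window = max(1, int(round(SMOOTH_WINDOW_S * sample_rate_hz)))
    smooth = uniform_filter1d(signal, size=window, mode="nearest")
    dynamic_range = float(smooth.max() - smooth.min())
    if dynamic_range <= 0:
        raise DetectionError("constant signal: zero dynamic range, no breaths exist")

    prominence = min_prominence_frac * dynamic_range
    distance = max(1, int(round(min_breath_s * sample_rate_hz)))
    peaks, _ = find_peaks(smooth, prominence=prominence, distance=distance)
    troughs, _ = find_peaks(-smooth, prominence=prominence, distance=distance)

    events = sorted([(int(p), "I") for p in peaks] + [(int(t), "E") for t in troughs])
    if not events:
        raise DetectionError(
            "no respiratory extrema found; review min_breath_s/min_prominence_frac"
        )
    events = _add_boundary_extrema(smooth, events, prominence)
    events = _collapse_runs(smooth, events)
    events = _to_raw_extrema(signal, events, half=max(1, window // 2))
    events = _collapse_runs(signal, events)

    insp = np.array([i for i, kind in events if kind == "I"], dtype=int)
    exp = np.array([i for i, kind in events if kind == "E"], dtype=int)
    marks = BreathMarks(insp, exp)
    if marks.n_breaths < 1:
        raise DetectionError(
            "fewer than one complete breath found; review detection parameters"
        )
    return marks


def _add_boundary_extrema(smooth, events, prominence):
    """Append a leading/trailing extremum when the signal starts or ends there.

    A boundary candidate (the argmin/argmax before the first or after the
    last detected event) is accepted only when it reaches the typical level
    of the interior extrema of its kind, so half-breath edges are ignored.
    """
    peak_vals = [smooth[i] for i, k in events if k == "I"]
    trough_vals = [smooth[i] for i, k in events if k == "E"]

    def accept(value, kind):
        if peak_vals and trough_vals:
            level_p, level_t = np.median(peak_vals), np.median(trough_vals)
            tol = _BOUNDARY_TOL * (level_p - level_t)
            return value >= level_p - tol if kind == "I" else value <= level_t + tol
        # one-sided signals: fall back to the absolute prominence requirement
        ref = trough_vals[0] if kind == "I" else peak_vals[0]
        excursion = value - ref if kind == "I" else ref - value
        return excursion >= prominence

    out = list(events)
    first_i, first_k = events[0]
    if first_i > 0:
        kind = "E" if first_k == "I" else "I"
        seg = smooth[:first_i]
        cand = int(np.argmin(seg) if kind == "E" else np.argmax(seg))
        if cand != first_i and accept(smooth[cand], kind):
            out.insert(0, (cand, kind))
    last_i, last_k = events[-1]
    if last_i < smooth.size - 1:
        kind = "E" if last_k == "I" else "I"
        seg = smooth[last_i + 1:]
        off = int(np.argmin(seg) if kind == "E" else np.argmax(seg))
        cand = last_i + 1 + off
        if accept(smooth[cand], kind):
            out.append((cand, kind))
    return out


def _collapse_runs(values, events):
    """Enforce alternation: of consecutive same-type events keep the most extreme."""
    out: list[tuple[int, str]] = []
    for idx, kind in sorted(events):
        if out and out[-1][1] == kind:
            prev_idx = out[-1][0]
            better = (
                values[idx] > values[prev_idx]
                if kind == "I"
                else values[idx] < values[prev_idx]
            )
            if better:
                out[-1] = (idx, kind)
        elif out and out[-1][0] == idx:
            continue  # identical index with opposite type: keep the first
        else:
            out.append((idx, kind))
    return out


def _to_raw_extrema(signal, events, half):
    """Snap each smoothed-extremum index to the raw extremum within the window."""
    out = []
    for idx, kind in events:
        lo, hi = max(0, idx - half), min(signal.size, idx + half + 1)
        seg = signal[lo:hi]
        off = int(np.argmax(seg) if kind == "I" else np.argmin(seg))
        out.append((lo + off, kind))
    return sorted(set(out))


def select_last_n(marks: BreathMarks, n: int) -> BreathMarks:
    """Keep the last ``n`` end-inspiratory and end-expiratory marks.

    Follows the convention of analysing the final breaths of a PEEP step
    (default elsewhere: five).  If fewer than ``n`` marks of either kind
    exist, all available marks are returned with ``shortfall`` set.
    """
    if n < 1:
        raise ValidationError("n must be at least 1")
    if marks.end_insp_idx.size == 0 or marks.end_exp_idx.size == 0:
        raise ValidationError("cannot select from empty breath marks")
    shortfall = marks.end_insp_idx.size < n or marks.end_exp_idx.size < n
    return replace(
        marks,
        end_insp_idx=marks.end_insp_idx[-n:],
        end_exp_idx=marks.end_exp_idx[-n:],
        shortfall=shortfall,
    )
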