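"""Labelled synthetic EIT PEEP-trial generator.

The phantom emulates tidal impedance oscillations superimposed on a
PEEP-dependent end-expiratory aeration level.  Every pixel ``p`` at PEEP
level ``P`` produces::

    signal_p(t) = a_p(P) + b_p(P) * w(t) + noise(t) [+ cardiac(t)]

where ``w(t)`` is a raised sinusoid in [0, 1] at the set respiratory rate
(so troughs are end-expiration and peaks end-inspiration), ``a`` is the
end-expiratory aeration amplitude and ``b`` the tidal amplitude, both in
the same arbitrary relative-impedance units a device emits after baseline
re-referencing.  Noise is i.i.d. Gaussian per pixel and frame.

Each pixel belongs to one archetype:

* ``non_lung``           — a = b = 0 at every PEEP;
* ``normal``             — aerated and ventilated at every PEEP;
* ``overdistending``     — stays aerated but ventilation ceases at and above
  its overdistension-onset pressure (the classifier should call it
  overinflated there);
* ``recruitable``        — airless and unventilated below its opening
  pressure, normal at and above it (recruited relative to a low reference);
* ``cyclic_low_peep``    — ventilated but airless at end-expiration below
  its opening pressure (tidal recruitment/derecruitment), normal above.

Opening/onset pressures may be per-pixel maps; the default phantom grades
them with gravitational depth so counts evolve monotonically with PEEP, the
way a lavage-injured lung behaves.  An elliptical amplitude profile mimics
the smooth centre-to-edge falloff of reconstructed EIT images.

Transitions are hard switches at the stated pressures by default, which
makes the ground truth unambiguous; a sigmoid mode exists for
stress-testing, with ground truth then defined by thresholding the
noiseless ``a``/``b`` maps exactly as for the hard mode.

All randomness flows from a single seed: the per-step generators are spawned
from ``numpy.random.SeedSequence(seed)`` in PEEP order, so any subset of a
trial is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.special import expit

from .errors import ConfigError, ValidationError
from .io import FrameSequence
from .zones import Thresholds

ARCHETYPES = {
    "non_lung": 0,
    "normal": 1,
    "overdistending": 2,
    "recruitable": 3,
    "cyclic_low_peep": 4,
}

_DEFAULT_PEEPS = tuple(float(p) for p in range(0, 31, 3))


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of one synthetic PEEP trial.

    Defaults follow the measurement conditions the classifier targets:
    32×32 pixel images at 40 frames/s, 30 breaths/min, an incremental PEEP
    ladder 0→30 cmH2O in 3 cmH2O steps with the recruitment reference at
    6 cmH2O, aeration amplitude 1 and tidal amplitude 0.5 (arbitrary
    units) and sensor noise of SD 0.05 — i.e. 10 % of the tidal amplitude.
    Steps last 20 s (ten breaths), comfortably more than the five final
    breaths the analysis averages.
    """

    height: int = 32
    width: int = 32
    sample_rate_hz: float = 40.0
    rr_bpm: float = 30.0
    step_duration_s: float = 20.0
    peep_levels: tuple[float, ...] = _DEFAULT_PEEPS
    reference_peep_cmH2O: float = 6.0
    archetype_map: np.ndarray | None = None
    opening_pressure_cmH2O: float | np.ndarray = 12.0
    overdistension_onset_cmH2O: float | np.ndarray = 15.0
    aeration_amplitude: float = 1.0
    tidal_amplitude: float = 0.5
    amplitude_profile: np.ndarray | None = None
    noise_sd: float = 0.05
    cardiac_amplitude: float = 0.0
    cardiac_freq_hz: float = 1.25
    transition: str = "hard"
    transition_width_cmH2O: float = 2.0
    thresholds: Thresholds = field(default_factory=Thresholds)
    subject_id: str = "phantom-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype_map is None:
            amap, opening, onset, profile = default_archetype_map(self.height, self.width)
            object.__setattr__(self, "archetype_map", amap)
            object.__setattr__(self, "opening_pressure_cmH2O", opening)
            object.__setattr__(self, "overdistension_onset_cmH2O", onset)
            if self.amplitude_profile is None:
                object.__setattr__(self, "amplitude_profile", profile)
        amap = np.asarray(self.archetype_map)
        if amap.shape != (self.height, self.width):
            raise ConfigError(
                f"archetype map shape {amap.shape} != grid {(self.height, self.width)}"
            )
        if not np.isin(amap, list(ARCHETYPES.values())).all():
            raise ConfigError(f"archetype codes must be in {sorted(ARCHETYPES.values())}")
        if self.amplitude_profile is None:
            object.__setattr__(self, "amplitude_profile", np.ones((self.height, self.width)))
        peeps = np.asarray(self.peep_levels, dtype=float)
        if peeps.size < 2 or not np.all(np.diff(peeps) > 0):
            raise ConfigError("peep_levels must be strictly increasing with ≥ 2 levels")
        if self.reference_peep_cmH2O not in self.peep_levels:
            raise ConfigError("reference PEEP must be one of peep_levels")
        for name in ("aeration_amplitude", "tidal_amplitude", "noise_sd",
                     "cardiac_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.transition not in ("hard", "sigmoid"):
            raise ConfigError("transition must be 'hard' or 'sigmoid'")


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless labels per PEEP level, following the classifier's definitions.

    ``masks[peep]`` holds boolean arrays ``lung_ee_true``, ``lung_tidal_true``,
    ``overinflated_true``, ``cyclic_true`` and ``recruited_true`` (relative to
    ``reference_peep_cmH2O``); ``aeration[peep]`` and ``tidal[peep]`` are the
    noiseless a/b amplitude maps the labels derive from.
    """

    reference_peep_cmH2O: float
    masks: dict[float, dict[str, np.ndarray]]
    aeration: dict[float, np.ndarray]
    tidal: dict[float, np.ndarray]


def default_archetype_map(height: int = 32, width: int = 32):
    """Build the default mixed (and monotone) archetype layout.

    Two elliptical lungs in a supine 32×32 thorax; from ventral (row 0) to
    dorsal: an overdistending band whose onset pressures grade from 7 to
    22 cmH2O, normally ventilated mid-lung, a cyclic band whose opening
    pressures grade from 9 to 18 cmH2O — its deepest row cycles throughout
    the studied range — and a dependent recruitable band opening between 8
    and 28 cmH2O.  An elliptical amplitude profile (1.0 at the lung centre,
    0.5 at the rim) mimics reconstruction falloff.

    Returns ``(archetype_map, opening_pressure_map, onset_map, profile)``.
    """
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    d2 = np.full((height, width), np.inf)
    for cc in (width * 10 / 32, width * 22 / 32):
        cur = ((rows - height / 2) / (height * 12 / 32)) ** 2 + (
            (cols - cc) / (width * 6.2 / 32)
        ) ** 2
        d2 = np.minimum(d2, cur)
    lung = d2 <= 1.0
    profile = np.where(lung, 0.5 + 0.5 * (1.0 - np.minimum(d2, 1.0)), 0.0)

    amap = np.zeros((height, width), dtype=int)
    opening = np.zeros((height, width), dtype=float)
    onset = np.full((height, width), np.inf)

    r = rows + np.zeros_like(cols)  # broadcast row index per pixel
    band_overdistending = lung & (r <= 9)
    band_normal = lung & (r >= 10) & (r <= 17)
    band_cyclic = lung & (r >= 18) & (r <= 22)
    band_recruitable = lung & (r >= 23)

    amap[band_overdistending] = ARCHETYPES["overdistending"]
    amap[band_normal] = ARCHETYPES["normal"]
    amap[band_cyclic] = ARCHETYPES["cyclic_low_peep"]
    amap[band_recruitable] = ARCHETYPES["recruitable"]

    onset_by_row = 7.0 + 3.0 * (r - 4)  # 7, 10, ... cmH2O down the band
    onset[band_overdistending] = onset_by_row[band_overdistending]

    cyc_open = 9.0 + 3.0 * (r - 18)  # 9, 12, 15, 18 cmH2O
    cyc_open = np.where(r >= 22, 33.0, cyc_open)  # deepest row cycles throughout
    opening[band_cyclic] = cyc_open[band_cyclic]

    rec_open = 8.0 + 4.0 * (r - 23)  # 8, 12, ... 28 cmH2O
    opening[band_recruitable] = rec_open[band_recruitable]

    return amap, opening, onset, profile


def amplitude_maps(config: PhantomConfig, peep: float) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless end-expiratory (a) and tidal (b) amplitude maps at one PEEP."""
    amap = config.archetype_map
    s = config.amplitude_profile
    opening = np.broadcast_to(np.asarray(config.opening_pressure_cmH2O, dtype=float),
                              amap.shape)
    onset = np.broadcast_to(np.asarray(config.overdistension_onset_cmH2O, dtype=float),
                            amap.shape)
    if config.transition == "hard":
        open_frac = (peep >= opening).astype(float)
        vent_frac = (peep < onset).astype(float)
    else:
        w = config.transition_width_cmH2O
        open_frac = expit((peep - opening) / w)
        vent_frac = expit((onset - peep) / w)

    a0, b0 = config.aeration_amplitude, config.tidal_amplitude
    a = np.zeros(amap.shape)
    b = np.zeros(amap.shape)
    m = amap == ARCHETYPES["normal"]
    a[m], b[m] = (a0 * s)[m], (b0 * s)[m]
    m = amap == ARCHETYPES["overdistending"]
    a[m], b[m] = (a0 * s)[m], (b0 * s * vent_frac)[m]
    m = amap == ARCHETYPES["recruitable"]
    a[m], b[m] = (a0 * s * open_frac)[m], (b0 * s * open_frac)[m]
    m = amap == ARCHETYPES["cyclic_low_peep"]
    a[m], b[m] = (a0 * s * open_frac)[m], (b0 * s)[m]
    return a, b


def _truth_mask(image: np.ndarray, frac: float) -> np.ndarray:
    """Relative-threshold mask that is empty (not an error) for an all-zero map."""
    peak = image.max()
    if peak <= 0:
        return np.zeros(image.shape, dtype=bool)
    return image > frac * peak


def ground_truth(config: PhantomConfig) -> GroundTruth:
    """Derive per-level labels from the noiseless amplitude maps."""
    th = config.thresholds
    aeration = {p: amplitude_maps(config, p)[0] for p in config.peep_levels}
    tidal = {p: amplitude_maps(config, p)[1] for p in config.peep_levels}
    ref_lung_ee = _truth_mask(aeration[config.reference_peep_cmH2O], th.ee_frac)
    masks = {}
    for p in config.peep_levels:
        lung_ee = _truth_mask(aeration[p], th.ee_frac)
        lung_tidal = _truth_mask(tidal[p], th.tidal_frac)
        masks[p] = {
            "lung_ee_true": lung_ee,
            "lung_tidal_true": lung_tidal,
            "overinflated_true": lung_ee & ~lung_tidal,
            "cyclic_true": lung_tidal & ~lung_ee,
            "recruited_true": lung_ee & ~ref_lung_ee,
        }
    return GroundTruth(
        reference_peep_cmH2O=config.reference_peep_cmH2O,
        masks=masks,
        aeration=aeration,
        tidal=tidal,
    )


def generate(config: PhantomConfig | None = None) -> tuple[list[FrameSequence], GroundTruth]:
    """Generate one labelled synthetic PEEP trial.

    Returns one :class:`FrameSequence` per PEEP level (in ladder order) plus
    the :class:`GroundTruth` labels of the noiseless generative model.
    """
    cfg = config or PhantomConfig()
    n = int(round(cfg.step_duration_s * cfg.sample_rate_hz))
    t = np.arange(n) / cfg.sample_rate_hz
    wave = 0.5 * (1.0 - np.cos(2.0 * np.pi * (cfg.rr_bpm / 60.0) * t))
    body = (np.asarray(cfg.archetype_map) != ARCHETYPES["non_lung"]).astype(float)

    children = np.random.SeedSequence(cfg.seed).spawn(len(cfg.peep_levels))
    sequences = []
    for peep, child in zip(cfg.peep_levels, children):
        a, b = amplitude_maps(cfg, peep)
        frames = a[None, :, :] + wave[:, None, None] * b[None, :, :]
        if cfg.cardiac_amplitude > 0:
            cardiac = cfg.cardiac_amplitude * 0.5 * (
                1.0 - np.cos(2.0 * np.pi * cfg.cardiac_freq_hz * t)
            )
            frames = frames + cardiac[:, None, None] * body[None, :, :]
        if cfg.noise_sd > 0:
            rng = np.random.default_rng(child)
            frames = frames + rng.normal(0.0, cfg.noise_sd, size=frames.shape)
        sequences.append(
            FrameSequence(
                frames=frames,
                sample_rate_hz=cfg.sample_rate_hz,
                subject_id=cfg.subject_id,
                peep_cmH2O=peep,
            )
        )
    return sequences, ground_truth(cfg)


def corrupt(seq: FrameSequence, noise_sd: float, seed: int) -> FrameSequence:
    """Add seeded Gaussian pixel noise; ``noise_sd == 0`` returns the input unchanged."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if noise_sd == 0:
        return seq
    rng = np.random.default_rng(seed)
    return replace(seq, frames=seq.frames + rng.normal(0.0, noise_sd, size=seq.frames.shape))


def config_overrides(base: PhantomConfig | None = None, **kwargs) -> PhantomConfig:
    """Return a config with fields replaced (arrays passed through as-is)."""
    return replace(base or PhantomConfig(), **kwargs)
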