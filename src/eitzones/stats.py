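"""Correlation of regional pixel counts with ancillary physiology.

Per subject, the pixel count of one category (recruited, overinflated or
cyclic) across the analyzed PEEP steps is correlated with a physiological
variable (e.g. PaO2/FiO2 or PAWP) by Pearson's product-moment coefficient;
the group is summarised as mean ± SD of the per-subject r.  Per-subject
p-values come from the exact t transform of r at n−2 degrees of freedom.

No single established test exists for a group-level p-value on a set of
per-subject correlation coefficients; as one documented interpretation,
``fisher_test=True`` additionally reports a one-sample t-test on the
Fisher-z-transformed per-subject r values against zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, ValidationError
from .trial import TrialResult

#: Minimum number of matched PEEP steps for a per-subject correlation.
MIN_STEPS = 3


@dataclass(frozen=True)
class CorrelationResult:
    """Per-subject Pearson coefficients and their group summary."""

    subjects: tuple[str, ...]
    per_subject_r: tuple[float, ...]
    per_subject_p: tuple[float, ...]
    group_mean_r: float
    group_sd_r: float | None  # None when fewer than two subjects
    group_p: float | None = None  # Fisher-z one-sample t-test, when requested
    warnings: tuple[str, ...] = ()


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided exact-t p-value.

    Requires equal lengths n ≥ 3 and nonzero variance in both series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be one-dimensional and of equal length")
    if x.size < MIN_STEPS:
        raise ValidationError(f"need at least {MIN_STEPS} observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: a series has zero variance")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlate_trials(
    trials: list[TrialResult],
    ancillary,
    category: str = "recruited",
    variable: str = "pao2_fio2",
    use_percentages: bool = False,
    fisher_test: bool = False,
) -> CorrelationResult:
    """Per-subject correlation of a category's pixel count with a physiology variable.

    Parameters
    ----------
    trials
        One analyzed trial per subject.
    ancillary
        Mapping ``subject_id -> DataFrame`` or a list of DataFrames each
        carrying a ``subject_id`` column; every table needs ``peep_cmH2O``
        and the requested ``variable``.
    category
        ``"recruited"``, ``"overinflated"`` or ``"cyclic"``.
    use_percentages
        Correlate percentages of total lung pixels instead of raw counts.
    fisher_test
        Also report a one-sample t-test on Fisher-z-transformed per-subject
        r values (one plausible reading of a group-level p; not a default).

    Subjects with fewer than three matched, non-failed steps are skipped
    with a warning; a trial whose subject has no ancillary table raises
    :class:`ConfigError`.
    """
    tables = _normalise_ancillary(ancillary)
    missing = [t.subject_id for t in trials if t.subject_id not in tables]
    if missing:
        raise ConfigError(f"no ancillary table for subjects: {missing}")

    subjects, rs, ps, warnings = [], [], [], []
    for trial in trials:
        table = tables[trial.subject_id]
        if variable not in table.columns:
            raise ConfigError(
                f"ancillary table of {trial.subject_id} lacks column {variable!r}"
            )
        values, physio = [], []
        lookup = dict(zip(table["peep_cmH2O"].astype(float), table[variable]))
        for s in trial.steps:
            if s.failed or s.peep_cmH2O not in lookup:
                continue
            v = lookup[s.peep_cmH2O]
            if pd.isna(v):
                continue
            source = s.percentages if use_percentages else s.counts
            values.append(float(source[category]))
            physio.append(float(v))
        if len(values) < MIN_STEPS:
            warnings.append(
                f"{trial.subject_id}: only {len(values)} matched steps, skipped"
            )
            continue
        r, p = pearson(values, physio)
        subjects.append(trial.subject_id)
        rs.append(r)
        ps.append(p)

    if not rs:
        raise ConfigError("no subject had enough matched steps to correlate")
    group_mean = float(np.mean(rs))
    group_sd = float(np.std(rs, ddof=1)) if len(rs) >= 2 else None
    group_p = None
    if fisher_test and len(rs) >= 2:
        z = np.arctanh(np.clip(rs, -1 + 1e-15, 1 - 1e-15))
        group_p = float(sps.ttest_1samp(z, 0.0).pvalue)
    return CorrelationResult(
        subjects=tuple(subjects),
        per_subject_r=tuple(rs),
        per_subject_p=tuple(ps),
        group_mean_r=group_mean,
        group_sd_r=group_sd,
        group_p=group_p,
        warnings=tuple(warnings),
    )


def _normalise_ancillary(ancillary) -> dict[str, pd.DataFrame]:
    if isinstance(ancillary, dict):
        return ancillary
    tables: dict[str, pd.DataFrame] = {}
    for df in ancillary:
        if "subject_id" not in df.columns:
            raise ConfigError(
                "ancillary DataFrames must carry a subject_id column "
                "(or pass a {subject_id: DataFrame} mapping)"
            )
        for sid, sub in df.groupby("subject_id"):
            tables[str(sid)] = sub
    return tables


def crs(vt_ml: float, pplat_cmH2O: float, peep_cmH2O: float) -> float:
    """Quasi-static respiratory system compliance, ml/cmH2O.

    Crs = VT / (Pplat − PEEP); the standard definition from an
    end-inspiratory hold.
    """
    if vt_ml <= 0:
        raise ValidationError("tidal volume must be positive")
    if pplat_cmH2O <= peep_cmH2O:
        raise ValidationError("plateau pressure must exceed PEEP")
    return vt_ml / (pplat_cmH2O - peep_cmH2O)
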