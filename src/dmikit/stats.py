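"""Test-retest repeatability statistics.

The three core statistics (Lodge-style, all relative so different timepoints
and metabolites are comparable):

* between-subject CoV = SD / mean  (sample SD, n-1 denominator; when two
  sessions are available, each subject's sessions are averaged first so the
  estimand is variation between individuals),
* within-subject CoV = [SD(Exam2 - Exam1) / sqrt(2)] / grand mean,
* repeatability coefficient = 1.96 * sqrt(2) * within-subject CoV — the
  smallest change unlikely (95%) to be measurement noise.

All three are reported in percent and are invariant under a common positive
rescaling of the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

RC_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass
class RepeatabilityInput:
    """Matched exam pairs for one metabolite/region/timepoint cell."""

    exam1: np.ndarray
    exam2: np.ndarray
    labels: np.ndarray | None = None  # subject ids

    def __post_init__(self) -> None:
        self.exam1 = np.asarray(self.exam1, dtype=float)
        self.exam2 = np.asarray(self.exam2, dtype=float)
        if self.exam1.shape != self.exam2.shape:
            raise ValueError("exam1 and exam2 must be matched (equal length)")


def between_subject_cov(values: np.ndarray) -> float:
    """Between-subject CoV in percent.

    ``values`` is either one value per subject, or an (n_subjects, n_sessions)
    array in which case sessions are averaged per subject first.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 2:
        v = v.mean(axis=1)
    if v.size < 2:
        raise ValueError("need at least 2 subjects")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("between-subject CoV requires a positive mean")
    return 100.0 * v.std(ddof=1) / mean


def within_subject_cov(data: RepeatabilityInput | np.ndarray, exam2: np.ndarray | None = None) -> float:
    """Within-subject CoV in percent: SD of paired differences over sqrt(2),
    relative to the grand mean of all observations."""
    if not isinstance(data, RepeatabilityInput):
        data = RepeatabilityInput(data, exam2)
    e1, e2 = data.exam1, data.exam2
    if e1.size < 2:
        raise ValueError("need at least 2 matched pairs")
    grand = np.concatenate([e1, e2]).mean()
    if grand <= 0:
        raise ValueError("within-subject CoV requires a positive grand mean")
    return 100.0 * (np.std(e2 - e1, ddof=1) / math.sqrt(2.0)) / grand


def repeatability_coefficient(ws_cov_pct: float) -> float:
    """Repeatability coefficient, percent: 1.96 * sqrt(2) * within-subject CoV."""
    if ws_cov_pct < 0:
        raise ValueError("within-subject CoV must be non-negative")
    return RC_FACTOR * ws_cov_pct


def bland_altman(data: RepeatabilityInput | np.ndarray, exam2: np.ndarray | None = None) -> tuple[float, float, float]:
    """Bland-Altman agreement: (bias, lower limit, upper limit).

    bias = mean(exam2 - exam1); limits = bias +/- 1.96 SD(differences).
    """
    if not isinstance(data, RepeatabilityInput):
        data = RepeatabilityInput(data, exam2)
    diff = data.exam2 - data.exam1
    if diff.size < 2:
        raise ValueError("need at least 2 pairs")
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def dynamics_fit(time_min: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Ordinary least-squares quadratic fit of pooled dynamics data.

    Returns coefficients (c0, c1, c2) of ``c0 + c1 t + c2 t^2``.  Requires at
    least 3 distinct timepoints.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("quadratic fit needs >= 3 distinct timepoints")
    design = np.stack([np.ones_like(t), t, t * t], axis=1)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def repeatability_table(regional: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Build a repeatability table from tidy per-exam regional values.

    ``regional`` needs columns subject, session (0/1), timepoint_min, region,
    metabolite, and ``value_col``.  One output row per metabolite x timepoint x
    region with within-subject CoV, repeatability coefficient, between-subject
    CoV (all %), and the number of complete subject pairs n.  Cells with fewer
    than 2 complete pairs are reported as missing.
    """
    rows = []
    for (metab, tp, region), cell in regional.groupby(
        ["metabolite", "timepoint_min", "region"], sort=True
    ):
        wide = cell.pivot_table(index="subject", columns="session", values=value_col)
        wide = wide.dropna()
        n = len(wide)
        # cells with no usable signal (e.g. metabolites at baseline, where the
        # mean is not positive) are reported as missing
        try:
            if n >= 2 and wide.shape[1] >= 2:
                e1, e2 = wide.iloc[:, 0].to_numpy(), wide.iloc[:, 1].to_numpy()
                ws = within_subject_cov(e1, e2)
                rc = repeatability_coefficient(ws)
                bs = between_subject_cov(np.stack([e1, e2], axis=1))
            elif n >= 2:
                ws, rc = np.nan, np.nan
                bs = between_subject_cov(wide.iloc[:, 0].to_numpy())
            else:
                ws = rc = bs = np.nan
        except ValueError:
            ws = rc = bs = np.nan
        rows.append((metab, tp, region, ws, rc, bs, n))
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite",
            "timepoint",
            "region",
            "within_subject_cov_pct",
            "repeatability_coefficient_pct",
            "between_subject_cov_pct",
            "n",
        ],
    )
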