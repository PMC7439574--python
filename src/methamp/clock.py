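"""Targeted epigenetic age prediction from a small panel of CpG beta values.

The packaged default model is a three-CpG blood clock: a linear predictor of
chronological age from pyrosequencing-style beta values at CpGs in *ASPA*
(cg02228185), *ITGA2B* (cg25809905) and a CpG in *PDE4C* directly upstream of
cg17861230 (that CpG is absent from the Illumina BeadChip, hence the
``_upstream`` suffix used as its marker id here).

Predicted ages are reported as-is: negative or very large predictions are
meaningful outputs of the linear model (iPSC-derived samples predict close to
0 years), so clamping at zero is a separate opt-in step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ClockModel",
    "BLOOD_CLOCK_3CPG",
    "AgePrediction",
    "CohortSummary",
    "predict_epigenetic_age",
    "delta_ages",
    "cohort_summary",
]


@dataclass(frozen=True)
class ClockModel:
    """Linear age predictor: ``age = intercept + sum(weight_i * beta_i)``.

    Parameters
    ----------
    intercept
        Predicted age in years when all betas are zero.
    coefficients
        Ordered ``(marker_id, weight)`` pairs; weights are in years per
        beta-unit. Marker ids must be unique.
    """

    intercept: float
    coefficients: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        ids = [m for m, _ in self.coefficients]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate marker ids in clock model")
        if not ids:
            raise ValueError("clock model needs at least one marker")

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.coefficients)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.coefficients], dtype=float)


#: Default blood clock: intercept 38.0 years; weights in years per beta-unit.
BLOOD_CLOCK_3CPG = ClockModel(
    intercept=38.0,
    coefficients=(
        ("cg02228185", -26.4),
        ("cg25809905", -23.7),
        ("cg17861230_upstream", 164.7),
    ),
)


@dataclass(frozen=True)
class AgePrediction:
    subject_id: str
    predicted_age: float
    delta_age: float  # predicted - chronological


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level accuracy and age-acceleration statistics.

    ``mae`` is the mean absolute delta age, ``mean_delta`` the signed mean;
    ``r_squared`` is the squared Pearson correlation of predicted versus
    chronological age. When a reference group is supplied, ``t_statistic`` /
    ``p_value`` report a two-sample unpaired t test of the delta ages.
    """

    group: str
    n: int
    mae: float
    mean_delta: float
    r_squared: float | None
    t_statistic: float | None = None
    p_value: float | None = None


def predict_epigenetic_age(
    betas: Mapping[str, float],
    model: ClockModel = BLOOD_CLOCK_3CPG,
    *,
    percent: bool = False,
    clamp_negative: bool = False,
) -> float:
    """Evaluate the clock on one sample's beta values.

    Parameters
    ----------
    betas
        Map of marker id to beta value in [0, 1]; must cover every marker of
        ``model`` (extra keys are ignored).
    percent
        Set explicitly when betas are on the 0–100 scale; they are divided by
        100. Percent input is never auto-detected.
    clamp_negative
        If set, negative predictions are floored at 0 years.
    """
    total = model.intercept
    for marker, weight in model.coefficients:
        if marker not in betas:
            raise KeyError(f"missing beta value for marker {marker!r}")
        beta = float(betas[marker])
        if percent:
            beta /= 100.0
        if not 0.0 <= beta <= 1.0 or not np.isfinite(beta):
            raise ValueError(
                f"beta for {marker!r} is {beta}, outside the unit interval"
            )
        total += weight * beta
    return max(total, 0.0) if clamp_negative else total


def delta_ages(predictions: Iterable[tuple[float, float]]) -> list[float]:
    """Elementwise ``predicted - chronological`` for (predicted, chronological)
    pairs; positive values indicate age acceleration."""
    return [float(pred) - float(chron) for pred, chron in predictions]


def cohort_summary(
    deltas: Sequence[float],
    chronological: Sequence[float] | None = None,
    predicted: Sequence[float] | None = None,
    reference_deltas: Sequence[float] | None = None,
    *,
    group: str = "cohort",
    equal_var: bool = False,
) -> CohortSummary:
    """Summarise a cohort's delta ages.

    MAE and mean delta follow the usual definitions over delta age x_i:
    MAE = (1/n) * sum(|x_i|) and mean = (1/n) * sum(x_i). R^2 is computed
    only when both ``chronological`` and ``predicted`` are given, as the
    squared Pearson correlation between them. ``reference_deltas`` triggers a
    two-sided unpaired t test (Welch by default; ``equal_var=True`` for the
    pooled-variance Student flavour).
    """
    x = np.asarray(deltas, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty cohort")
    if chronological is not None and len(chronological) != n:
        raise ValueError("chronological ages and deltas differ in length")
    if predicted is not None and len(predicted) != n:
        raise ValueError("predicted ages and deltas differ in length")

    mae = float(np.mean(np.abs(x)))
    mean_delta = float(np.mean(x))

    r_squared = None
    if chronological is not None and predicted is not None:
        r, _ = stats.pearsonr(np.asarray(predicted, float), np.asarray(chronological, float))
        r_squared = float(r**2)

    t_stat = p_val = None
    if reference_deltas is not None:
        ref = np.asarray(reference_deltas, dtype=float)
        if n < 2 or ref.size < 2:
            raise ValueError("t test requires at least 2 subjects per group")
        res = stats.ttest_ind(x, ref, equal_var=equal_var)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
        if np.isnan(t_stat):  # identical constant samples: no difference
            t_stat, p_val = 0.0, 1.0

    return CohortSummary(
        group=group,
        n=n,
        mae=mae,
        mean_delta=mean_delta,
        r_squared=r_squared,
        t_statistic=t_stat,
        p_value=p_val,
    )
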