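"""Telomere-length-vs-age modelling.

Telomere length (flow-FISH, kilobases) shortens roughly linearly with age in
healthy blood. Fitting length ~ age on healthy donors and inverting the line
converts an observed telomere length into a "telomere age": the age at which
the healthy regression attains that length. The offset to chronological age
(delta telomere age) quantifies disease-specific attrition; in bone-marrow
failure it can exceed the human lifespan and is deliberately not clamped.

The fit is ordinary least squares on raw kilobases against age only; a log
scale is available via ``log_scale`` for users who prefer multiplicative
attrition models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .cohort import CellFraction, SubjectRecord

__all__ = [
    "TelomereModel",
    "TelomereAgePrediction",
    "fit_telomere_model",
    "predict_telomere_age",
]


@dataclass(frozen=True)
class TelomereModel:
    """OLS fit of telomere length (kb, or log-kb) on age for one cell fraction."""

    slope: float  # kb per year, expected negative
    intercept: float  # kb at age 0
    residual_sd: float  # kb, n-2 denominator
    n_train: int
    cell_fraction: CellFraction | None = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.n_train < 3:
            raise ValueError("telomere model requires >= 3 training subjects")
        if self.slope == 0:
            raise ValueError("slope must be nonzero for age inversion")


@dataclass(frozen=True)
class TelomereAgePrediction:
    subject_id: str
    telomere_age: float
    delta_telomere_age: float  # telomere_age - chronological_age


def fit_telomere_model(
    healthy: Iterable[SubjectRecord],
    cell_fraction: CellFraction | str | None = None,
    *,
    log_scale: bool = False,
) -> TelomereModel:
    """Fit the healthy-donor regression of telomere length on age.

    Subjects without a telomere measurement, or from a different cell
    fraction when one is requested, are dropped. Raises on fewer than three
    usable records or zero age variance.
    """
    if cell_fraction is not None and not isinstance(cell_fraction, CellFraction):
        cell_fraction = CellFraction(cell_fraction)
    ages, lengths = [], []
    for rec in healthy:
        if rec.telomere_kb is None:
            continue
        if cell_fraction is not None and rec.cell_fraction != cell_fraction:
            continue
        ages.append(rec.chronological_age)
        lengths.append(rec.telomere_kb)
    if len(ages) < 3:
        raise ValueError(
            f"need >= 3 healthy subjects with telomere length, got {len(ages)}"
        )
    x = np.asarray(ages, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero age variance in training subjects")
    if log_scale:
        y = np.log(y)

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(fit.ssr / (len(x) - 2))) if len(x) > 2 else 0.0
    return TelomereModel(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        residual_sd=resid_sd,
        n_train=len(x),
        cell_fraction=cell_fraction,
        log_scale=log_scale,
    )


def predict_telomere_age(telomere_kb: float, model: TelomereModel) -> float:
    """Invert the healthy regression: the age at which the fitted line attains
    the observed telomere length, ``(length - intercept) / slope``."""
    if telomere_kb <= 0:
        raise ValueError("telomere length must be positive")
    y = np.log(telomere_kb) if model.log_scale else telomere_kb
    return float((y - model.intercept) / model.slope)


def telomere_age_table(
    subjects: Sequence[SubjectRecord], model: TelomereModel
) -> list[TelomereAgePrediction]:
    """Telomere age and delta for every subject with a telomere measurement."""
    out = []
    for rec in subjects:
        if rec.telomere_kb is None:
            continue
        t_age = predict_telomere_age(rec.telomere_kb, model)
        out.append(
            TelomereAgePrediction(
                subject_id=rec.subject_id,
                telomere_age=t_age,
                delta_telomere_age=t_age - rec.chronological_age,
            )
        )
    return out
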