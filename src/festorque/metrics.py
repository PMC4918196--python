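"""Prediction-quality measures: RMSE, NRMSE and variance accounted for."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray


def evaluate(tau_meas: ArrayLike, tau_pred: ArrayLike) -> tuple[float, float, float]:
    """Return ``(rmse, nrmse, vaf)`` for a predicted torque series.

    * ``rmse``  — root mean square error, Nm.
    * ``nrmse`` — RMSE as a percentage of the measured peak-to-peak range.
    * ``vaf``   — variance accounted for, ``100 * (1 - var(residual) / var(measured))``,
      in percent.  Population (1/N) variances are used for both numerator
      and denominator.  VAF can be negative (worse than the mean predictor)
      and is never clipped.

    Raises
    ------
    ValueError
        Mismatched or empty series; zero measured range ("NRMSE
        undefined"); zero measured variance ("VAF undefined").
    """
    y = np.asarray(tau_meas, dtype=float)
    yhat = np.asarray(tau_pred, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("series must be non-empty 1-D arrays of equal length")
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    span = float(np.max(y) - np.min(y))
    if span <= 0:
        raise ValueError("NRMSE undefined: measured range is zero")
    var_y = float(np.var(y))
    if var_y <= 0:
        raise ValueError("VAF undefined: measured variance is zero")
    nrmse = 100.0 * rmse / span
    vaf = 100.0 * (1.0 - float(np.var(resid)) / var_y)
    return rmse, nrmse, vaf


@dataclass(frozen=True)
class PredictionReport:
    """Free-run prediction outcome over the post-identification phase."""

    estimator: str
    tau_meas: NDArray[np.float64]
    tau_pred: NDArray[np.float64]
    rmse: float
    nrmse: float
    vaf: float
    k_id: int  # last identification loop; metrics cover k > k_id only
    per_loop_time_s: NDArray[np.float64] = field(default_factory=lambda: np.array([]))
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.nrmse < 0:
            raise ValueError("error measures must be non-negative")
        if self.vaf > 100.0 + 1e-9:
            raise ValueError("VAF cannot exceed 100 %")

    @classmethod
    def from_series(
        cls,
        estimator: str,
        tau_meas: ArrayLike,
        tau_pred: ArrayLike,
        k_id: int,
        per_loop_time_s: ArrayLike | None = None,
        subject_id: str = "sim",
    ) -> "PredictionReport":
        rmse, nrmse, vaf = evaluate(tau_meas, tau_pred)
        return cls(
            estimator=estimator,
            tau_meas=np.asarray(tau_meas, dtype=float),
            tau_pred=np.asarray(tau_pred, dtype=float),
            rmse=rmse,
            nrmse=nrmse,
            vaf=vaf,
            k_id=k_id,
            per_loop_time_s=(
                np.asarray(per_loop_time_s, dtype=float)
                if per_loop_time_s is not None
                else np.array([])
            ),
            subject_id=subject_id,
        )

    def summary_row(self) -> dict:
        """One row of the tabular report (subject, estimator, metrics)."""
        return {
            "subject_id": self.subject_id,
            "estimator": self.estimator,
            "rmse_Nm": self.rmse,
            "nrmse_pct": self.nrmse,
            "vaf_pct": self.vaf,
        }
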