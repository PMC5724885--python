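"""Evaluation statistics for calibration and prediction.

Conventions (the field's names, with the denominators this package uses):

* SEC  — standard error of calibration, sqrt(SSE / (n - n_lv - 1)).
* SECV — standard error of cross-validation, sqrt(mean squared held-out
  residual), denominator n.
* SEP  — standard error of prediction on an independent set,
  sqrt(mean squared residual), denominator n.
* SEP(C) — SEP corrected for bias: residuals re-centred, denominator n-1.
* bias — mean(predicted - observed).
* RPD  — ratio of performance to deviation, SD / SECV (unitless;
  > 3 is generally considered sufficient for screening).
* R2p  — squared Pearson correlation of predicted vs observed.

The SEP/SEP(C) denominators imply the identity
SEP^2 = SEP(C)^2 * (n-1)/n + bias^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = ["ValidationResult", "rpd", "validation_stats", "pearson", "linreg"]


@dataclass(frozen=True)
class ValidationResult:
    """Prediction-quality summary for an independent validation set."""

    n: int
    SEP: float
    SEP_C: float
    bias: float
    R2p: float
    SD: float
    RPD_val: float

    def round(self, ndigits: int = 2) -> dict:
        """Presentation copy rounded to ``ndigits`` (tables round to 2)."""
        return {
            "n": self.n,
            **{
                k: round(getattr(self, k), ndigits)
                for k in ("SEP", "SEP_C", "bias", "R2p", "SD", "RPD_val")
            },
        }


def rpd(sd: float, secv: float, ndigits: int | None = None) -> float:
    """RPD = SD / SECV; scale-invariant model-quality ratio."""
    if secv <= 0:
        raise ValueError("SECV must be positive")
    value = sd / secv
    return round(value, ndigits) if ndigits is not None else value


def pearson(x, y) -> float:
    """Product-moment correlation; requires n >= 3 and non-zero variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs two equal-length vectors, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def linreg(x, y) -> tuple[float, float, float]:
    """OLS fit y = slope*x + intercept; returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("linreg needs two equal-length vectors, n >= 3")
    if x.std() == 0:
        raise ValueError("zero variance in x")
    fit = _sps.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2


def validation_stats(pred, obs) -> ValidationResult:
    """SEP, SEP(C), bias, R2p, SD of observed, and RPD = SD/SEP(C)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    n = pred.size
    e = pred - obs
    bias = float(e.mean())
    sep = float(np.sqrt(np.mean(e**2)))
    sep_c = float(np.sqrt(np.sum((e - bias) ** 2) / (n - 1)))
    if obs.std() == 0:
        raise ValueError("zero variance in observed values: R2p undefined")
    r2p = pearson(pred, obs) ** 2
    sd = float(obs.std(ddof=1))
    return ValidationResult(
        n=n,
        SEP=sep,
        SEP_C=sep_c,
        bias=bias,
        R2p=r2p,
        SD=sd,
        RPD_val=sd / sep_c if sep_c > 0 else float("inf"),
    )
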