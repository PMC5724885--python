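"""Modified PLS calibration with cross-validation and outlier elimination.

"Modified" PLS here means PLS1 in which both the reference values and the
spectral data at each wavelength are centred and scaled to standard
deviation 1.0 before factor extraction (NIPALS).  Model complexity (the
number of latent variables) is chosen by leave-one-out cross-validation
at the minimum SECV; calibration then iterates outlier elimination:

* H-outliers — samples whose spectra sit far from the calibration cloud:
  squared Mahalanobis distance in latent-score space divided by the
  number of latent variables (the "global H" convention), flagged above
  ``h_max`` (default 10);
* t-outliers — samples whose reference value disagrees with the model:
  |residual| / SECV, flagged above ``t_max`` (default 2.5).

Up to ``max_iterations`` (default 3) rounds of flag-remove-recalibrate
are performed; most models stabilise after one or two.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pretreat import PretreatmentSpec, Pretreater, parse_spec
from .spectra import SpectraSet
from .stats import pearson

__all__ = [
    "OutlierLimits",
    "PLSFit",
    "CalibrationModel",
    "mpls_fit",
    "loocv",
    "detect_outliers",
    "calibrate",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class OutlierLimits:
    """Elimination thresholds: H (Mahalanobis/LV), t (|resid|/SECV)."""

    h_max: float = 10.0
    t_max: float = 2.5
    max_iterations: int = 3

    def __post_init__(self):
        if self.h_max <= 0 or self.t_max <= 0 or self.max_iterations <= 0:
            raise ValueError("outlier limits must be positive")


def _autoscale(X: np.ndarray, ddof: int = 1):
    """Column centre/scale to SD 1; zero-SD columns get scale 1 and a mask."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    keep = sd > 0
    scale = np.where(keep, sd, 1.0)
    return (X - mean) / scale, mean, scale, keep


def _nipals_pls1(Xs: np.ndarray, ys: np.ndarray, max_lv: int, tol: float = 1e-12):
    """NIPALS factor extraction for a single response.

    Returns weights W (p x a), loadings P (p x a), y-loadings q (a,),
    scores T (n x a); may return fewer than ``max_lv`` factors if the
    residual X or covariance collapses (rank exhausted).
    """
    X = Xs.copy()
    y = ys.copy()
    n, p = X.shape
    W, P, Q, T = [], [], [], []
    for _ in range(max_lv):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn < tol * max(1.0, np.linalg.norm(y)):
            break
        w /= wn
        t = X @ w
        tt = t @ t
        if tt < tol:
            break
        pvec = X.T @ t / tt
        q = (y @ t) / tt
        X -= np.outer(t, pvec)
        y = y - t * q
        W.append(w)
        P.append(pvec)
        Q.append(q)
        T.append(t)
    if not W:
        raise ValueError("no PLS factor extractable (constant y or zero X)")
    return (
        np.column_stack(W),
        np.column_stack(P),
        np.asarray(Q),
        np.column_stack(T),
    )


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, a: int) -> np.ndarray:
    """Regression vector in autoscaled space using the first ``a`` factors."""
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


@dataclass
class PLSFit:
    """A fitted MPLS regression (autoscaled NIPALS PLS1)."""

    n_lv: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    keep: np.ndarray  # boolean mask of non-constant wavelengths
    y_mean: float
    y_scale: float
    coef: np.ndarray  # regression vector in autoscaled space, kept columns
    scores: np.ndarray  # training scores T (n x n_lv)
    fitted: np.ndarray  # training fitted values, original units
    sec: float
    r2c: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X[:, self.keep] - self.x_mean[self.keep]) / self.x_scale[self.keep]
        return self.y_mean + self.y_scale * (Xs @ self.coef)


def mpls_fit(X: np.ndarray, y: np.ndarray, n_lv: int, ddof: int = 1) -> PLSFit:
    """Fit MPLS with ``n_lv`` latent variables.

    X and y are centred and scaled to unit SD per column before NIPALS.
    SEC uses df = n - n_lv - 1; R2c is the squared correlation of fitted
    vs observed values.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n != y.size:
        raise ValueError("X and y sample counts differ")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if n <= n_lv + 1:
        raise ValueError(f"need n > n_lv + 1 samples (n={n}, n_lv={n_lv})")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed")
    if y.std() == 0:
        raise ValueError("constant reference values: nothing to calibrate")

    Xs, x_mean, x_scale, keep = _autoscale(X, ddof=ddof)
    if not keep.all():
        warnings.warn(
            f"dropped {int((~keep).sum())} constant wavelength(s)", stacklevel=2
        )
    y_mean = float(y.mean())
    y_scale = float(y.std(ddof=ddof))
    ys = (y - y_mean) / y_scale

    W, P, q, T = _nipals_pls1(Xs[:, keep], ys, n_lv)
    attained = W.shape[1]
    if attained < n_lv:
        warnings.warn(
            f"rank limited: {attained} factors extracted (requested {n_lv})",
            stacklevel=2,
        )
        n_lv = attained
    coef = _coefficients(W, P, q, n_lv)
    fitted = y_mean + y_scale * (Xs[:, keep] @ coef)
    resid = y - fitted
    df = max(n - n_lv - 1, 1)
    sec = float(np.sqrt(np.sum(resid**2) / df))
    r2c = pearson(fitted, y) ** 2 if np.std(fitted) > 0 else 0.0
    return PLSFit(
        n_lv=n_lv,
        x_mean=x_mean,
        x_scale=x_scale,
        keep=keep,
        y_mean=y_mean,
        y_scale=y_scale,
        coef=coef,
        scores=T[:, :n_lv],
        fitted=fitted,
        sec=sec,
        r2c=float(r2c),
    )


def loocv(X: np.ndarray, y: np.ndarray, max_lv: int, ddof: int = 1):
    """Leave-one-out cross-validation over 1..max_lv latent variables.

    Each sample is removed in turn, the model (including the autoscaling)
    is re-estimated on the rest, and the held-out sample is predicted.
    Returns ``(secv, best_lv, cv_pred)``: SECV per LV count (denominator
    n), the argmin LV (ties go to fewer factors), and the n x max_lv
    matrix of held-out predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < max_lv + 2:
        max_lv = max(1, n - 2)
    cv_pred = np.empty((n, max_lv))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        Xs, x_mean, x_scale, keep = _autoscale(Xi, ddof=ddof)
        y_mean = yi.mean()
        y_scale = yi.std(ddof=ddof)
        ys = (yi - y_mean) / y_scale
        W, P, q, T = _nipals_pls1(Xs[:, keep], ys, max_lv)
        attained = W.shape[1]
        xh = (X[i, keep] - x_mean[keep]) / x_scale[keep]
        for a in range(1, max_lv + 1):
            coef = _coefficients(W, P, q, min(a, attained))
            cv_pred[i, a - 1] = y_mean + y_scale * (xh @ coef)
    secv = np.sqrt(np.mean((cv_pred - y[:, None]) ** 2, axis=0))
    best_lv = int(np.argmin(secv)) + 1  # argmin takes the first (fewest LV) tie
    return secv, best_lv, cv_pred


def detect_outliers(
    fit: PLSFit, y: np.ndarray, secv: float, limits: OutlierLimits = OutlierLimits()
):
    """Flag H- and t-outliers against a fitted calibration.

    Returns a list of ``(index, kind, value)`` with kind ``"H"`` (squared
    Mahalanobis distance of the sample's latent scores over n_lv) or
    ``"t"`` (|residual| / SECV).  A sample failing both checks is
    reported once, as an H-outlier.
    """
    T = fit.scores
    n, a = T.shape
    Tc = T - T.mean(axis=0)
    cov = Tc.T @ Tc / (n - 1)
    try:
        cinv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular score covariance") from exc
    d2 = np.einsum("ij,jk,ik->i", Tc, cinv, Tc)
    H = d2 / a
    t = np.abs(np.asarray(y, dtype=float) - fit.fitted) / secv
    flags = []
    for i in range(n):
        if H[i] > limits.h_max:
            flags.append((i, "H", float(H[i])))
        elif t[i] > limits.t_max:
            flags.append((i, "t", float(t[i])))
    return flags


@dataclass
class CalibrationModel:
    """A calibrated trait model: pre-treatment + MPLS fit + statistics.

    ``stats`` holds n_used, SEC, R2c, SECV, R2cv, SD (of retained
    reference values) and RPD = SD/SECV; ``outlier_log`` records every
    removal as (iteration, sample_id, kind, value).
    """

    trait: str
    units: str
    pretreatment: PretreatmentSpec
    pretreater: Pretreater
    grid: np.ndarray
    sample_ids: list[str]
    n_lv: int
    fit: PLSFit
    stats: dict
    outlier_log: list = field(default_factory=list)
    secv_by_lv: np.ndarray | None = None
    r2cv_alternative: float | None = None  # 1 - PRESS/SST convention

    def predict(self, spectra: SpectraSet) -> np.ndarray:
        return predict(self, spectra)


_TRAIT_UNITS = {"DMC": "%", "TCC": "ug/g", "ATBC": "ug/g"}


def calibrate(
    spectra: SpectraSet,
    refs,
    trait: str,
    pretreatment: PretreatmentSpec | str = "SNVD+1111",
    limits: OutlierLimits = OutlierLimits(),
    max_lv: int = 16,
    units: str | None = None,
) -> CalibrationModel:
    """Full calibration: pre-treat, LOOCV-select LV, eliminate outliers.

    ``refs`` is a reference DataFrame (``sample_id`` column + trait
    columns); only samples present in both inputs with a non-missing
    trait value are used.  Scatter corrections are estimated once per
    elimination round on the retained samples (not inside each LOOCV
    fold).
    """
    if isinstance(pretreatment, str):
        pretreatment = parse_spec(pretreatment)
    if trait not in refs.columns:
        raise KeyError(f"trait {trait!r} not in reference table")
    ref_map = refs.set_index("sample_id")[trait].dropna().to_dict()
    keep_idx = [i for i, sid in enumerate(spectra.sample_ids) if sid in ref_map]
    if len(keep_idx) < 4:
        raise ValueError(f"only {len(keep_idx)} matched samples for {trait!r}")
    if len(keep_idx) < 20:
        warnings.warn(
            f"only {len(keep_idx)} matched samples; >= 20 recommended", stacklevel=2
        )

    ids = [spectra.sample_ids[i] for i in keep_idx]
    raw = spectra.matrix[keep_idx]
    y = np.array([ref_map[sid] for sid in ids])

    outlier_log: list[tuple[int, str, str, float]] = []
    pretreater = Pretreater(pretreatment)
    for iteration in range(1, limits.max_iterations + 2):
        pretreater = Pretreater(pretreatment)
        base = SpectraSet(sample_ids=ids, grid=spectra.grid, matrix=raw)
        X = pretreater.fit_transform(base).matrix
        secv_by_lv, best_lv, cv_pred = loocv(X, y, max_lv)
        fit = mpls_fit(X, y, best_lv)
        secv = float(secv_by_lv[best_lv - 1])
        if iteration > limits.max_iterations:
            break
        flags = detect_outliers(fit, y, secv, limits)
        if not flags:
            break
        drop = sorted(i for i, _, _ in flags)
        if len(drop) >= len(ids) - 3:
            raise ValueError("outlier elimination would remove (almost) all samples")
        for i, kind, value in flags:
            outlier_log.append((iteration, ids[i], kind, value))
        keep_mask = np.ones(len(ids), dtype=bool)
        keep_mask[drop] = False
        ids = [sid for sid, k in zip(ids, keep_mask) if k]
        raw = raw[keep_mask]
        y = y[keep_mask]

    cv = cv_pred[:, best_lv - 1]
    sd = float(y.std(ddof=1))
    r2cv = pearson(cv, y) ** 2
    sst = float(np.sum((y - y.mean()) ** 2))
    r2cv_alt = 1.0 - float(np.sum((y - cv) ** 2)) / sst
    stats = {
        "n_used": len(ids),
        "SEC": fit.sec,
        "R2c": fit.r2c,
        "SECV": secv,
        "R2cv": float(r2cv),
        "SD": sd,
        "RPD": sd / secv,
    }
    return CalibrationModel(
        trait=trait,
        units=units or _TRAIT_UNITS.get(trait, ""),
        pretreatment=pretreatment,
        pretreater=pretreater,
        grid=spectra.grid.copy(),
        sample_ids=ids,
        n_lv=fit.n_lv,
        fit=fit,
        stats=stats,
        outlier_log=outlier_log,
        secv_by_lv=secv_by_lv,
        r2cv_alternative=float(r2cv_alt),
    )


def predict(model: CalibrationModel, spectra: SpectraSet) -> np.ndarray:
    """Predict trait values: stored pre-treatment, then stored coefficients."""
    if spectra.grid.shape != model.grid.shape or not np.allclose(
        spectra.grid, model.grid
    ):
        raise ValueError("wavelength grid does not match the training grid")
    X = model.pretreater.transform(spectra).matrix
    return model.fit.predict(X)


# ---------------------------------------------------------------------------
# serialization: a single JSON bundle (arrays as lists) round-trips the model


def save_model(model: CalibrationModel, path) -> None:
    fit = model.fit
    payload = {
        "trait": model.trait,
        "units": model.units,
        "pretreatment": {
            "scatter": model.pretreatment.scatter,
            "code": list(model.pretreatment.code),
            "segments": [list(s) for s in model.pretreatment.segments],
            "snv_ddof": model.pretreatment.snv_ddof,
        },
        "msc_references": {
            str(k): v.tolist() for k, v in model.pretreater.msc_references_.items()
        },
        "grid": model.grid.tolist(),
        "sample_ids": model.sample_ids,
        "n_lv": model.n_lv,
        "fit": {
            "n_lv": fit.n_lv,
            "x_mean": fit.x_mean.tolist(),
            "x_scale": fit.x_scale.tolist(),
            "keep": fit.keep.astype(int).tolist(),
            "y_mean": fit.y_mean,
            "y_scale": fit.y_scale,
            "coef": fit.coef.tolist(),
            "scores": fit.scores.tolist(),
            "fitted": fit.fitted.tolist(),
            "sec": fit.sec,
            "r2c": fit.r2c,
        },
        "stats": model.stats,
        "outlier_log": [list(entry) for entry in model.outlier_log],
        "secv_by_lv": (
            model.secv_by_lv.tolist() if model.secv_by_lv is not None else None
        ),
        "r2cv_alternative": model.r2cv_alternative,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> CalibrationModel:
    with open(path) as fh:
        payload = json.load(fh)
    p = payload["pretreatment"]
    spec = PretreatmentSpec(
        scatter=p["scatter"],
        code=tuple(p["code"]),
        segments=tuple(tuple(s) for s in p["segments"]),
        snv_ddof=p["snv_ddof"],
    )
    pretreater = Pretreater(spec)
    pretreater.msc_references_ = {
        int(k): np.asarray(v) for k, v in payload["msc_references"].items()
    }
    pretreater._fitted = True
    f = payload["fit"]
    fit = PLSFit(
        n_lv=f["n_lv"],
        x_mean=np.asarray(f["x_mean"]),
        x_scale=np.asarray(f["x_scale"]),
        keep=np.asarray(f["keep"], dtype=bool),
        y_mean=f["y_mean"],
        y_scale=f["y_scale"],
        coef=np.asarray(f["coef"]),
        scores=np.asarray(f["scores"]),
        fitted=np.asarray(f["fitted"]),
        sec=f["sec"],
        r2c=f["r2c"],
    )
    return CalibrationModel(
        trait=payload["trait"],
        units=payload["units"],
        pretreatment=spec,
        pretreater=pretreater,
        grid=np.asarray(payload["grid"]),
        sample_ids=list(payload["sample_ids"]),
        n_lv=payload["n_lv"],
        fit=fit,
        stats=payload["stats"],
        outlier_log=[tuple(e) for e in payload["outlier_log"]],
        secv_by_lv=(
            np.asarray(payload["secv_by_lv"])
            if payload["secv_by_lv"] is not None
            else None
        ),
        r2cv_alternative=payload["r2cv_alternative"],
    )
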