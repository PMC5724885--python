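"""Spectral pre-treatments: SNV, de-trend, MSC, Norris-Williams smoothing
and gap derivatives, applied segment-wise.

Scatter from particle-size and path-length differences shows up as
additive baseline and multiplicative gain on absorbance spectra.  Two
standard corrections are offered: SNV + de-trend (per-spectrum
standardisation followed by quadratic baseline removal) and MSC
(per-spectrum regression onto a reference, usually the training-set mean,
then removal of the fitted offset and slope).  Derivatives follow the
Norris-Williams scheme -- a running-mean smooth, a finite difference at a
gap, and an optional second smooth -- encoded by the four-digit
(D, G, S1, S2) convention: derivative order, gap in data points, first-
and second-smoothing window (1 = none).

Treatments act independently on wavelength segments (default
350-1000 / 1001-1800 / 1801-2500 nm) and the corrected segments are
concatenated back onto the original grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectraSet

__all__ = [
    "PretreatmentSpec",
    "Pretreater",
    "parse_code",
    "parse_spec",
    "snv",
    "detrend",
    "snvd",
    "msc",
    "nw_smooth",
    "nw_derivative",
    "apply_pretreatment",
    "DEFAULT_SEGMENTS",
]

DEFAULT_SEGMENTS: tuple[tuple[float, float], ...] = (
    (350.0, 1000.0),
    (1001.0, 1800.0),
    (1801.0, 2500.0),
)

_SCATTER_NAMES = {"none": "none", "snvd": "snvd", "msc": "msc"}


def parse_code(code: str) -> tuple[int, int, int, int]:
    """Parse a derivative/smoothing code like ``"1111"`` or ``"0,0,1,1"``.

    Returns (D, G, S1, S2): derivative order (0 = none), gap in data
    points, first- and second-smoothing points (1 = none).
    """
    text = str(code).strip()
    parts = text.split(",") if "," in text else list(text)
    if len(parts) != 4:
        raise ValueError(f"code {code!r} must have exactly 4 settings")
    try:
        d, g, s1, s2 = (int(p) for p in parts)
    except ValueError as exc:
        raise ValueError(f"non-integer setting in code {code!r}") from exc
    if d not in (0, 1, 2):
        raise ValueError(f"derivative order must be 0, 1 or 2, got {d}")
    if d > 0 and g < 1:
        raise ValueError("gap must be >= 1 when a derivative is taken")
    if g < 0 or s1 < 1 or s2 < 1:
        raise ValueError(f"invalid settings in code {code!r}")
    return d, g, s1, s2


@dataclass
class PretreatmentSpec:
    """Scatter correction + (D, G, S1, S2) derivative code + segments.

    Expressible as a config string, e.g. ``"SNVD+1111"``, ``"MSC+2551"``,
    ``"NONE+0011"`` (identity).
    """

    scatter: str = "none"
    code: tuple[int, int, int, int] = (0, 0, 1, 1)
    segments: tuple[tuple[float, float], ...] = DEFAULT_SEGMENTS
    snv_ddof: int = 1

    def __post_init__(self) -> None:
        self.scatter = _SCATTER_NAMES[self.scatter.lower()]
        self.code = parse_code(",".join(str(c) for c in self.code))
        segs = tuple((float(lo), float(hi)) for lo, hi in self.segments)
        for lo, hi in segs:
            if hi < lo:
                raise ValueError(f"segment ({lo}, {hi}) reversed")
        for (_, hi_a), (lo_b, _) in zip(segs, segs[1:]):
            if lo_b <= hi_a:
                raise ValueError("segments must be ordered and non-overlapping")
        self.segments = segs

    def __str__(self) -> str:
        return f"{self.scatter.upper()}+{''.join(str(c) for c in self.code)}"


def parse_spec(text: str, segments=DEFAULT_SEGMENTS) -> PretreatmentSpec:
    """Parse ``"SNVD+1111"`` / ``"MSC+2,5,5,1"`` / ``"NONE+0011"``."""
    try:
        scatter, code = text.split("+", 1)
    except ValueError as exc:
        raise ValueError(f"expected SCATTER+CODE, got {text!r}") from exc
    key = scatter.strip().lower()
    if key not in _SCATTER_NAMES:
        raise ValueError(f"unknown scatter correction {scatter!r}")
    return PretreatmentSpec(scatter=key, code=parse_code(code), segments=segments)


def snv(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to SD 1.

    Uses sample SD (ddof=1) by default.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("SNV needs at least 2 points")
    sd = x.std(ddof=ddof)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("constant spectrum: SNV undefined (zero SD)")
    return (x - x.mean()) / sd


def detrend(values: np.ndarray, k: np.ndarray | None = None) -> np.ndarray:
    """Residual after a least-squares quadratic fit over the point index.

    Fits S = a + b*k + c*k^2 (k = 0..n-1 unless given) and subtracts the
    fitted baseline; the residual is orthogonal to {1, k, k^2}.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("de-trend needs at least 3 points (quadratic fit)")
    kk = np.arange(x.size, dtype=float) if k is None else np.asarray(k, dtype=float)
    basis = np.vander(kk, 3, increasing=True)  # [1, k, k^2]
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return x - basis @ coef


def snvd(values: np.ndarray, k: np.ndarray | None = None, ddof: int = 1) -> np.ndarray:
    """SNV followed by de-trending (the usual combined correction)."""
    return detrend(snv(values, ddof=ddof), k=k)


def msc(
    matrix: np.ndarray,
    reference: np.ndarray | None = None,
    tol: float = 1e-8,
    return_coef: bool = False,
):
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is regressed on the reference (S_i = a_i * ref + b_i, by
    OLS) and replaced by (S_i - b_i) / a_i.  The reference defaults to the
    columnwise mean of ``matrix`` (which then needs >= 2 spectra).
    Correcting the reference itself returns the reference.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if reference is None:
        if X.shape[0] < 2:
            raise ValueError("defaulted MSC reference needs at least 2 spectra")
        reference = X.mean(axis=0)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ValueError("reference length does not match spectra")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom <= 0:
        raise ValueError("constant MSC reference")
    a = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.abs(a) < tol
    if np.any(bad):
        raise ValueError(
            f"MSC slope below tolerance for spectrum index {int(np.argmax(bad))}"
        )
    b = X.mean(axis=1) - a * ref.mean()
    corrected = (X - b[:, None]) / a[:, None]
    if return_coef:
        return corrected, a, b
    return corrected


def nw_smooth(values: np.ndarray, points: int) -> np.ndarray:
    """Running mean over an odd window; edges replicate-padded.

    ``points`` = 1 means no smoothing.  Length is preserved.
    """
    if points < 1 or points % 2 == 0:
        raise ValueError(f"smoothing points must be odd and >= 1, got {points}")
    x = np.asarray(values, dtype=float)
    if points == 1:
        return x.copy()
    m = (points - 1) // 2
    padded = np.pad(x, m, mode="edge")
    return np.convolve(padded, np.full(points, 1.0 / points), mode="valid")


def nw_derivative(values: np.ndarray, d: int, gap: int, s1: int = 1, s2: int = 1) -> np.ndarray:
    """Norris-Williams gap derivative with pre- and post-smoothing.

    First smooth with window ``s1``, then difference at distance ``gap``
    (first order: x[i+g] - x[i-g]; second order: x[i-g] - 2x[i] + x[i+g]),
    then smooth with ``s2``.  Length is preserved by replicate-padding
    before differencing.
    """
    if d not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if gap < 1:
        raise ValueError("gap must be >= 1")
    x = np.asarray(values, dtype=float)
    if x.size <= 2 * gap + max(s1, 1) - 1:
        raise ValueError(
            f"vector of length {x.size} too short for gap {gap} and smoothing {s1}"
        )
    xs = nw_smooth(x, s1)
    padded = np.pad(xs, gap, mode="edge")
    n = x.size
    lower = padded[:n]                 # x_{i-gap}
    upper = padded[2 * gap:]           # x_{i+gap}
    if d == 1:
        deriv = upper - lower
    else:
        deriv = lower - 2.0 * xs + upper
    return nw_smooth(deriv, s2)


def _apply_code(row: np.ndarray, code: tuple[int, int, int, int]) -> np.ndarray:
    d, g, s1, s2 = code
    if d == 0:
        return nw_smooth(nw_smooth(row, s1), s2)
    return nw_derivative(row, d, g, s1, s2)


class Pretreater:
    """Stateful applier of a :class:`PretreatmentSpec`.

    MSC needs a reference spectrum per segment; ``fit_transform`` estimates
    it from the training set (mean spectrum) and ``transform`` reuses the
    stored reference for new samples, so prediction never re-estimates it.
    """

    def __init__(self, spec: PretreatmentSpec):
        self.spec = spec
        self.msc_references_: dict[int, np.ndarray] = {}
        self._fitted = False

    def _segment_slices(self, grid: np.ndarray) -> list[np.ndarray]:
        masks = []
        covered = np.zeros(len(grid), dtype=bool)
        for lo, hi in self.spec.segments:
            mask = (grid >= lo) & (grid <= hi)
            if not mask.any():
                continue
            if mask.sum() < 3:
                raise ValueError(f"segment ({lo:g}, {hi:g}) covers fewer than 3 grid points")
            masks.append(mask)
            covered |= mask
        if not covered.all():
            wl = grid[~covered][0]
            raise ValueError(f"wavelength {wl:g} nm not covered by any segment")
        return masks

    def _run(self, spectra: SpectraSet, fit: bool) -> SpectraSet:
        if spectra.mode != "absorbance":
            raise ValueError("pre-treatment expects absorbance spectra")
        if not fit and self.spec.scatter == "msc" and not self._fitted:
            raise RuntimeError("MSC reference not fitted; call fit_transform first")
        out = np.empty_like(spectra.matrix)
        for seg_idx, mask in enumerate(self._segment_slices(spectra.grid)):
            block = spectra.matrix[:, mask]
            if self.spec.scatter == "snvd":
                block = np.vstack(
                    [snvd(row, ddof=self.spec.snv_ddof) for row in block]
                )
            elif self.spec.scatter == "msc":
                if fit:
                    self.msc_references_[seg_idx] = block.mean(axis=0)
                block = msc(block, reference=self.msc_references_[seg_idx])
            out[:, mask] = np.vstack([_apply_code(row, self.spec.code) for row in block])
        if fit:
            self._fitted = True
        result = spectra.copy()
        result.matrix = out
        return result

    def fit_transform(self, spectra: SpectraSet) -> SpectraSet:
        return self._run(spectra, fit=True)

    def transform(self, spectra: SpectraSet) -> SpectraSet:
        return self._run(spectra, fit=False)


def apply_pretreatment(spectra: SpectraSet, spec: PretreatmentSpec) -> SpectraSet:
    """One-shot pre-treatment (fits MSC references from ``spectra``)."""
    return Pretreater(spec).fit_transform(spectra)
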