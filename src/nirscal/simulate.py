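"""Synthetic Vis/NIR datasets with the structure calibration assumes.

The generator emulates fresh-root absorbance spectra: each constituent
(dry matter, total carotenoids, all-trans beta-carotene) contributes
Gaussian absorption bands linearly in its concentration, on top of which
every sample receives a multiplicative scatter factor, a quadratic
baseline drift and iid measurement noise -- exactly the interferences the
scatter corrections and derivatives are designed to remove.  Carotenoid
bands sit in the visible region (the 450 nm absorbance chemistry),
dry-matter bands near the 1450/1940 nm water-overtone and 2100 nm
carbohydrate regions.  Concentrations are truncated normals with
moments/bounds typical of fresh cassava roots (DMC ~ 36 +/- 4 %,
TCC ~ 15 +/- 8 ug/g, ATBC ~ 10 +/- 6 ug/g); TCC and ATBC are generated
with a configurable Gaussian-copula correlation since one is a component
of the other.

Everything is reproducible from the config seed.  :func:`plant_outliers`
corrupts copies of a dataset with gross reference errors and spectral
artifacts, returning truth labels, for outlier-elimination sensitivity
experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .spectra import SpectraSet

__all__ = [
    "Band",
    "TraitDist",
    "SyntheticConfig",
    "generate",
    "plant_outliers",
    "fresh_root_background",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band tied to a constituent."""

    center: float  # nm
    width: float  # nm (Gaussian sigma)
    constituent: str
    coefficient: float  # absorbance per concentration unit at band centre

    def profile(self, grid: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((grid - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class TraitDist:
    """Truncated-normal concentration distribution for one trait."""

    mean: float
    sd: float
    lo: float
    hi: float

    def ppf(self, u: np.ndarray) -> np.ndarray:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


#: Default constituent bands.  ``WATER`` is the derived complement
#: 100 - DMC (fresh roots are essentially water + dry matter): carotenoid
#: absorption sits in the visible, water at its 1450/1940 nm overtones,
#: dry matter (starch) near 2100 nm.  Coefficients are absorbance per
#: concentration unit, sized so water/dry-matter bands reach the few
#: tenths of an AU a wet-tissue spectrum shows.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band(450.0, 60.0, "TCC", 0.006),
    Band(488.0, 50.0, "ATBC", 0.006),
    Band(1450.0, 120.0, "WATER", 0.008),
    Band(1940.0, 140.0, "WATER", 0.012),
    Band(2100.0, 150.0, "DMC", 0.010),
)

#: constituents derivable from the drawn traits
_DERIVED = {"WATER": lambda conc: 100.0 - conc["DMC"]}


def fresh_root_background(grid: np.ndarray) -> np.ndarray:
    """Fixed background absorbance of the root matrix.

    A gentle upward slope plus broad invariant features (the 680 nm
    chlorophyll/pigment tail, the 970 nm water third overtone, residual
    structure at 1450/1940/2270 nm).  Real spectra vary around a large
    common structure like this; its presence keeps the per-segment SNV
    normalisation close to linear in the constituent signals.
    """

    def g(c, w):
        return np.exp(-0.5 * ((grid - c) / w) ** 2)

    return (
        0.45
        + 0.25 * (grid - grid[0]) / max(grid[-1] - grid[0], 1.0)
        + 0.3 * g(680.0, 80.0)
        + 0.35 * g(970.0, 80.0)
        + 0.3 * g(1450.0, 100.0)
        + 0.4 * g(1940.0, 120.0)
        + 0.2 * g(2270.0, 100.0)
    )

DEFAULT_TRAITS: dict[str, TraitDist] = {
    "DMC": TraitDist(36.16, 4.16, 20.14, 44.13),
    "TCC": TraitDist(14.91, 7.73, 0.70, 30.84),
    "ATBC": TraitDist(10.07, 5.86, 0.03, 21.02),
}


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_samples: int = 150
    grid: tuple[float, float, float] = (400.0, 2500.0, 2.0)  # lo, hi, step nm
    bands: tuple[Band, ...] = DEFAULT_BANDS
    constituent_dists: dict[str, TraitDist] = field(
        default_factory=lambda: dict(DEFAULT_TRAITS)
    )
    baseline_sd: tuple[float, float, float] = (0.02, 0.01, 0.005)  # a, b, c
    scatter_sd: float = 0.05  # SD of the multiplicative factor around 1
    noise_sd: float = 0.001  # absorbance units
    background: str | float = "fresh-root"  # fixed structure, or a constant level
    rho_tcc_atbc: float = 0.9  # copula correlation between TCC and ATBC
    seed: int = 0

    def __post_init__(self):
        lo, hi, step = self.grid
        if hi <= lo or step <= 0:
            raise ValueError("invalid grid")
        if self.noise_sd < 0 or self.scatter_sd < 0:
            raise ValueError("noise_sd and scatter_sd must be >= 0")
        for b in self.bands:
            if b.width <= 0:
                raise ValueError(f"band at {b.center} nm has non-positive width")
        for name, dist in self.constituent_dists.items():
            if dist.hi <= dist.lo or dist.sd <= 0:
                raise ValueError(f"invalid distribution for {name}")
            if name == "DMC" and not (0.0 < dist.lo and dist.hi < 100.0):
                raise ValueError("DMC bounds must lie inside (0, 100)")
            if name in ("TCC", "ATBC") and dist.lo < 0:
                raise ValueError(f"{name} cannot be negative")

    def wavelengths(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [asdict(b) for b in self.bands]
        d["constituent_dists"] = {k: asdict(v) for k, v in self.constituent_dists.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(Band(**b) for b in d["bands"])
        if "constituent_dists" in d:
            d["constituent_dists"] = {
                k: TraitDist(**v) for k, v in d["constituent_dists"].items()
            }
        if "grid" in d:
            d["grid"] = tuple(d["grid"])
        if "baseline_sd" in d:
            d["baseline_sd"] = tuple(d["baseline_sd"])
        return cls(**d)


def _draw_concentrations(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Truncated-normal traits; TCC/ATBC coupled by a Gaussian copula."""
    n = config.n_samples
    dists = config.constituent_dists
    out = {}
    paired = "TCC" in dists and "ATBC" in dists
    if paired:
        rho = config.rho_tcc_atbc
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal(np.zeros(2), cov, size=n)
        u = norm.cdf(z)
        out["TCC"] = dists["TCC"].ppf(u[:, 0])
        out["ATBC"] = dists["ATBC"].ppf(u[:, 1])
    for name, dist in dists.items():
        if paired and name in ("TCC", "ATBC"):
            continue
        out[name] = dist.ppf(rng.uniform(size=n))
    return pd.DataFrame(out)


def generate(config: SyntheticConfig) -> tuple[SpectraSet, pd.DataFrame]:
    """Draw a synthetic (spectra, reference-table) pair.

    Clean absorbance is the linear constituent->band mixture; each sample
    is then transformed as ``scatter_factor * clean + quadratic baseline
    + iid noise``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.wavelengths()
    conc = _draw_concentrations(config, rng)
    levels = conc.copy()
    if "DMC" in conc.columns:
        levels["WATER"] = _DERIVED["WATER"](conc)

    for band in config.bands:
        if band.constituent not in levels.columns:
            raise ValueError(f"band references unknown constituent {band.constituent!r}")
        if not (grid[0] <= band.center <= grid[-1]):
            warnings.warn(
                f"band at {band.center:g} nm lies outside the grid", stacklevel=2
            )

    if config.background == "fresh-root":
        base = fresh_root_background(grid)
    else:
        base = np.full(grid.size, float(config.background))
    clean = np.tile(base, (config.n_samples, 1))
    for band in config.bands:
        clean += np.outer(
            band.coefficient * levels[band.constituent].to_numpy(), band.profile(grid)
        )

    scatter = 1.0 + config.scatter_sd * rng.standard_normal(config.n_samples)
    scatter = np.clip(scatter, 0.1, None)
    u = (grid - grid[0]) / (grid[-1] - grid[0])  # normalised position in [0, 1]
    abc = rng.standard_normal((config.n_samples, 3)) * np.asarray(config.baseline_sd)
    baseline = abc[:, [0]] + abc[:, [1]] * u + abc[:, [2]] * u**2
    noise = config.noise_sd * rng.standard_normal(clean.shape)

    matrix = scatter[:, None] * clean + baseline + noise
    ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    spectra = SpectraSet(sample_ids=ids, grid=grid, matrix=matrix, mode="absorbance")
    refs = pd.concat([pd.Series(ids, name="sample_id"), conc], axis=1)
    return spectra, refs


def plant_outliers(
    spectra: SpectraSet,
    refs: pd.DataFrame,
    n_ref_errors: int = 0,
    n_spectral_errors: int = 0,
    magnitude: float = 5.0,
    trait: str = "DMC",
    seed: int = 0,
) -> tuple[SpectraSet, pd.DataFrame, dict[str, list[str]]]:
    """Corrupt copies of a dataset and return truth labels.

    Reference errors add ``+/- magnitude * SD(y)`` to the trait value of
    the chosen samples (gross lab errors -> t-outliers).  Spectral errors
    add a large offset, slope and a spurious narrow band; the band
    survives scatter correction, so the sample lands far from the
    calibration cloud (-> H-outlier).
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    total = n_ref_errors + n_spectral_errors
    if total > len(spectra):
        raise ValueError("more corruptions than samples")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(spectra), size=total, replace=False)
    ref_idx, spec_idx = chosen[:n_ref_errors], chosen[n_ref_errors:]

    out_refs = refs.copy()
    sd_y = out_refs[trait].std(ddof=1)
    for i in ref_idx:
        sign = rng.choice([-1.0, 1.0])
        out_refs.loc[out_refs.index[i], trait] += sign * magnitude * sd_y

    out_spectra = spectra.copy()
    grid = spectra.grid
    u = (grid - grid[0]) / (grid[-1] - grid[0])
    for i in spec_idx:
        center = rng.uniform(grid[0] + 100, grid[-1] - 100)
        artifact = 0.5 + 0.3 * u + 0.5 * np.exp(-0.5 * ((grid - center) / 15.0) ** 2)
        out_spectra.matrix[i] = out_spectra.matrix[i] + artifact

    labels = {
        "reference": [spectra.sample_ids[i] for i in ref_idx],
        "spectral": [spectra.sample_ids[i] for i in spec_idx],
    }
    return out_spectra, out_refs, labels
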