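"""Reference wet-chemistry conversions and the reference-value table.

Closed-form conversions used to produce the reference ("wet-lab") values
a spectral calibration is trained against:

* total carotenoid content (TCC) from the absorbance of a petroleum-ether
  extract at 450 nm,
* dry matter content (DMC) from oven fresh/dry weights,
* specific gravity (SG) from in-air / in-water weights, and the linear
  SG -> DMC conversions used by breeding programs.

The reference table itself is a pandas DataFrame with a ``sample_id``
column and one column per trait (DMC %, TCC and ATBC in ug/g fresh
weight, SG unitless); :func:`read_reference_table` validates the physical
ranges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "A1CM_BETA_CAROTENE_PETROLEUM_ETHER",
    "SG_DMC_COEFFICIENTS",
    "tcc_from_absorbance",
    "dmc_from_sg",
    "sg_from_weights",
    "dmc_oven",
    "read_reference_table",
    "write_reference_table",
]

#: 1%, 1 cm absorption coefficient of beta-carotene in petroleum ether
A1CM_BETA_CAROTENE_PETROLEUM_ETHER: float = 2592.0

#: named (slope, intercept) sets for the linear SG -> DMC conversion:
#: "published" is the relationship long used by breeding programs,
#: "nrcri_2016" the refit on the NRCRI 2016 samples.
SG_DMC_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "published": (158.3, -142.0),
    "nrcri_2016": (67.33, -37.03),
}


def tcc_from_absorbance(
    absorbance: float,
    volume_ml: float,
    weight_g: float,
    a1cm: float = A1CM_BETA_CAROTENE_PETROLEUM_ETHER,
) -> float:
    """Total carotenoids (ug/g): A * V(mL) * 1e4 / (A1cm * weight(g))."""
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    if volume_ml <= 0 or weight_g <= 0:
        raise ValueError("volume and sample weight must be positive")
    return absorbance * volume_ml * 1e4 / (a1cm * weight_g)


def sg_from_weights(w_air: float, w_water: float) -> float:
    """Specific gravity = w_air / (w_air - w_water)."""
    if w_water < 0 or w_air <= w_water:
        raise ValueError("need w_air > w_water >= 0 (non-physical weights)")
    return w_air / (w_air - w_water)


def dmc_from_sg(sg, coefficients: str | tuple[float, float] = "published"):
    """Linear SG -> DMC (%) conversion, DMC = slope*SG + intercept.

    ``coefficients`` is a named set from :data:`SG_DMC_COEFFICIENTS`
    (default the published 158.3 / -142) or an explicit (slope,
    intercept) pair.
    """
    sg = np.asarray(sg, dtype=float)
    if np.any(sg <= 0):
        raise ValueError("specific gravity must be positive")
    if isinstance(coefficients, str):
        slope, intercept = SG_DMC_COEFFICIENTS[coefficients]
    else:
        slope, intercept = coefficients
    out = slope * sg + intercept
    return float(out) if out.ndim == 0 else out


def dmc_oven(fresh_w, dry_w) -> float:
    """Oven DMC (%) = 100 * dry / fresh; replicate pairs are averaged.

    Scalars give one measurement; equal-length sequences are treated as
    replicate pairs and the mean DMC is returned.
    """
    fresh = np.atleast_1d(np.asarray(fresh_w, dtype=float))
    dry = np.atleast_1d(np.asarray(dry_w, dtype=float))
    if fresh.shape != dry.shape:
        raise ValueError("fresh and dry weights must pair up")
    if np.any(fresh <= 0) or np.any(dry <= 0):
        raise ValueError("weights must be positive")
    if np.any(dry > fresh):
        raise ValueError("dry weight exceeds fresh weight")
    return float(np.mean(100.0 * dry / fresh))


_TRAIT_BOUNDS = {
    "DMC": (0.0, 100.0),
    "TCC": (0.0, None),
    "ATBC": (0.0, None),
    "SG": (0.0, None),
}


def read_reference_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a per-sample trait table (sample_id + trait columns).

    Validates physical ranges: DMC in (0, 100), carotenoids >= 0, SG > 0.
    Returns a DataFrame with a string ``sample_id`` column.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if df.columns[0] != "sample_id":
        df = df.rename(columns={df.columns[0]: "sample_id"})
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in reference table")
    validate_reference_table(df)
    return df


def validate_reference_table(df: pd.DataFrame) -> None:
    for trait, (lo, hi) in _TRAIT_BOUNDS.items():
        if trait not in df.columns:
            continue
        col = df[trait].dropna()
        strict = trait in ("DMC", "SG")
        if (strict and np.any(col <= lo)) or (not strict and np.any(col < lo)):
            raise ValueError(f"{trait} values must be {'>' if strict else '>='} {lo}")
        if hi is not None and np.any(col >= hi):
            raise ValueError(f"{trait} values must be < {hi}")


def write_reference_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
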