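"""End-to-end experiment orchestration over the library modules.

Each function here composes the building blocks (simulation, splitting,
calibration, prediction, statistics) into one of the standard
experiments:

* :func:`run_simulate` — write a synthetic spectra + reference dataset.
* :func:`compare_pretreatments` — the scatter-correction x derivative
  grid (eight treatments vs none), R2c/R2cv per trait with per-treatment
  averages.
* :func:`split_calibrate_validate` — PCA/k-means calibration sampling,
  calibration on one side, independent validation on the other, in both
  directions (large set predicts small, and conversely), plus averages.
* :func:`dmc_method_comparison` — the 4x4 Pearson matrix over DMC
  phenotyping methods (NIRS on intact roots, NIRS on mashed roots, oven
  drying, specific gravity) and the SG -> oven-DMC regression.

There is no hidden state: every function takes its inputs explicitly and
returns plain DataFrames/objects, so pipeline output equals direct
module calls.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import mpls, sampling, simulate, stats
from .chem import write_reference_table
from .mpls import OutlierLimits, calibrate, predict
from .sampling import naes_split, subset
from .spectra import SpectraSet, write_spectra
from .stats import linreg, pearson, validation_stats

__all__ = [
    "DEFAULT_PRETREATMENTS",
    "run_simulate",
    "compare_pretreatments",
    "split_calibrate_validate",
    "dmc_method_comparison",
]

log = logging.getLogger("nirscal")

#: the nine-treatment comparison grid: no treatment, and the two scatter
#: corrections crossed with four derivative/smoothing codes
DEFAULT_PRETREATMENTS: tuple[str, ...] = (
    "NONE+0011",
    "SNVD+1111",
    "SNVD+1551",
    "SNVD+2111",
    "SNVD+2551",
    "MSC+1111",
    "MSC+1551",
    "MSC+2111",
    "MSC+2551",
)


def run_simulate(config: simulate.SyntheticConfig, outdir) -> dict:
    """Generate one synthetic dataset and write spectra/reference CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spectra, refs = simulate.generate(config)
    write_spectra(spectra, outdir / "spectra.csv")
    write_reference_table(refs, outdir / "reference.csv")
    with open(outdir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    return {
        "spectra": outdir / "spectra.csv",
        "reference": outdir / "reference.csv",
        "config": outdir / "config.json",
        "n_samples": len(spectra),
        "n_wavelengths": len(spectra.grid),
    }


def compare_pretreatments(
    spectra: SpectraSet,
    refs: pd.DataFrame,
    traits,
    pretreatments=DEFAULT_PRETREATMENTS,
    limits: OutlierLimits = OutlierLimits(),
    max_lv: int = 16,
) -> pd.DataFrame:
    """R2c/R2cv for every (pre-treatment, trait) cell, plus averages.

    A failing cell is logged and reported as NA; the grid continues.
    Returns a tidy frame with columns pretreatment, trait, n_used, n_lv,
    R2c, R2cv, SECV, RPD, and per-pretreatment average rows
    (trait = "AV.").
    """
    rows = []
    for pt in pretreatments:
        for trait in traits:
            try:
                model = calibrate(
                    spectra, refs, trait, pretreatment=pt, limits=limits, max_lv=max_lv
                )
                s = model.stats
                rows.append(
                    dict(
                        pretreatment=pt,
                        trait=trait,
                        n_used=s["n_used"],
                        n_lv=model.n_lv,
                        R2c=s["R2c"],
                        R2cv=s["R2cv"],
                        SECV=s["SECV"],
                        RPD=s["RPD"],
                    )
                )
            except Exception as exc:  # one bad cell never aborts the grid
                log.warning("cell (%s, %s) failed: %s", pt, trait, exc)
                rows.append(
                    dict(
                        pretreatment=pt,
                        trait=trait,
                        n_used=np.nan,
                        n_lv=np.nan,
                        R2c=np.nan,
                        R2cv=np.nan,
                        SECV=np.nan,
                        RPD=np.nan,
                    )
                )
    table = pd.DataFrame(rows)
    averages = (
        table.groupby("pretreatment", sort=False)[["R2c", "R2cv"]]
        .mean()
        .reset_index()
        .assign(trait="AV.")
    )
    return pd.concat([table, averages], ignore_index=True)


def split_calibrate_validate(
    spectra: SpectraSet,
    refs: pd.DataFrame,
    trait: str,
    k: int,
    pretreatment: str = "SNVD+1111",
    limits: OutlierLimits = OutlierLimits(),
    max_lv: int = 16,
    seed: int = 0,
) -> dict:
    """naes split, then calibrate/validate in both directions.

    Scenario 1 trains on the (larger) calibration side and predicts the
    validation side; scenario 2 swaps the roles.  Returns the split, both
    models, both :class:`~nirscal.stats.ValidationResult` objects and
    their fieldwise average.
    """
    split = naes_split(spectra, k=k, seed=seed)
    cal = subset(spectra, split.calibration_ids)
    val = subset(spectra, split.validation_ids)

    def _one(train, test):
        model = calibrate(
            train, refs, trait, pretreatment=pretreatment, limits=limits, max_lv=max_lv
        )
        ref_map = refs.set_index("sample_id")[trait].dropna()
        ids = [sid for sid in test.sample_ids if sid in ref_map.index]
        pred = predict(model, subset(test, ids))
        obs = ref_map.loc[ids].to_numpy()
        return model, validation_stats(pred, obs)

    model_1, val_1 = _one(cal, val)
    model_2, val_2 = _one(val, cal)
    avg = {
        f: (getattr(val_1, f) + getattr(val_2, f)) / 2.0
        for f in ("SEP", "SEP_C", "bias", "R2p", "SD", "RPD_val")
    }
    return {
        "split": split,
        "scenario1": {"model": model_1, "validation": val_1},
        "scenario2": {"model": model_2, "validation": val_2},
        "average": avg,
    }


def dmc_method_comparison(table: pd.DataFrame) -> dict:
    """Compare DMC phenotyping methods on one set of samples.

    ``table`` must hold the four per-sample DMC columns ``NIRS_I``
    (intact-root NIRS), ``NIRS_M`` (mashed-root NIRS), ``DM_V`` (oven)
    and ``DM_G`` (specific-gravity derived), plus optionally ``SG``
    itself for the SG -> oven regression.  Returns the 4x4 Pearson
    matrix and, when SG is present, the (slope, intercept, R2) of
    oven DMC on SG.
    """
    methods = ["NIRS_I", "NIRS_M", "DM_V", "DM_G"]
    missing = [m for m in methods if m not in table.columns]
    if missing:
        raise KeyError(f"missing DMC method column(s): {missing}")
    sub = table[methods].dropna()
    mat = pd.DataFrame(np.eye(4), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            r = pearson(sub[a], sub[b])
            mat.loc[a, b] = mat.loc[b, a] = r
    out = {"correlations": mat}
    if "SG" in table.columns:
        sg_sub = table[["SG", "DM_V"]].dropna()
        out["sg_regression"] = linreg(sg_sub["SG"], sg_sub["DM_V"])
    return out
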