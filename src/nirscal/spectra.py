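"""Spectral containers and I/O on explicit wavelength grids.

A portable Vis/NIR instrument records reflectance R on a dense nanometre
grid (here typically 350-2500 nm at 1 nm, later trimmed to 400-2500 nm at
2 nm).  Calibration consumes apparent absorbance log10(1/R), one averaged
spectrum per sample.  This module holds the two containers -- a single
:class:`Spectrum` and an aligned :class:`SpectraSet` matrix -- together
with the CSV readers/writers, the absorbance transform, replicate
averaging and exact grid subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraSet",
    "read_spectra",
    "write_spectra",
    "to_absorbance",
    "average_replicates",
    "trim_resample",
]

#: recognised non-wavelength columns in wide CSV files, in canonical order
_ID_COLUMNS = ("sample_id", "replicate_id", "scan_position")


class SpectraParseError(ValueError):
    """Raised when a spectra file violates the expected layout."""


@dataclass(frozen=True)
class Spectrum:
    """One spectral trace with sample/replicate identity.

    ``mode`` is ``"reflectance"`` (R, in (0, 1]) or ``"absorbance"``
    (log10(1/R)).  Wavelengths are strictly increasing nanometres.
    """

    sample_id: str
    wavelengths: np.ndarray
    values: np.ndarray
    mode: str = "absorbance"
    replicate_id: str = ""
    scan_position: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if len(wl) != len(vals):
            raise ValueError(
                f"length mismatch: {len(wl)} wavelengths vs {len(vals)} values"
            )
        if len(wl) > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.mode not in ("reflectance", "absorbance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "reflectance" and (np.any(vals <= 0) or np.any(vals > 1)):
            raise ValueError("reflectance values must lie in (0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)


@dataclass
class SpectraSet:
    """Aligned matrix of spectra sharing one wavelength grid.

    ``matrix`` is samples x wavelengths.  ``replicate_ids`` is empty once
    replicates have been averaged, after which ``sample_ids`` are unique.
    """

    sample_ids: list[str]
    grid: np.ndarray
    matrix: np.ndarray
    mode: str = "absorbance"
    replicate_ids: list[str] = field(default_factory=list)
    scan_positions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape != (len(self.sample_ids), len(self.grid)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.sample_ids)} ids x {len(self.grid)} wavelengths"
            )
        if len(self.grid) > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if self.mode not in ("reflectance", "absorbance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.replicate_ids and len(self.replicate_ids) != len(self.sample_ids):
            raise ValueError("replicate_ids length mismatch")
        if not self.replicate_ids and len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique once replicates are averaged")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(
            sample_id=self.sample_ids[i],
            wavelengths=self.grid,
            values=self.matrix[i],
            mode=self.mode,
            replicate_id=self.replicate_ids[i] if self.replicate_ids else "",
            scan_position=self.scan_positions[i] if self.scan_positions else "",
        )

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            sample_ids=list(self.sample_ids),
            grid=self.grid.copy(),
            matrix=self.matrix.copy(),
            mode=self.mode,
            replicate_ids=list(self.replicate_ids),
            scan_positions=list(self.scan_positions),
        )


def read_spectra(
    path,
    mode: str = "absorbance",
    layout: str = "wide",
    sep: str | None = None,
) -> SpectraSet:
    """Read a spectra table into a :class:`SpectraSet`.

    Wide layout: first column ``sample_id``, optional ``replicate_id`` /
    ``scan_position`` columns, then one numeric-named column per
    wavelength (nm).  Long layout: columns ``sample_id``, optional
    ``replicate_id``, ``wavelength``, ``value``.  Wavelength columns out
    of order are sorted (values reordered to match).
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={c: str for c in _ID_COLUMNS})
    if layout == "long":
        df = _long_to_wide(df)
    if df.columns[0] != "sample_id":
        df = df.rename(columns={df.columns[0]: "sample_id"})

    id_cols = [c for c in _ID_COLUMNS if c in df.columns]
    wl_cols = [c for c in df.columns if c not in id_cols]
    try:
        grid = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraParseError(f"non-numeric wavelength column: {exc}") from exc

    order = np.argsort(grid)
    grid = grid[order]
    wl_cols = [wl_cols[i] for i in order]
    if len(grid) > 1 and np.any(np.diff(grid) <= 0):
        raise SpectraParseError("duplicate wavelength columns")

    values = (
        df[wl_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    )
    bad = np.argwhere(np.isnan(values))
    if bad.size:
        r, c = bad[0]
        raise SpectraParseError(
            f"non-numeric or missing cell at row {r} ({df['sample_id'].iloc[r]!r}), "
            f"wavelength {grid[c]:g}"
        )

    sample_ids = df["sample_id"].astype(str).tolist()
    replicate_ids = (
        df["replicate_id"].astype(str).tolist() if "replicate_id" in df else []
    )
    keys = list(zip(sample_ids, replicate_ids)) if replicate_ids else sample_ids
    seen: set = set()
    for row, key in enumerate(keys):
        if key in seen:
            raise SpectraParseError(f"duplicate (sample, replicate) key {key!r} at row {row}")
        seen.add(key)
    if not replicate_ids and len(set(sample_ids)) != len(sample_ids):
        raise SpectraParseError("duplicate sample_id without replicate_id column")

    return SpectraSet(
        sample_ids=sample_ids,
        grid=grid,
        matrix=values,
        mode=mode,
        replicate_ids=replicate_ids,
        scan_positions=(
            df["scan_position"].astype(str).tolist() if "scan_position" in df else []
        ),
    )


def _long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "wavelength", "value"}
    if not required <= set(df.columns):
        raise SpectraParseError(
            f"long layout needs columns {sorted(required)}, got {list(df.columns)}"
        )
    index = [c for c in ("sample_id", "replicate_id", "scan_position") if c in df.columns]
    wide = df.pivot_table(
        index=index, columns="wavelength", values="value", aggfunc="first"
    )
    wide.columns = [str(c) for c in wide.columns]
    return wide.reset_index()


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write a wide CSV (ids, then one column per wavelength in nm)."""
    data = {"sample_id": spectra.sample_ids}
    if spectra.replicate_ids:
        data["replicate_id"] = spectra.replicate_ids
    if spectra.scan_positions:
        data["scan_position"] = spectra.scan_positions
    values = pd.DataFrame(
        spectra.matrix, columns=[f"{wl:g}" for wl in spectra.grid]
    )
    pd.concat([pd.DataFrame(data), values], axis=1).to_csv(path, index=False)


def to_absorbance(s):
    """log10(1/R) transform; idempotent on absorbance input.

    Accepts a :class:`Spectrum` or a :class:`SpectraSet`.
    """
    if s.mode == "absorbance":
        return s
    if isinstance(s, Spectrum):
        if np.any(s.values <= 0):
            raise ValueError("reflectance must be > 0 for log10(1/R)")
        return replace(s, values=np.log10(1.0 / s.values), mode="absorbance")
    if np.any(s.matrix <= 0):
        raise ValueError("reflectance must be > 0 for log10(1/R)")
    out = s.copy()
    out.matrix = np.log10(1.0 / s.matrix)
    out.mode = "absorbance"
    return out


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """One spectrum per sample: columnwise arithmetic mean over replicates.

    Sample order follows first appearance.  A set without replicate ids is
    returned unchanged (already one row per sample).
    """
    if not spectra.replicate_ids:
        return spectra
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(spectra.sample_ids):
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(i)
    matrix = np.vstack([spectra.matrix[groups[sid]].mean(axis=0) for sid in order])
    return SpectraSet(sample_ids=order, grid=spectra.grid, matrix=matrix, mode=spectra.mode)


def trim_resample(spectra: SpectraSet, lo: float, hi: float, step: float) -> SpectraSet:
    """Subsample onto the grid lo, lo+step, ..., hi (exact points only).

    Pure subsampling, no interpolation: every requested wavelength must be
    present in the source grid.  E.g. a 350-2500 nm @ 1 nm grid (2151
    points) trimmed with (400, 2500, 2) yields 1051 points.
    """
    if hi < lo or step <= 0:
        raise ValueError("need lo <= hi and step > 0")
    n_pts = int(round((hi - lo) / step)) + 1
    target = lo + step * np.arange(n_pts)
    idx = np.searchsorted(spectra.grid, target)
    ok = (idx < len(spectra.grid)) & np.isclose(
        spectra.grid[np.minimum(idx, len(spectra.grid) - 1)], target
    )
    if not np.all(ok):
        missing = target[~ok][0]
        raise ValueError(f"wavelength {missing:g} nm not present in source grid")
    out = spectra.copy()
    out.grid = spectra.grid[idx]
    out.matrix = spectra.matrix[:, idx]
    return out
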