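"""Calibration/validation splitting by PCA + k-means cluster sampling.

The selection strategy (the "naes" algorithm of the prospectr tradition):
run PCA on the centred spectra and keep the smallest number of components
explaining at least a target fraction of the variance (99% by default);
k-means the scores into as many clusters as desired calibration samples;
take the sample nearest each cluster centre as a calibration sample and
leave the rest for validation.  This yields a calibration set spread over
the spectral space rather than a random draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .spectra import SpectraSet

__all__ = ["SplitResult", "naes_split"]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/validation partition of the sample ids."""

    calibration_ids: list[str]
    validation_ids: list[str]
    n_components: int
    seed: int

    def as_frame(self):
        import pandas as pd

        rows = [(sid, "cal") for sid in self.calibration_ids] + [
            (sid, "val") for sid in self.validation_ids
        ]
        return pd.DataFrame(rows, columns=["sample_id", "set"])


def naes_split(
    spectra: SpectraSet,
    k: int,
    variance_target: float = 0.99,
    kmeans_iters: int = 1000,
    seed: int = 0,
) -> SplitResult:
    """Select ``k`` calibration samples by PCA + k-means centre sampling.

    Deterministic given ``seed``.  Ties in nearest-to-centroid go to the
    lowest sample index.
    """
    n = len(spectra)
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n (k={k}, n={n})")
    # PCA on centred (not autoscaled) absorbance
    pca = PCA(n_components=min(n - 1, spectra.matrix.shape[1]))
    scores = pca.fit_transform(spectra.matrix)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_target) + 1)
    n_comp = min(n_comp, scores.shape[1])
    scores = scores[:, :n_comp]

    km = KMeans(
        n_clusters=k,
        n_init=1,
        max_iter=kmeans_iters,
        random_state=seed,
    ).fit(scores)
    labels = km.labels_

    cal_idx = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:  # sklearn re-assigns empty clusters, but guard anyway
            continue
        d = np.linalg.norm(scores[members] - km.cluster_centers_[c], axis=1)
        # argmin returns the first minimum -> lowest index wins ties
        cal_idx.append(int(members[np.argmin(d)]))
    cal_idx = sorted(set(cal_idx))
    cal_set = set(cal_idx)
    return SplitResult(
        calibration_ids=[spectra.sample_ids[i] for i in cal_idx],
        validation_ids=[
            sid for i, sid in enumerate(spectra.sample_ids) if i not in cal_set
        ],
        n_components=n_comp,
        seed=seed,
    )


def subset(spectra: SpectraSet, ids) -> SpectraSet:
    """Row-subset a SpectraSet by sample id, preserving the given order."""
    pos = {sid: i for i, sid in enumerate(spectra.sample_ids)}
    idx = [pos[sid] for sid in ids]
    return SpectraSet(
        sample_ids=list(ids),
        grid=spectra.grid,
        matrix=spectra.matrix[idx],
        mode=spectra.mode,
    )
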