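"""Principal component analysis of a complete-case genotype matrix.

Input is the thinned (one SNP per contig), no-missing-data dosage
matrix.  Sites are mean-centered (no variance scaling by default) and
the sample covariance is eigendecomposed; each axis reports the
fraction of total variance it carries.  Axis signs are arbitrary in
PCA, so for reproducibility each axis is flipped to make its
largest-magnitude site loading positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import GenotypeDataset


@dataclass
class PcaResult:
    sample_ids: list[str]
    sample_scores: np.ndarray  # (n_samples, n_axes)
    variance_fraction: np.ndarray  # per axis, non-increasing, sums to <= 1
    loadings: np.ndarray  # (n_axes, n_sites)
    n_sites: int
    n_axes: int

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.sample_scores, index=self.sample_ids, columns=cols)


def genotype_pca(
    dataset: GenotypeDataset, n_axes: int = 10, scale: bool = False
) -> PcaResult:
    """PCA of the dosage matrix; requires a complete-case dataset.

    Raises if any genotype is missing (run ``subset_no_missing`` first),
    if there are fewer than 2 samples, or if every site is monomorphic.
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples for PCA")
    if np.any(dataset.dosage < 0):
        raise ValueError(
            "dataset contains missing genotypes; apply subset_no_missing first"
        )
    X = dataset.dosage.T.astype(float)  # samples x sites
    sd = X.std(axis=0)
    if not np.any(sd > 0):
        raise ValueError("all sites are monomorphic; PCA undefined")
    if scale:
        X = X[:, sd > 0] / sd[sd > 0]
    k = min(n_axes, dataset.n_samples - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for axis in range(k):  # deterministic sign: top |loading| positive
        j = int(np.argmax(np.abs(loadings[axis])))
        if loadings[axis, j] < 0:
            loadings[axis] *= -1.0
            scores[:, axis] *= -1.0
    return PcaResult(
        sample_ids=list(dataset.sample_ids),
        sample_scores=scores,
        variance_fraction=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        n_sites=X.shape[1],
        n_axes=k,
    )
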