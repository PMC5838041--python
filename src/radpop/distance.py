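"""Geographic and genetic distance matrices and Mantel tests.

Geographic distances are great-circle (haversine) kilometres on a
sphere of radius 6371 km.  Genetic distances are uncorrected
p-distances computed on genotype dosages with pairwise deletion: for
diploid dosages the per-site difference is |d1 - d2| / 2, so a
heterozygote against a homozygote counts one half.  Because samples
collected at one locality are pseudoreplicates for an
isolation-by-distance question, sample-level genetic distances are
averaged between localities before testing.

The Mantel test correlates the upper triangles of two labeled distance
matrices and builds the null by simultaneous row/column permutation of
one matrix, with the +1-corrected permutation p-value
``p = (1 + #{r* >= r_obs}) / (1 + n_permutations)`` (one-tailed
"greater", the isolation-by-distance direction, by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

from .io import GenotypeDataset, PopulationMap

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Labeled symmetric non-negative matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    kind: str = "user_supplied"  # geographic_km | genetic_p | user_supplied

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        if set(labels) != set(self.labels):
            raise ValueError("label sets differ")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.kind
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "user_supplied"):
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), kind)


@dataclass
class MantelResult:
    r_observed: float
    p_value: float
    n_permutations: int
    tail: str


def haversine_matrix(
    coords: list[tuple[float, float]], labels: list[str] | None = None
) -> DistanceMatrix:
    """Great-circle distance matrix (km) from (lat, lon) decimal degrees."""
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("coords must be (lat, lon) pairs")
    if np.any(np.abs(arr[:, 0]) > 90) or np.any(np.abs(arr[:, 1]) > 180):
        raise ValueError("coordinates out of range (lat in ±90, lon in ±180)")
    km = haversine_distances(np.radians(arr)) * EARTH_RADIUS_KM
    np.fill_diagonal(km, 0.0)
    km = (km + km.T) / 2.0  # enforce exact symmetry against fp jitter
    if labels is None:
        labels = [f"loc{i + 1}" for i in range(arr.shape[0])]
    return DistanceMatrix(list(labels), km, kind="geographic_km")


def p_distance_matrix(
    dataset: GenotypeDataset, deletion: str = "pairwise"
) -> DistanceMatrix:
    """Uncorrected p-distance between samples on genotype dosages.

    ``deletion="pairwise"`` (default) uses, per pair, the sites called
    in both samples; ``"complete"`` restricts all pairs to sites called
    in every sample.
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = dataset.dosage.astype(float)
    d[dataset.dosage < 0] = np.nan
    if deletion == "complete":
        keep = ~np.isnan(d).any(axis=1)
        d = d[keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = dataset.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    "no shared called sites between "
                    f"{dataset.sample_ids[i]!r} and {dataset.sample_ids[j]!r}"
                )
            out[i, j] = out[j, i] = (
                np.abs(d[both, i] - d[both, j]).sum() / (2.0 * m)
            )
    return DistanceMatrix(list(dataset.sample_ids), out, kind="genetic_p")


def average_by_locality(
    dm: DistanceMatrix, popmap: PopulationMap
) -> DistanceMatrix:
    """Collapse a sample-level matrix to mean between-locality distances."""
    groups: dict[str, list[int]] = {}
    for pop in popmap.populations:
        idx = [dm.labels.index(s) for s in popmap.samples_for(pop) if s in dm.labels]
        if idx:
            groups[pop] = idx
        else:
            warnings.warn(f"locality {pop!r} has no samples in the matrix; dropped")
    pops = list(groups)
    out = np.zeros((len(pops), len(pops)))
    for i, p in enumerate(pops):
        for j in range(i + 1, len(pops)):
            q = pops[j]
            block = dm.values[np.ix_(groups[p], groups[q])]
            out[i, j] = out[j, i] = float(block.mean())
    return DistanceMatrix(pops, out, kind=dm.kind)


def mantel_test(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_permutations: int = 999,
    tail: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Permutation Mantel test between two labeled distance matrices.

    ``dm_b`` is reordered to ``dm_a``'s labels if the label sets match.
    The observed statistic is the Pearson correlation of the upper
    triangles; the null permutes rows and columns of ``dm_b`` jointly.
    """
    if dm_a.labels != dm_b.labels:
        dm_b = dm_b.reorder(dm_a.labels)
    n = dm_a.n
    if n < 3:
        raise ValueError("need at least 3 localities for a Mantel test")
    if tail not in ("greater", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    iu = np.triu_indices(n, 1)
    x = dm_a.values[iu]
    y = dm_b.values[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = dm_b.values[np.ix_(perm, perm)][iu]
        r_star = float(np.mean(xc * (yp - yp.mean()) / yp.std()))
        if tail == "greater":
            hits += r_star >= r_obs
        else:
            hits += abs(r_star) >= abs(r_obs)
    p = (1 + hits) / (1 + n_permutations)
    return MantelResult(
        r_observed=r_obs, p_value=float(p), n_permutations=n_permutations, tail=tail
    )
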