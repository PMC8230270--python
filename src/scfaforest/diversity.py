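"""Alpha diversity, beta-diversity distance matrices and NMDS ordination.

Shannon entropy (natural log by default, switchable base) and the
Gini-Simpson index describe within-sample diversity; Bray-Curtis
dissimilarity on read counts and the presence/absence Jaccard distance
describe between-sample diversity.  Non-metric multidimensional scaling
minimises Kruskal stress-1 over several seeded restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .tables import AbundanceTable

METRICS = ("bray_curtis", "jaccard")


def _validated(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D counts vector")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return x


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log unless ``base`` given)."""
    x = _validated(counts)
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero counts vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson(counts) -> float:
    """Gini-Simpson index 1 - sum p_i^2."""
    x = _validated(counts)
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero counts vector")
    p = x / total
    return float(1.0 - (p**2).sum())


def _pair(u, v) -> tuple[np.ndarray, np.ndarray]:
    a, b = _validated(u), _validated(v)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return a, b


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(u, v)) / (sum u + sum v)."""
    a, b = _pair(u, v)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / denom)


def jaccard(u, v) -> float:
    """Presence/absence Jaccard distance 1 - |A & B| / |A | B|."""
    a, b = _pair(u, v)
    sa, sb = a > 0, b > 0
    union = (sa | sb).sum()
    if union == 0:
        raise ValueError("both supports are empty")
    return float(1.0 - (sa & sb).sum() / union)


def alpha_diversity(
    table: AbundanceTable, metric: str = "shannon", base: float | None = None
) -> pd.Series:
    """Per-sample alpha diversity over the table's taxa."""
    if metric == "shannon":
        values = [shannon(row, base=base) for row in table.counts.to_numpy()]
    elif metric == "simpson":
        values = [simpson(row) for row in table.counts.to_numpy()]
    else:
        raise ValueError(f"unknown alpha metric {metric!r}")
    return pd.Series(values, index=table.sample_ids, name=metric)


def distance_matrix(
    table: AbundanceTable, metric: str = "bray_curtis", relative: bool = False
) -> DistanceMatrix:
    """All-pairs distances between samples (Bray-Curtis on counts, Jaccard on presence).

    ``relative=True`` converts counts to within-sample relative abundances
    first (Bray-Curtis only; Jaccard depends on presence alone).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    x = table.counts.to_numpy(dtype=float)
    if metric == "bray_curtis":
        if relative:
            x = x / x.sum(axis=1, keepdims=True)
        condensed = pdist(x, metric="braycurtis")
    else:
        condensed = pdist(x > 0, metric="jaccard")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def kruskal_stress(distances: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against target dissimilarities.

    Disparities are the isotonic (primary tie approach) regression of the
    configuration distances on the target dissimilarities.
    """
    d_config = pdist(coords)
    d_target = squareform(np.asarray(distances), checks=False)
    # primary approach to ties: within tied target blocks, order by config distance
    order = np.lexsort((d_config, d_target))
    iso = IsotonicRegression()
    disparities = np.empty_like(d_config)
    disparities[order] = iso.fit_transform(np.arange(len(order)), d_config[order])
    denom = (d_config**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_config - disparities) ** 2).sum() / denom))


@dataclass
class Ordination:
    """NMDS result: coordinates, final Kruskal stress-1, bookkeeping."""

    sample_ids: list
    coordinates: np.ndarray  # (n_samples, k)
    stress: float
    n_starts: int
    converged: bool

    @property
    def frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> Ordination:
    """Non-metric MDS: best of ``n_starts`` seeded SMACOF runs by stress-1.

    Never raises on non-convergence; the best configuration is returned with
    ``converged=False`` when the iteration cap was hit in that run.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    dissim = np.asarray(dm.data, dtype=float)
    seeds = np.random.SeedSequence(seed).generate_state(n_starts)
    best = None
    for s in seeds:
        mds = MDS(
            n_components=k,
            metric_mds=False,
            n_init=1,
            init="random",
            max_iter=max_iter,
            eps=tol,
            metric="precomputed",
            random_state=int(s % (2**31 - 1)),
            normalized_stress=True,
        )
        coords = mds.fit_transform(dissim)
        stress = kruskal_stress(dissim, coords)
        converged = mds.n_iter_ < max_iter
        if best is None or stress < best[0]:
            best = (stress, coords, converged)
    stress, coords, converged = best
    return Ordination(
        sample_ids=list(dm.ids),
        coordinates=coords,
        stress=stress,
        n_starts=n_starts,
        converged=converged,
    )
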