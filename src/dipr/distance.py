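"""Pairwise distances among samples and the Mantel permutation test.

Distances among varieties can be computed from any standardized covariate
block.  Two variants are offered: plain Euclidean distances, and the
cophenetic distances from an average-linkage (UPGMA) tree built on them —
clustering-based workflows sometimes report the latter, which is the tree
height at which two samples first merge and is always ultrametric.

The Mantel test correlates the vectorized upper triangles of two distance
matrices over the same samples and assesses significance by jointly
permuting the rows and columns of the second matrix; the one-sided
("greater") p-value uses the standard +1 correction, so p >= 1/(B+1) for B
permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .errors import IdMismatchError, TooFewRowsError, ZeroVarianceError


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with a zero diagonal."""

    sample_ids: list[str]
    D: np.ndarray
    source_block: str = ""
    metric: str = "euclidean"  # or "upgma-cophenetic"

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.sample_ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample IDs")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.D < -1e-10):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int


def euclidean_distances(
    X: np.ndarray,
    sample_ids: Optional[list[str]] = None,
    source_block: str = "",
) -> DistanceMatrix:
    """Euclidean distance between every pair of rows of ``X`` (no missing)."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains missing values; standardize/impute first")
    D = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(X, metric="euclidean")
    )
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(X.shape[0])]
    return DistanceMatrix(list(ids), D, source_block, "euclidean")


def upgma_cophenetic(dm: DistanceMatrix) -> DistanceMatrix:
    """Cophenetic distances from an average-linkage (UPGMA) tree on ``dm``."""
    condensed = scipy.spatial.distance.squareform(dm.D, checks=False)
    linkage = scipy.cluster.hierarchy.linkage(condensed, method="average")
    coph = scipy.spatial.distance.squareform(
        scipy.cluster.hierarchy.cophenet(linkage)
    )
    return DistanceMatrix(
        list(dm.sample_ids), coph, dm.source_block, "upgma-cophenetic"
    )


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> MantelResult:
    """One-sided Mantel test of association between two distance matrices.

    r is the Pearson correlation of the upper-triangle distances;
    significance comes from jointly permuting rows and columns of ``d2``
    with a seeded generator: p = (#{r_perm >= r_obs} + 1) / (B + 1).
    """
    if d1.sample_ids != d2.sample_ids:
        raise IdMismatchError("distance matrices are over different samples")
    n = d1.n
    if n < 4:
        raise TooFewRowsError("Mantel test needs at least 4 samples")
    iu, ju = np.triu_indices(n, k=1)
    x = d1.D[iu, ju]
    y = d2.D[iu, ju]
    xc = x - x.mean()
    xn = np.linalg.norm(xc)
    yc = y - y.mean()
    yn = np.linalg.norm(yc)
    if xn == 0.0 or yn == 0.0:
        raise ZeroVarianceError("all off-diagonal distances equal; r undefined")
    r_obs = float(xc @ yc / (xn * yn))

    rng = np.random.default_rng(seed)
    D2 = d2.D
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = D2[perm[iu], perm[ju]]
        ypc = yp - yp.mean()
        ypn = np.linalg.norm(ypc)
        r_perm = xc @ ypc / (xn * ypn)
        if r_perm >= r_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, p=float(p), n_permutations=n_permutations, seed=seed)
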