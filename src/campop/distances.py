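"""Genetic distances and principal coordinates analysis.

Individual-level distances use the codominant-genotypic scheme for diploid
biallelic loci: per-locus squared dosage difference (0, 1 or 4), summed over
loci called in both individuals and rescaled to the full locus count so
pairs with different completeness stay comparable. Population-level
divergence uses Nei's standard genetic distance. PCoA is classical metric
multidimensional scaling (Gower double-centering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.labels = [str(l) for l in self.labels]
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match label count")
        if np.abs(self.d - self.d.T).max(initial=0.0) > 1e-9:
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def condensed(self) -> pd.DataFrame:
        rows = [
            (self.labels[i], self.labels[j], self.d[i, j])
            for i in range(self.n)
            for j in range(i + 1, self.n)
        ]
        return pd.DataFrame(rows, columns=["a", "b", "distance"])


def pairwise_squared_dosage(
    matrix: np.ndarray, rescale_to: int | None = None
) -> np.ndarray:
    """Pairwise sums of squared entry differences over jointly called columns.

    ``matrix`` holds row vectors with :data:`MISSING` sentinels. Each pair's
    sum runs over columns called in both rows and is rescaled by
    ``rescale_to / n_shared`` (default: the column count). Raises if any pair
    shares no called column.
    """
    x = np.asarray(matrix, dtype=float)
    called = x != MISSING
    x0 = np.where(called, x, 0.0)
    m = called.astype(float)
    shared = m @ m.T
    if (shared == 0).any():
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(f"rows {i} and {j} share no called loci")
    sq = x0**2
    cross = x0 @ x0.T
    a = sq @ m.T
    d2 = a + a.T - 2.0 * cross
    L = x.shape[1] if rescale_to is None else rescale_to
    d2 = d2 * (L / shared)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def individual_distances(genotypes: GenotypeMatrix) -> DistanceMatrix:
    """Squared-dosage-difference distances between all individuals.

    Per locus the squared difference of ALT dosages is 0, 1 or 4 (the
    codominant-genotypic values for shared, one-step and opposite-homozygote
    genotypes); the pairwise distance sums these over loci called in both
    individuals, rescaled by L / L_shared.
    """
    if genotypes.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    try:
        d2 = pairwise_squared_dosage(genotypes.dosages)
    except ValueError as exc:
        raise ValueError(f"individual distance failed: {exc}") from exc
    return DistanceMatrix(genotypes.sample_ids, d2)


def nei_distance(p_x, p_y) -> float:
    """Nei's standard genetic distance between two populations.

    ``p_x`` and ``p_y`` are per-locus ALT-allele frequencies over the same
    loci. With Jx = mean Σpᵢ², Jy likewise, and Jxy = mean Σ pᵢqᵢ,
    D = −ln(Jxy / √(Jx·Jy)). Disjoint allele sets (Jxy = 0) make D infinite;
    NaN is returned with a warning.
    """
    p_x = np.asarray(p_x, dtype=float)
    p_y = np.asarray(p_y, dtype=float)
    if p_x.shape != p_y.shape:
        raise ValueError("populations must share the same loci")
    jx = float(np.mean(p_x**2 + (1 - p_x) ** 2))
    jy = float(np.mean(p_y**2 + (1 - p_y) ** 2))
    jxy = float(np.mean(p_x * p_y + (1 - p_x) * (1 - p_y)))
    if jxy == 0.0:
        warnings.warn("Nei distance undefined (no shared alleles)", stacklevel=2)
        return float("nan")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


@dataclass
class PcoaResult:
    """Principal coordinates, eigenvalues and explained-variance shares."""

    labels: list[str]
    coordinates: np.ndarray  # (n, n_axes)
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    pct_variance: np.ndarray  # per retained axis, % of positive-eigenvalue sum

    def to_frame(self) -> pd.DataFrame:
        cols = {f"axis{i + 1}": self.coordinates[:, i]
                for i in range(self.coordinates.shape[1])}
        return pd.DataFrame(cols, index=self.labels)


def pcoa(
    distances: DistanceMatrix, n_axes: int = 2, standardize: bool = False
) -> PcoaResult:
    """Principal coordinates analysis of a distance matrix.

    Gower double-centering of −½·D², eigendecomposition, coordinates scaled
    by √eigenvalue. Axes are ordered by decreasing eigenvalue; negative
    eigenvalues (non-Euclidean input) are reported but excluded from the
    explained-variance denominator and never yield coordinates. Axis signs
    are arbitrary. ``standardize`` divides the distances by their largest
    entry first.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d = distances.d.copy()
    if standardize and d.max() > 0:
        d = d / d.max()
    n = d.shape[0]
    b = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # clip numerically-zero eigenvalues
    eigval[np.abs(eigval) < 1e-10 * max(1.0, np.abs(eigval).max())] = 0.0
    n_pos = int((eigval > 0).sum())
    keep = min(n_axes, max(n_pos, 0))
    coords = eigvec[:, :keep] * np.sqrt(eigval[:keep])
    if keep < n_axes:
        coords = np.pad(coords, ((0, 0), (0, n_axes - keep)))
    pos_sum = eigval[eigval > 0].sum()
    if pos_sum > 0:
        pct = 100.0 * np.maximum(eigval[:n_axes], 0.0) / pos_sum
    else:
        pct = np.zeros(n_axes)
    return PcoaResult(distances.labels, coords, eigval, pct)
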