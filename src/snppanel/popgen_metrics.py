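"""Population-structure and linkage-disequilibrium metrics.

Identity-by-state distances between genotyped samples, classical
(Torgerson) multidimensional scaling of the distance matrix, pairwise r²
from allele-dosage correlation, and distance-binned LD-decay profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel_io import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "MdsResult",
    "LdDecayProfile",
    "ibs_distance",
    "classical_mds",
    "r2_pair",
    "ld_decay_profile",
    "adjacent_r2_mean",
]


@dataclass
class DistanceMatrix:
    """Symmetric IBS distance matrix with zero diagonal, entries in [0,1]."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with sample ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("IBS distances must lie in [0, 1]")
        self.values = v


@dataclass
class MdsResult:
    """Coordinates (n x k) and eigenvalues (descending) of classical MDS.

    Coordinates are defined up to sign and rotation; axes with negative
    eigenvalues are truncated to zero."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class LdDecayProfile:
    """Distance-binned mean r²: contiguous bin edges (bp), per-bin mean
    over defined pairs, and pair counts."""

    bin_edges: np.ndarray  # length nbins + 1
    mean_r2: np.ndarray  # NaN where a bin has no defined pair
    pair_count: np.ndarray


# ---------------------------------------------------------------------------
# IBS distance
# ---------------------------------------------------------------------------


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise identity-by-state distance over mutually called loci.

    Per-locus similarity between dosages g_i, g_j is 1 − |g_i − g_j| / 2
    (allele-sharing fraction); pair distance is one minus the mean
    similarity.  A pair with no shared called locus raises.
    """
    if matrix.n_samples < 2:
        raise ValueError("at least two samples required")
    g = matrix.geno.astype(float)
    g[matrix.geno == MISSING] = np.nan
    n = matrix.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(g[i] - g[j])
            ok = ~np.isnan(diff)
            if not ok.any():
                raise ValueError(
                    f"samples {matrix.samples[i][0]} and {matrix.samples[j][0]} "
                    "share no called locus"
                )
            sim = 1.0 - np.mean(diff[ok]) / 2.0
            d[i, j] = d[j, i] = 1.0 - sim
    return DistanceMatrix(sample_ids=[s for s, _ in matrix.samples], values=d)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------


def classical_mds(dist: DistanceMatrix, k: int = 2) -> MdsResult:
    """Torgerson scaling: double-center −½D², eigendecompose, scale the top
    k eigenvectors by sqrt(eigenvalue).

    Negative eigenvalues (non-Euclidean distances) are truncated to zero
    with a warning.
    """
    d = dist.values
    n = d.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    top = eigval[:k].copy()
    if (top < -1e-9 * max(1.0, abs(eigval[0]))).any():
        warnings.warn(
            "negative MDS eigenvalues truncated to zero (non-Euclidean distances)",
            UserWarning,
            stacklevel=2,
        )
    top = np.clip(top, 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(top)
    return MdsResult(coordinates=coords, eigenvalues=eigval[:k])


# ---------------------------------------------------------------------------
# LD: dosage-correlation r²
# ---------------------------------------------------------------------------


def r2_pair(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over mutually called samples.

    Returns NaN (undefined) when fewer than two shared calls exist or
    either column is constant on the shared set.  Invariant under allele
    relabeling (g -> 2 - g) of either column.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[ok], g2[ok]
    if a.size < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_decay_profile(
    matrix: GenotypeMatrix,
    max_dist: int = 40_000,
    bin_width: int = 5_000,
) -> LdDecayProfile:
    """Bin all intra-chromosome pairs within ``max_dist`` by distance and
    average r² per bin (undefined pairs excluded from the means)."""
    positions = [(loc.chrom, loc.pos) for loc in matrix.loci]
    nbins = math.ceil(max_dist / bin_width)
    edges = np.arange(nbins + 1) * bin_width
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)

    by_chrom: dict[str, list[int]] = {}
    for j, (chrom, _pos) in enumerate(positions):
        by_chrom.setdefault(chrom, []).append(j)
    any_pair = False
    for chrom, idx in by_chrom.items():
        idx.sort(key=lambda j: positions[j][1])
        for a in range(len(idx)):
            ja = idx[a]
            pa = positions[ja][1]
            for b in range(a + 1, len(idx)):
                jb = idx[b]
                dist = positions[jb][1] - pa
                if dist > max_dist:
                    break
                any_pair = True
                r2 = r2_pair(matrix.geno[:, ja], matrix.geno[:, jb])
                if math.isnan(r2):
                    continue
                k = min(dist // bin_width, nbins - 1) if dist < max_dist else nbins - 1
                sums[k] += r2
                counts[k] += 1
    if not any_pair:
        return LdDecayProfile(
            bin_edges=edges, mean_r2=np.empty(0), pair_count=np.empty(0, dtype=int)
        )
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdDecayProfile(bin_edges=edges, mean_r2=mean, pair_count=counts)


def adjacent_r2_mean(matrix: GenotypeMatrix, chromosome: str) -> float:
    """Mean r² over consecutive-marker pairs on one chromosome, skipping
    pairs where r² is undefined."""
    idx = [j for j, loc in enumerate(matrix.loci) if loc.chrom == chromosome]
    idx.sort(key=lambda j: matrix.loci[j].pos)
    if len(idx) < 2:
        raise ValueError(f"need at least two markers on chromosome {chromosome}")
    vals = []
    for a, b in zip(idx, idx[1:]):
        r2 = r2_pair(matrix.geno[:, a], matrix.geno[:, b])
        if not math.isnan(r2):
            vals.append(r2)
    if not vals:
        raise ValueError("no defined adjacent pair on chromosome")
    return float(np.mean(vals))
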