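"""Genetic relatedness: dosage PCA via principal coordinates, and
identity-by-state similarity.

The call matrix is numerically encoded as reference-allele dosage (0/1/2
copies of the per-marker major allele). PCA "based on Euclidean
distances" is computed by classical scaling (double-centering the squared
distance matrix and eigendecomposing); because the distances are Euclidean
over the dosage vectors this provably coincides with ordinary PCA of the
centered dosage matrix — eigenvalues exactly, scores up to sign.

IBS similarity scores each marker as the shared-allele count over two
(1, 0.5, or 0, heterozygotes included) and averages over markers where
both calls are non-missing. IBS and the trees built from it use raw calls
and are never imputed; mean-dosage imputation applies to PCA only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .iupac import MISSING, SCORE_TABLE, alleles


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    eigenvalues: np.ndarray  # positive eigenvalues, non-increasing
    variance_percent: np.ndarray  # 100 * eigenvalue / sum(positive)


@dataclass
class SimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, in [0, 1]; NaN where no shared markers
    n_compared: np.ndarray  # markers used per pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def encode_dosage(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Encode calls as copies of the per-marker major allele.

    hom-major = 2, het = 1, hom-minor = 0, missing = NaN. Allele-count
    ties break to the lexicographically smaller base. Returns the dosage
    frame and the per-marker reference (major) allele. Markers with more
    than two observed alleles are rejected.
    """
    dosages = np.full(matrix.shape, np.nan)
    refs = []
    for i, (marker, row) in enumerate(matrix.iterrows()):
        counts: dict[str, int] = {}
        for call in row:
            if call == MISSING:
                continue
            for a in alleles(call):
                counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise ValueError(f"marker {marker} has more than two alleles")
        if not counts:
            refs.append(MISSING)
            continue
        ref = min(counts, key=lambda a: (-counts[a], a))
        refs.append(ref)
        for j, call in enumerate(row):
            if call != MISSING:
                dosages[i, j] = sum(a == ref for a in alleles(call))
    dosage = pd.DataFrame(dosages, index=matrix.index, columns=matrix.columns)
    return dosage, pd.Series(refs, index=matrix.index, name="reference_allele")


def euclidean_distances(dosage: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Pairwise Euclidean distances between samples over marker dimensions.

    Missing dosages are imputed with the per-marker mean first; markers
    with no observed calls are dropped with a warning.
    """
    d = dosage.to_numpy(dtype=float)
    all_missing = np.isnan(d).all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} marker(s) with no observed calls",
            stacklevel=2,
        )
        d = d[~all_missing]
    means = np.nanmean(d, axis=1, keepdims=True)
    d = np.where(np.isnan(d), means, d)
    dist = squareform(pdist(d.T, metric="euclidean"))
    return list(dosage.columns), dist


def pcoa(sample_ids: list[str], dist: np.ndarray) -> PCAResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Gower double-centering of -D**2/2 followed by eigendecomposition;
    only positive eigenvalues are retained as components.
    """
    n = dist.shape[0]
    if n < 2:
        raise ValueError("pcoa needs at least 2 samples")
    b = -0.5 * dist**2
    b = b - b.mean(axis=0, keepdims=True) - b.mean(axis=1, keepdims=True) + b.mean()
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    positive = eigvals > tol
    eigvals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(eigvals)
    variance = 100.0 * eigvals / eigvals.sum()
    frame = pd.DataFrame(
        coords,
        index=sample_ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return PCAResult(coordinates=frame, eigenvalues=eigvals, variance_percent=variance)


def select_pcs(result: PCAResult, threshold_percent: float = 80.0) -> int:
    """Smallest k whose cumulative variance strictly exceeds the threshold."""
    if threshold_percent >= 100:
        raise ValueError("threshold_percent must be < 100")
    cumulative = np.cumsum(result.variance_percent)
    return int(np.argmax(cumulative > threshold_percent)) + 1


def ibs_matrix(matrix: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise mean IBS site score over both-called markers."""
    samples = list(matrix.columns)
    codes = np.array(
        [matrix[s].str.encode("ascii").map(lambda b: b[0]).to_numpy(np.uint8) for s in samples]
    )
    n = len(samples)
    values = np.full((n, n), np.nan)
    n_compared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            scores = SCORE_TABLE[codes[i], codes[j]]
            valid = ~np.isnan(scores)
            k = int(valid.sum())
            n_compared[i, j] = n_compared[j, i] = k
            if k:
                values[i, j] = values[j, i] = float(scores[valid].mean())
    return SimilarityMatrix(sample_ids=samples, values=values, n_compared=n_compared)


def nearest_neighbors(
    sim: SimilarityMatrix, query_samples: list[str]
) -> pd.DataFrame:
    """Rank non-query samples by descending similarity to each query.

    All queries are excluded from the candidate pool; ties break by
    sample id.
    """
    unknown = set(query_samples) - set(sim.sample_ids)
    if unknown:
        raise KeyError(f"unknown query samples: {sorted(unknown)}")
    frame = sim.to_frame()
    candidates = [s for s in sim.sample_ids if s not in set(query_samples)]
    rows = []
    for q in query_samples:
        ranked = sorted(
            ((frame.loc[q, c], c) for c in candidates),
            key=lambda t: (-t[0] if not np.isnan(t[0]) else np.inf, t[1]),
        )
        for rank, (value, c) in enumerate(ranked, start=1):
            rows.append((q, rank, c, value))
    return pd.DataFrame(rows, columns=["query", "rank", "neighbor", "similarity"])
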