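"""Descriptive analyses: group mean +/- SD spectra, peak counting, PCA.

These reproduce the unsupervised half of the pipeline: mean spectra with
their point-wise standard deviation bands, the characteristic-peak count of
the group mean spectra, and a three-component PCA of the fingerprint
vectors together with a permutation test for group separation in score
space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.decomposition import PCA

from .preprocessing import FeatureMatrix

__all__ = [
    "GroupSummary",
    "PCAResult",
    "group_mean_sd",
    "count_peaks",
    "run_pca",
    "group_separation_permutation_test",
]


@dataclass
class GroupSummary:
    """Per-group pointwise mean and population SD over the fingerprint grid."""

    group: str
    mean: np.ndarray
    sd: np.ndarray
    n: int


@dataclass
class PCAResult:
    """Mean-centred PCA of the feature matrix (spectra as observations)."""

    loadings: np.ndarray  # (n_components, n_features), rows orthonormal
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n_spectra, n_components)


def group_mean_sd(features: FeatureMatrix) -> list[GroupSummary]:
    """Mean and population SD per wavenumber for each group present.

    Requires at least two spectra per group (a single spectrum has no
    spread to report).
    """
    summaries = []
    for group in dict.fromkeys(features.groups):  # preserve first-appearance order
        mask = features.groups == group
        n = int(mask.sum())
        if n < 2:
            raise ValueError(f"group {group!r} has only {n} spectrum; need >= 2")
        block = features.X[mask]
        summaries.append(
            GroupSummary(group=str(group), mean=block.mean(axis=0), sd=block.std(axis=0), n=n)
        )
    return summaries


def count_peaks(
    intensities: np.ndarray,
    wavenumbers: np.ndarray,
    min_prominence: float = 0.01,
    min_separation: float = 8.0,
) -> tuple[int, np.ndarray]:
    """Count local maxima of a (mean) spectrum.

    ``min_prominence`` is relative to the spectrum's intensity range, so
    counting is invariant to positive rescaling; ``min_separation`` is the
    minimum distance between accepted maxima in cm^-1.
    """
    if min_prominence <= 0 or min_separation <= 0:
        raise ValueError("min_prominence and min_separation must be > 0")
    y = np.asarray(intensities, dtype=float)
    w = np.asarray(wavenumbers, dtype=float)
    span = float(y.max() - y.min())
    if span == 0.0:
        return 0, np.array([])
    step = float(np.median(np.diff(w)))
    idx, _ = find_peaks(
        y,
        prominence=min_prominence * span,
        distance=max(1, int(round(min_separation / step))),
    )
    return int(idx.size), w[idx]


def run_pca(features: FeatureMatrix, n_components: int = 3) -> PCAResult:
    """Mean-centred PCA on spectra; deterministic up to a fixed sign convention.

    Each component's sign is fixed so that its largest-magnitude loading
    element is positive.
    """
    n = features.X.shape[0]
    if n <= n_components:
        raise ValueError(f"need more spectra ({n}) than components ({n_components})")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(features.X)
    loadings = pca.components_.copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=scores,
    )


def group_separation_permutation_test(
    scores: np.ndarray,
    groups: np.ndarray,
    sample_ids: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for group separation of PCA score centroids.

    The statistic is the Euclidean distance between the two groups' centroids
    in score space, computed over per-sample mean scores. Group labels are
    permuted at the *sample* level (replicate spectra of one sample carry the
    same label and move together), which is the exchangeable unit of the
    design. Returns ``(observed_distance, p_value)`` with the add-one
    permutation p-value.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    sample_ids = np.asarray(sample_ids)
    uniq = list(dict.fromkeys(sample_ids))
    sample_scores = np.vstack([scores[sample_ids == s].mean(axis=0) for s in uniq])
    sample_groups = np.array([groups[sample_ids == s][0] for s in uniq])
    labels = np.unique(sample_groups)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {labels.tolist()}")

    def centroid_distance(g: np.ndarray) -> float:
        a = sample_scores[g == labels[0]].mean(axis=0)
        b = sample_scores[g == labels[1]].mean(axis=0)
        return float(np.linalg.norm(a - b))

    observed = centroid_distance(sample_groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if centroid_distance(rng.permutation(sample_groups)) >= observed:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return observed, p
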