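"""Multidimensional neural-space analyses.

Each trial's population response is a point in n-neuron space.  The
*main diagonal* is the all-equal line: a point's projection onto it is
its population mean, and its distance to the diagonal is the
multidimensional heterogeneity.  This module provides pairwise
inter-trial distance distributions, mirroring across the diagonal
(sign inversion of per-neuron deviations, which preserves both the
mean and the distance to the diagonal), asymmetry quantification by
one-at-a-time mirroring, the removal transforms that delete the
per-trial mean and/or normalize the distance-to-diagonal to 1, and
hit/miss decoding on the transformed clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .decoding import loo_gaussian_nb


@dataclass
class PointCloud:
    """Trials x neurons points with a hit/miss label per point."""

    points: np.ndarray            # [n_trials x n_neurons]
    labels: np.ndarray            # object array, e.g. "hit"/"miss"
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.points.shape[0]:
            raise ValueError("one label per point required")

    def select(self, label) -> np.ndarray:
        return self.points[self.labels == label]


@dataclass
class DistanceDistribution:
    distances: np.ndarray
    mean: float
    label: object


def pairwise_distances(cloud: PointCloud, label) -> DistanceDistribution:
    """All unique-pair Euclidean distances within one label set."""
    pts = cloud.select(label)
    if pts.shape[0] < 2:
        raise ValueError(f"need >= 2 points labelled {label!r}")
    d = pdist(pts, metric="euclidean")
    return DistanceDistribution(distances=d, mean=float(d.mean()),
                                label=label)


def mirror_across_diagonal(point: np.ndarray) -> np.ndarray:
    """r' = 2*mean(r) - r: reflect through the projection on the diagonal."""
    r = np.asarray(point, float)
    mu = r.mean(axis=-1, keepdims=True)
    return 2.0 * mu - r


def asymmetry_by_mirroring(cloud: PointCloud, label) -> float:
    """Mean distance increase under one-at-a-time mirroring.

    Each point is mirrored in turn and the mean pairwise distance of
    the modified set recomputed; the asymmetry index is the average
    difference to the original mean pairwise distance.  Clouds that are
    symmetric about the diagonal give ~0.
    """
    pts = cloud.select(label)
    if pts.shape[0] < 3:
        raise ValueError("need >= 3 points")
    base = pdist(pts).mean()
    diffs = np.empty(pts.shape[0])
    for i in range(pts.shape[0]):
        mod = pts.copy()
        mod[i] = mirror_across_diagonal(pts[i])
        diffs[i] = pdist(mod).mean() - base
    return float(diffs.mean())


# ---------------------------------------------------------------------------
# Removal transforms
# ---------------------------------------------------------------------------

def remove_mean(cloud: PointCloud) -> PointCloud:
    """Subtract each trial's own population mean (distance to the
    diagonal is untouched)."""
    pts = cloud.points - cloud.points.mean(axis=1, keepdims=True)
    return PointCloud(points=pts, labels=cloud.labels.copy())


def remove_heterogeneity(cloud: PointCloud) -> PointCloud:
    """Normalize every trial's distance-to-diagonal to 1, keeping its mean.

    The point is divided by the Euclidean norm of its deviations from
    its own mean, then the original mean is restored; afterwards every
    trial lies on the unit-radius cylinder around the main diagonal.
    Points exactly on the diagonal have no defined direction and are
    dropped with a warning entry.
    """
    pts = cloud.points
    mu = pts.mean(axis=1, keepdims=True)
    het = np.linalg.norm(pts - mu, axis=1, keepdims=True)
    ok = het[:, 0] > 0
    dropped = [(i, "point on the diagonal") for i in np.nonzero(~ok)[0]]
    scaled = pts[ok] / het[ok]
    restored = scaled + mu[ok] - scaled.mean(axis=1, keepdims=True)
    return PointCloud(points=restored, labels=cloud.labels[ok],
                      dropped=dropped)


def remove_both(cloud: PointCloud) -> PointCloud:
    """Remove the mean and normalize heterogeneity: points land on the
    unit sphere within the zero-mean subspace."""
    return remove_mean(remove_heterogeneity(cloud))


def distance_to_diagonal(points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, float))
    dev = pts - pts.mean(axis=1, keepdims=True)
    return np.linalg.norm(dev, axis=1)


# ---------------------------------------------------------------------------
# Post-removal decoding
# ---------------------------------------------------------------------------

def hitmiss_decode_after_removal(cloud: PointCloud) -> dict:
    """Balanced hit/miss decoding accuracy for each removal variant.

    Leave-one-out diagonal-Gaussian naive Bayes on the original cloud
    and on the mean-removed, heterogeneity-removed, and both-removed
    transforms; chance is 0.5.  Balanced accuracy = mean of per-class
    accuracies.
    """
    variants = {
        "original": cloud,
        "mean_removed": remove_mean(cloud),
        "heterogeneity_removed": remove_heterogeneity(cloud),
        "both_removed": remove_both(cloud),
    }
    out = {}
    for name, var in variants.items():
        result = loo_gaussian_nb(var.points.T, var.labels)
        accs = []
        for c in result.classes:
            mask = var.labels == c
            accs.append(result.correct[mask].mean())
        out[name] = float(np.mean(accs))
    return out
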