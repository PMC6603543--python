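"""Calibration of the decision boundaries from a reference feature table.

Normal performances fall into two styles: C1 "wider and slower" (large
apertures, lower rate) and C2 "narrower and faster".  The two style centers
are learned with 2-means on (alpha_av, f_av) pairs from a reference group.
Within each style, the score boundaries for a feature are the midpoints of
neighbouring 4-means cluster centers sorted in descending order
(b_i = (c_i + c_{i+1}) / 2), so that smaller apertures / lower rates map to
higher subscores.

Cluster assignment of a new recording uses the Euclidean distance to the two
style centers in raw units (degrees, Hz) by default, mirroring the original
procedure.  Because the aperture coordinate (tens of degrees) numerically
dominates the frequency coordinate (a few Hz), a z-scored distance is
available via ``standardize=True``; the scales are stored with the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import CalibrationError

#: k-means settings (restarts / iterations / tolerance), fixed for
#: reproducibility under a given seed.
KMEANS_KW = dict(n_init=10, max_iter=300, tol=1e-6)


@dataclass
class CalibrationModel:
    """Two style centers plus per-style boundary triples for angle and rate."""

    center_c1: np.ndarray   # (alpha_av deg, f_av Hz), wider & slower
    center_c2: np.ndarray   # narrower & faster
    b_alpha_c1: np.ndarray  # descending triples, degrees
    b_alpha_c2: np.ndarray
    b_freq_c1: np.ndarray   # descending triples, Hz
    b_freq_c2: np.ndarray
    seed: int = 0
    feature_scale: np.ndarray = field(default_factory=lambda: np.ones(2))

    def __post_init__(self) -> None:
        for name in ("center_c1", "center_c2", "b_alpha_c1", "b_alpha_c2",
                     "b_freq_c1", "b_freq_c2", "feature_scale"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.center_c1[0] <= self.center_c2[0]:
            raise CalibrationError(
                "naming contract violated: C1 must have the larger aperture coordinate"
            )
        if self.center_c1[1] >= self.center_c2[1]:
            warnings.warn(
                "C1 is not slower than C2: style naming contract only partially met",
                stacklevel=2,
            )
        for name in ("b_alpha_c1", "b_alpha_c2", "b_freq_c1", "b_freq_c2"):
            trip = getattr(self, name)
            if trip.shape != (3,) or np.any(np.diff(trip) >= 0):
                raise CalibrationError(f"{name} must be a strictly decreasing triple, got {trip}")
        if np.any(self.feature_scale <= 0):
            raise CalibrationError("feature_scale entries must be positive")


def fit_performance_clusters(features: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """2-means centers of an (n, 2) table of (alpha_av, f_av) pairs.

    Returns ``(center_c1, center_c2)`` with C1 the center of larger aperture.
    """
    feats = np.asarray(features, dtype=float)
    if feats.ndim != 2 or feats.shape[1] != 2:
        raise CalibrationError(f"features must have shape (n, 2), got {feats.shape}")
    if feats.shape[0] < 4:
        raise CalibrationError("need at least 4 feature pairs to fit performance clusters")
    if np.all(feats == feats[0]):
        raise CalibrationError("degenerate reference table: all feature pairs identical")
    km = KMeans(n_clusters=2, random_state=seed, **KMEANS_KW).fit(feats)
    centers = km.cluster_centers_
    order = np.argsort(centers[:, 0])[::-1]  # larger alpha first
    c1, c2 = centers[order[0]], centers[order[1]]
    if c1[1] >= c2[1]:
        warnings.warn("fitted C1 is not slower than C2", stacklevel=2)
    return c1, c2


def fit_score_boundaries(values: np.ndarray, seed: int) -> np.ndarray:
    """Descending boundary triple b_i = (c_i + c_{i+1}) / 2 from 4-means centers."""
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size < 4 or np.unique(vals).size < 4:
        raise CalibrationError("need at least 4 distinct values to fit 4 score clusters")
    km = KMeans(n_clusters=4, random_state=seed, **KMEANS_KW).fit(vals.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())[::-1]
    return (centers[:-1] + centers[1:]) / 2.0


def assign_cluster(
    alpha_av: float,
    f_av: float,
    model: CalibrationModel,
    standardize: bool = False,
) -> tuple[str, tuple[np.ndarray, np.ndarray]]:
    """Nearer style center ('C1' on ties) and its (angle, rate) boundary pair."""
    point = np.array([alpha_av, f_av], dtype=float)
    scale = model.feature_scale if standardize else np.ones(2)
    d1 = np.linalg.norm((point - model.center_c1) / scale)
    d2 = np.linalg.norm((point - model.center_c2) / scale)
    if d1 <= d2:
        return "C1", (model.b_alpha_c1, model.b_freq_c1)
    return "C2", (model.b_alpha_c2, model.b_freq_c2)


def build_calibration(
    normal_features: np.ndarray,
    cohort_c1: np.ndarray,
    cohort_c2: np.ndarray,
    seed: int = 0,
) -> CalibrationModel:
    """Fit a full calibration model.

    ``normal_features`` (n, 2) are pairs from performances rated normal, used
    for the style centers.  ``cohort_c1`` / ``cohort_c2`` (m, 2) are the
    severity-spanning reference pairs of each style, used for the four
    boundary triples.  How the cohort is split into styles (known grouping or
    :func:`split_cohort`) is the caller's choice.
    """
    c1, c2 = fit_performance_clusters(normal_features, seed)
    normal = np.asarray(normal_features, dtype=float)
    scale = normal.std(axis=0)
    scale[scale == 0] = 1.0
    cohort_c1 = np.asarray(cohort_c1, dtype=float)
    cohort_c2 = np.asarray(cohort_c2, dtype=float)
    return CalibrationModel(
        center_c1=c1,
        center_c2=c2,
        b_alpha_c1=fit_score_boundaries(cohort_c1[:, 0], seed + 1),
        b_alpha_c2=fit_score_boundaries(cohort_c2[:, 0], seed + 2),
        b_freq_c1=fit_score_boundaries(cohort_c1[:, 1], seed + 3),
        b_freq_c2=fit_score_boundaries(cohort_c2[:, 1], seed + 4),
        seed=seed,
        feature_scale=scale,
    )


def split_cohort(
    features: np.ndarray,
    center_c1: np.ndarray,
    center_c2: np.ndarray,
    scale: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask: True where a row is nearer to C1 (optionally z-scored)."""
    feats = np.asarray(features, dtype=float)
    scale = np.ones(2) if scale is None else np.asarray(scale, dtype=float)
    d1 = np.linalg.norm((feats - center_c1) / scale, axis=1)
    d2 = np.linalg.norm((feats - center_c2) / scale, axis=1)
    return d1 <= d2
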