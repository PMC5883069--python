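"""Plant/background segmentation.

Two routes, mirroring how each image modality is best separated: the
fluorescence frames are near-zero off the plant (non-plant matter does
not fluoresce), so an intensity threshold on Fm suffices; the
multispectral frames have a bright soil signal, so pixels are clustered
into two classes (plant vs background) on their reflectance features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from sklearn.cluster import KMeans

DEFAULT_MIN_COMPONENT_AREA = 25  # pixels; suppresses noise specks


class DegenerateInputError(ValueError):
    """Raised when an input carries no separable structure."""


@dataclass
class PlantMask:
    """Boolean foreground map with its provenance."""

    mask: np.ndarray
    provenance: str  # "fluorescence_threshold" or "multispectral_kmeans"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_plant_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap |A∩B| / |A∪B| between two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def segment_fluorescence_threshold(
    fm_frame: np.ndarray, threshold: float | None = None
) -> PlantMask:
    """Threshold the Fm frame; plant pixels fluoresce, background barely.

    The threshold defaults to Otsu's value computed on log counts —
    in log space the background/plant gap dominates, so dim diseased
    tissue stays on the plant side instead of being split off with the
    background — floored at the estimated background level plus five
    background standard deviations (background statistics estimated
    robustly via the median and MAD, since background dominates the
    frame).  An empty result is allowed and warned about, not an error.
    """
    fm = np.asarray(fm_frame, dtype=float)
    if fm.size == 0:
        raise ValueError("fm_frame is empty")
    if threshold is None:
        if np.ptp(fm) == 0:
            threshold = np.inf  # constant frame: nothing to segment
        else:
            med = float(np.median(fm))
            mad_sd = 1.4826 * float(np.median(np.abs(fm - med)))
            floor = med + 5.0 * mad_sd
            t_log = float(threshold_otsu(np.log1p(np.maximum(fm, 0))))
            threshold = max(float(np.expm1(t_log)), floor)
    mask = fm > threshold
    if not mask.any():
        warnings.warn("fluorescence threshold produced an empty plant mask", stacklevel=2)
    return PlantMask(mask=mask, provenance="fluorescence_threshold")


def _kmeans_features(r510: np.ndarray, r550: np.ndarray) -> np.ndarray:
    """Per-pixel feature vectors (R510, R550, R550/R510), standardized."""
    r510 = np.asarray(r510, dtype=float)
    r550 = np.asarray(r550, dtype=float)
    ratio = np.divide(r550, r510, out=np.zeros_like(r550), where=r510 > 0)
    feats = np.stack([r510.ravel(), r550.ravel(), ratio.ravel()], axis=1)
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    return (feats - mean) / sd


def segment_kmeans(
    r510_frame: np.ndarray, r550_frame: np.ndarray, seed: int = 0
) -> PlantMask:
    """Two-class K-means on the multispectral frames.

    Features are the two reflectances plus their 550/510 ratio,
    standardized to zero mean / unit variance.  The cluster with the
    higher mean 550/510 ratio is labelled plant (vegetation is
    relatively green), so the result does not depend on cluster index
    order.  Ten seeded restarts keep the solution at the minimum-SSE
    partition.
    """
    r510 = np.asarray(r510_frame, dtype=float)
    r550 = np.asarray(r550_frame, dtype=float)
    if r510.shape != r550.shape:
        raise ValueError(f"frame shapes differ: {r510.shape} vs {r550.shape}")
    feats = _kmeans_features(r510, r550)
    if np.allclose(feats, feats[0]):
        raise DegenerateInputError("all pixels identical; cannot split into two classes")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(feats)
    if feats.shape[0] <= _SMALL_INPUT_PIXELS:
        # Lloyd iterations can stall in tie-induced local optima on tiny
        # inputs (duplicate pixels, symmetric distances); scan separating-
        # hyperplane candidate partitions and keep the minimum-SSE one.
        lab2, sse2 = _best_hyperplane_partition(feats)
        if sse2 < _partition_sse(feats, labels.astype(bool)) - 1e-12:
            labels = lab2.astype(int)
    ratio = np.divide(r550, r510, out=np.zeros_like(r550), where=r510 > 0).ravel()
    mean_ratio = [ratio[labels == c].mean() if (labels == c).any() else -np.inf for c in (0, 1)]
    plant_cluster = int(np.argmax(mean_ratio))
    mask = (labels == plant_cluster).reshape(r510.shape)
    return PlantMask(mask=mask, provenance="multispectral_kmeans")


_SMALL_INPUT_PIXELS = 256


def _partition_sse(feats: np.ndarray, lab: np.ndarray) -> float:
    sse = 0.0
    for sel in (lab, ~lab):
        if sel.any():
            c = feats[sel].mean(axis=0)
            sse += float(((feats[sel] - c) ** 2).sum())
    return sse


def _best_hyperplane_partition(feats: np.ndarray) -> tuple[np.ndarray, float]:
    """Best 2-partition over separating-hyperplane candidates.

    The optimal 2-means partition is split by the hyperplane normal to
    the difference of its centroids, i.e. it is a threshold along some
    direction.  Candidate directions: the feature axes, the principal
    axes, and (iteratively) the centroid-difference direction of each
    improving partition found.
    """
    n = feats.shape[0]
    centered = feats - feats.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    cand = [*np.eye(feats.shape[1]), *vt]
    best_sse, best_lab = np.inf, None
    seen: set[bytes] = set()
    budget = 50  # bound on refinement directions
    while cand and budget > 0:
        d = cand.pop()
        budget -= 1
        order = np.argsort(feats @ d, kind="stable")
        for k in range(1, n):
            lab = np.zeros(n, dtype=bool)
            lab[order[:k]] = True
            key = lab.tobytes() if lab[0] else (~lab).tobytes()
            if key in seen:
                continue
            seen.add(key)
            sse = _partition_sse(feats, lab)
            if sse < best_sse - 1e-12:
                best_sse, best_lab = sse, lab
                diff = feats[lab].mean(axis=0) - feats[~lab].mean(axis=0)
                nrm = np.linalg.norm(diff)
                if nrm > 0:
                    cand.append(diff / nrm)
    return best_lab, best_sse


def kmeans_sse(r510_frame: np.ndarray, r550_frame: np.ndarray, mask: np.ndarray) -> float:
    """Within-cluster sum of squares of a 2-partition in feature space.

    Shares the exact feature construction of :func:`segment_kmeans`, so
    alternative partitions of the same frames are comparable.
    """
    feats = _kmeans_features(r510_frame, r550_frame)
    lab = np.asarray(mask, dtype=bool).ravel()
    sse = 0.0
    for sel in (lab, ~lab):
        if sel.any():
            c = feats[sel].mean(axis=0)
            sse += float(((feats[sel] - c) ** 2).sum())
    return sse


def clean_mask(mask: PlantMask, min_component_area: int = DEFAULT_MIN_COMPONENT_AREA) -> PlantMask:
    """Drop 4-connected components smaller than ``min_component_area``."""
    if min_component_area < 0:
        raise ValueError("min_component_area must be >= 0")
    if min_component_area == 0:
        return PlantMask(mask=mask.mask.copy(), provenance=mask.provenance)
    lab = label(mask.mask, connectivity=1)
    counts = np.bincount(lab.ravel())
    keep = counts >= min_component_area
    keep[0] = False
    return PlantMask(mask=keep[lab], provenance=mask.provenance)
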