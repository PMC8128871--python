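"""Visual dictionary construction, descriptor quantization, BoVW encoding.

The visual dictionary is the set of Euclidean cluster centres obtained by
k-means over a pool of SIFT descriptors from the model-fitting split (never
test descriptors).  New descriptors are mapped to their nearest centre
("visual word") either by exhaustive vector quantization (VQ) or through a
k-d tree; counting word occurrences per image yields the bag-of-visual-words
frequency vector that the classifier consumes.

Quantizer semantics:

* :func:`quantize_vq` — brute-force Euclidean nearest centre; ties broken by
  the lowest centre index.
* :func:`quantize_kdtree` — exact nearest-neighbour search through a k-d
  tree by default; with a ``max_comparisons`` budget the backtracking is
  bounded (best-bin-first) and assignments may deviate from VQ, in which
  case the mismatch rate is measured and reported.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .features import DescriptorSet

logger = logging.getLogger(__name__)


class DictionarySizeError(ValueError):
    """The descriptor pool is smaller than the requested vocabulary."""


class AssignmentIntegrityError(ValueError):
    """An assignment index falls outside the dictionary."""


@dataclass(frozen=True)
class VisualDictionary:
    """``vocsize x 128`` matrix of Euclidean cluster centres plus metadata."""

    centres: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.centres.ndim != 2:
            raise ValueError("centres must be a 2-d matrix")

    @property
    def vocsize(self) -> int:
        return self.centres.shape[0]


@dataclass(frozen=True)
class BoVWVector:
    """Visual-word frequency vector for one image.

    Unnormalized counts sum to ``n_keypoints``; under L1 normalization they
    sum to 1 for any image with at least one keypoint.  A patch without
    keypoints encodes as the zero vector with ``n_keypoints == 0``.
    """

    counts: np.ndarray
    n_keypoints: int
    normalization: str = "l1"


def build_dictionary(
    descriptor_pool: np.ndarray | DescriptorSet,
    vocsize: int,
    rng_seed: int = 0,
    max_iter: int = 100,
    n_init: int = 3,
    colour_space: str | None = None,
) -> VisualDictionary:
    """Cluster a descriptor pool into ``vocsize`` Euclidean centres.

    k-means with k-means++ initialization, ``n_init`` restarts and a fixed
    seed; the within-cluster sum of squares (inertia) of the best run is
    recorded in the metadata.
    """
    if isinstance(descriptor_pool, DescriptorSet):
        descriptor_pool = descriptor_pool.descriptors
    pool = np.asarray(descriptor_pool, dtype=float)
    if pool.ndim != 2:
        raise ValueError("descriptor pool must be a 2-d matrix")
    if pool.shape[0] < vocsize:
        raise DictionarySizeError(
            f"pool of {pool.shape[0]} descriptors cannot support "
            f"vocsize {vocsize}"
        )
    from threadpoolctl import threadpool_limits

    # Single-threaded fit: parallel BLAS reductions reorder float sums and
    # break bit-reproducibility across machines with different core counts.
    with threadpool_limits(limits=1):
        km = KMeans(
            n_clusters=vocsize,
            init="k-means++",
            n_init=n_init,
            max_iter=max_iter,
            random_state=rng_seed % (2**32),
        ).fit(pool)
    return VisualDictionary(
        centres=km.cluster_centers_.astype(float),
        metadata={
            "vocsize": vocsize,
            "rng_seed": rng_seed,
            "n_descriptors": int(pool.shape[0]),
            "inertia": float(km.inertia_),
            "colour_space": colour_space,
            "max_iter": max_iter,
            "n_init": n_init,
        },
    )


def _as_matrix(descriptors: np.ndarray | DescriptorSet) -> np.ndarray:
    if isinstance(descriptors, DescriptorSet):
        descriptors = descriptors.descriptors
    mat = np.asarray(descriptors, dtype=float)
    if mat.ndim != 2:
        raise ValueError("descriptors must be a 2-d matrix")
    return mat


def quantize_vq(
    descriptors: np.ndarray | DescriptorSet, dictionary: VisualDictionary
) -> np.ndarray:
    """Exhaustive nearest-centre assignment (ties -> lowest centre index)."""
    if dictionary.vocsize == 0:
        raise ValueError("dictionary is empty")
    mat = _as_matrix(descriptors)
    if mat.shape[0] == 0:
        return np.empty((0,), dtype=int)
    d2 = cdist(mat, dictionary.centres, metric="sqeuclidean")
    return np.argmin(d2, axis=1)  # argmin returns the first (lowest) index


class MaxVarianceKdTree:
    """k-d tree splitting on the dimension of maximum variance.

    Nodes split at the median of the chosen dimension.  Queries run
    best-bin-first: candidate branches are visited in order of their
    lower-bound distance, and with ``max_comparisons`` the number of
    point-distance evaluations is capped, giving the classic approximate
    nearest-neighbour trade-off.  Without a cap the search backtracks fully
    and is exact; tied distances resolve to the lowest point index.
    """

    _LEAF_SIZE = 8

    def __init__(self, points: np.ndarray):
        self.points = np.asarray(points, dtype=float)
        if self.points.ndim != 2 or not len(self.points):
            raise ValueError("points must be a non-empty 2-d matrix")
        self.root = self._build(np.arange(len(self.points)))

    def _build(self, idx: np.ndarray):
        if len(idx) <= self._LEAF_SIZE:
            return ("leaf", idx)
        sub = self.points[idx]
        dim = int(np.argmax(np.var(sub, axis=0)))
        vals = sub[:, dim]
        if np.all(vals == vals[0]):  # degenerate: identical along every dim
            return ("leaf", idx)
        thr = float(np.median(vals))
        left = vals <= thr
        if left.all() or not left.any():
            left = vals < thr if left.all() else vals <= thr
            if left.all() or not left.any():
                return ("leaf", idx)
        return ("node", dim, thr, self._build(idx[left]), self._build(idx[~left]))

    def query(self, q: np.ndarray, max_comparisons: int | None = None) -> int:
        """Index of the (approximately) nearest stored point to ``q``."""
        best_d = np.inf
        best_i = -1
        checked = 0
        budget = np.inf if max_comparisons is None else max_comparisons
        # heap entries: (lower-bound distance^2, tiebreak counter, node)
        counter = 0
        heap = [(0.0, counter, self.root)]
        while heap:
            bound, _, node = heapq.heappop(heap)
            if bound > best_d or checked >= budget:
                if bound > best_d:
                    continue
                break
            if node[0] == "leaf":
                idx = node[1]
                take = idx
                if checked + len(idx) > budget:
                    take = idx[: max(0, int(budget - checked))]
                if len(take) == 0:
                    break
                d2 = np.sum((self.points[take] - q) ** 2, axis=1)
                checked += len(take)
                for d, i in zip(d2, take):
                    if d < best_d or (d == best_d and i < best_i):
                        best_d, best_i = d, int(i)
            else:
                _, dim, thr, left, right = node
                delta = q[dim] - thr
                near, far = (left, right) if delta <= 0 else (right, left)
                counter += 1
                heapq.heappush(heap, (bound, counter, near))
                counter += 1
                far_bound = max(bound, delta * delta)
                heapq.heappush(heap, (far_bound, counter, far))
        return best_i


def quantize_kdtree(
    descriptors: np.ndarray | DescriptorSet,
    dictionary: VisualDictionary,
    max_comparisons: int | None = None,
    return_report: bool = False,
):
    """Nearest-centre assignment through a k-d tree.

    Exhaustive mode (``max_comparisons=None``) is exact and agrees with
    :func:`quantize_vq`.  Bounded mode runs a best-bin-first search through
    a max-variance-split tree, stops after ``max_comparisons`` distance
    evaluations per descriptor, and measures the disagreement rate against
    the exact assignment, which is logged (and returned with
    ``return_report=True``) rather than silently ignored.
    """
    if dictionary.vocsize == 0:
        raise ValueError("dictionary is empty")
    mat = _as_matrix(descriptors)
    if mat.shape[0] == 0:
        empty = np.empty((0,), dtype=int)
        return (empty, {"mismatch_rate": 0.0, "n": 0}) if return_report else empty
    if max_comparisons is None:
        k = min(4, dictionary.vocsize)
        dists, idx = cKDTree(dictionary.centres).query(mat, k=k)
        if k == 1:
            assignments = np.asarray(idx, dtype=int).reshape(-1)
        else:
            # exact distance ties resolve to the lowest centre index
            tied = dists == dists[:, [0]]
            assignments = np.where(tied, idx, dictionary.vocsize).min(axis=1)
        return (assignments, {"mismatch_rate": 0.0, "n": len(mat)}) if return_report else assignments
    tree = MaxVarianceKdTree(dictionary.centres)
    assignments = np.array(
        [tree.query(q, max_comparisons=max_comparisons) for q in mat], dtype=int
    )
    exact = quantize_vq(mat, dictionary)
    mismatch = float(np.mean(assignments != exact))
    if mismatch > 0:
        logger.warning(
            "approximate k-d tree quantization deviates from exact VQ on "
            "%.2f%% of %d descriptors (max_comparisons=%d)",
            100 * mismatch,
            len(mat),
            max_comparisons,
        )
    if return_report:
        return assignments, {"mismatch_rate": mismatch, "n": len(mat)}
    return assignments


def encode_bovw(
    assignments: np.ndarray,
    vocsize: int,
    normalization: str = "l1",
) -> BoVWVector:
    """Count word occurrences and normalize.

    ``normalization`` is one of ``"none"`` (raw counts), ``"l1"`` (counts sum
    to 1), ``"l2"`` (unit Euclidean norm) or ``"hellinger"`` (square root of
    the L1-normalized counts, giving a unit-L2 vector whose linear kernel is
    the Bhattacharyya coefficient — the classic variance-stabilizing
    transform for visual-word histograms under a linear SVM).  Empty
    assignments encode as the zero vector with ``n_keypoints = 0``.
    """
    if normalization not in ("none", "l1", "l2", "hellinger"):
        raise ValueError(f"unknown normalization {normalization!r}")
    assignments = np.asarray(assignments, dtype=int)
    n = len(assignments)
    if n and (assignments.min() < 0 or assignments.max() >= vocsize):
        raise AssignmentIntegrityError(
            f"assignment indices must lie in [0, {vocsize}), got range "
            f"[{assignments.min()}, {assignments.max()}]"
        )
    counts = np.bincount(assignments, minlength=vocsize).astype(float)
    if n > 0:
        if normalization == "l1":
            counts = counts / counts.sum()
        elif normalization == "l2":
            counts = counts / np.linalg.norm(counts)
        elif normalization == "hellinger":
            counts = np.sqrt(counts / counts.sum())
    return BoVWVector(counts=counts, n_keypoints=n, normalization=normalization)
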