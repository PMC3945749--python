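"""Fixed-length pooling and the five call-similarity measures.

Whole calls are compared as pooled (mean or median over frames) feature
vectors under five indices: Jaccard's distance (Ruzicka generalization on
magnitudes, with a binary set mode), the uncentered correlation
coefficient, the angular (cosine/arc-cosine) metric, and the city-block
and Euclidean l_p distances. Similarities are mapped to distances
(1 - r) so every index ranks a candidate library by ascending distance
with a deterministic lexicographic tie-break on candidate id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import FrameFeatures

logger = logging.getLogger(__name__)

#: fixed metric order, also the tie-break order for metric selection
METRIC_ORDER = ("jaccard", "correlation", "cosine", "cityblock", "euclidean")


@dataclass
class FeatureVector:
    values: np.ndarray
    kind: str = ""
    pooling: str = "mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector must be finite")


@dataclass
class RankedMatches:
    """A query's candidates ordered by ascending distance (rank 1 = best)."""

    query_id: str
    matches: list[tuple[str, float, int]]  # (candidate_id, distance, rank)
    metric: str
    kind: str = ""

    def rank_of(self, candidate_id: str) -> int:
        for cid, _, rank in self.matches:
            if cid == candidate_id:
                return rank
        raise KeyError(candidate_id)


def pool_frames(ff: FrameFeatures, method: str = "mean") -> FeatureVector:
    """Reduce a variable-length frame sequence to one vector per call."""
    if ff.n_frames < 1:
        raise ValueError("cannot pool zero frames")
    if method == "mean":
        pooled = ff.values.mean(axis=0)
    elif method == "median":
        pooled = np.median(ff.values, axis=0)
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    return FeatureVector(pooled, kind=ff.kind, pooling=method)


def _as_arrays(a, b) -> tuple[np.ndarray, np.ndarray]:
    va = a.values if isinstance(a, FeatureVector) else np.asarray(a, dtype=np.float64)
    vb = b.values if isinstance(b, FeatureVector) else np.asarray(b, dtype=np.float64)
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch: {va.shape} vs {vb.shape}")
    return va, vb


def jaccard_distance(a, b, binary: bool = False) -> float:
    """Jaccard distance 1 - |A∩B| / |A∪B|.

    Feature vectors are continuous, so the default is the Ruzicka
    generalization on magnitudes, 1 - sum min(|a|,|b|) / sum max(|a|,|b|);
    ``binary=True`` treats nonzero entries as set membership.
    """
    va, vb = _as_arrays(a, b)
    if binary:
        va, vb = (va != 0).astype(float), (vb != 0).astype(float)
    else:
        va, vb = np.abs(va), np.abs(vb)
    union = np.maximum(va, vb).sum()
    if union == 0:
        logger.warning("Jaccard distance of two all-zero vectors defined as 0")
        return 0.0
    return float(1.0 - np.minimum(va, vb).sum() / union)


def correlation_coefficient(a, b, centered: bool = False) -> float:
    """Uncentered normalized inner product <a,b> / (||a|| ||b||) in [-1, 1]."""
    va, vb = _as_arrays(a, b)
    if centered:
        va, vb = va - va.mean(), vb - vb.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined for a zero-norm vector")
    return float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))


def angular_similarity(a, b) -> float:
    """arccos of the correlation coefficient: an angle in [0, pi]."""
    return float(np.arccos(correlation_coefficient(a, b)))


def lp_distance(a, b, p: float = 2) -> float:
    """Minkowski distance; p=1 city block, p=2 Euclidean."""
    if p < 1:
        raise ValueError("p must be >= 1")
    va, vb = _as_arrays(a, b)
    return float(np.linalg.norm(va - vb, ord=p))


def metric_distance(name: str, a, b) -> float:
    """Evaluate a named index as a distance (similarities mapped via 1 - r)."""
    if name == "jaccard":
        return jaccard_distance(a, b)
    if name == "correlation":
        return 1.0 - correlation_coefficient(a, b)
    if name == "cosine":
        return angular_similarity(a, b)
    if name == "cityblock":
        return lp_distance(a, b, 1)
    if name == "euclidean":
        return lp_distance(a, b, 2)
    raise ValueError(f"unknown metric {name!r}")


def rank_library(
    query: FeatureVector,
    candidates: dict[str, FeatureVector],
    metric: str,
    query_id: str = "query",
) -> RankedMatches:
    """Rank candidates by ascending distance to the query.

    Ties are broken by lexicographic candidate id so rankings are
    deterministic.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    dists = sorted(
        ((metric_distance(metric, query, vec), cid) for cid, vec in candidates.items()),
    )
    matches = [(cid, d, rank) for rank, (d, cid) in enumerate(dists, start=1)]
    return RankedMatches(query_id=query_id, matches=matches, metric=metric, kind=query.kind)
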