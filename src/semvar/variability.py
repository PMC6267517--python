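"""Semantic variability (SemVar): cluster-structure-aware ambiguity.

A word's context vectors are clustered with k-means for k = 1..k_max, the
cluster count is selected as the smallest k achieving 90% of the attainable
SSE reduction, and the score is the mean within-cluster distance divided by
the mean between-centroid distance.  Words whose meanings fall into tight,
mutually distant clusters (homonym-like) score low; words whose contexts
form one diffuse cloud (polyseme-like) score high.

All distances are cosine distances (1 - cosine) on unit-normalized vectors.
The clustering itself is Euclidean Lloyd k-means on the normalized vectors:
for unit vectors ||u - v||^2 = 2(1 - cos theta), so the Euclidean and cosine
objectives are equivalent up to a constant, and reported centroids are
re-normalized cluster means with distances on the cosine scale.

SemVar is strongly tied to the number of contexts a word has, so a
residualized variant (SemVarRes) regresses SemVar on log CD across the
lexicon and keeps the residual: the clustering signal orthogonal to sheer
context count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .diversity import ContextSet
from .space import SemanticSpace

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSolution",
    "SseProfile",
    "SemVarResult",
    "ResidualizedScores",
    "cluster_contexts",
    "sse_profile",
    "select_k",
    "within_group_distance",
    "between_group_distance",
    "semantic_variability",
    "residualize_semvar",
]

DEFAULT_K_MAX = 200
DEFAULT_N_RESTARTS = 10
DEFAULT_SSE_THRESHOLD = 0.9
DEFAULT_MIN_CONTEXTS = 10


def _unit_rows(vectors: np.ndarray) -> np.ndarray:
    v = np.asarray(vectors, dtype=np.float64)
    if v.ndim != 2:
        raise ValueError("expected a 2-D array of row vectors")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm vector cannot be placed on the unit sphere")
    return v / norms[:, None]


@dataclass(frozen=True)
class ClusterSolution:
    k: int
    assignments: np.ndarray  # (n,), labels 0..k-1
    centroids: np.ndarray  # (k, d), unit rows
    sse: float  # sum over members of cosine distance to own centroid

    def __post_init__(self) -> None:
        if len(np.unique(self.assignments)) != self.k:
            raise ValueError("empty cluster in solution")


@dataclass(frozen=True)
class SseProfile:
    k_values: np.ndarray
    sse: np.ndarray  # monotone-repaired, non-increasing

    @property
    def k_max(self) -> int:
        return int(self.k_values[-1])


@dataclass(frozen=True)
class SemVarResult:
    word: str
    k_best: int | None
    within: float | None
    between: float | None
    semvar: float | None
    n_contexts_used: int
    missing_reason: str | None = None
    k_reselected: bool = False  # provenance: selection rule returned k=1, re-run at k>=2


@dataclass(frozen=True)
class ResidualizedScores:
    slope: float
    intercept: float
    residuals: dict[str, float | None] = field(default_factory=dict)


def _cosine_sse(unit: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    sims = np.einsum("ij,ij->i", unit, centroids[labels])
    # rounding can push a unit-vector self-similarity past 1; clamp at 0
    return float(np.sum(np.maximum(1.0 - sims, 0.0)))


def _normalized_centroids(unit: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    d = unit.shape[1]
    cents = np.zeros((k, d))
    for c in range(k):
        members = unit[labels == c]
        m = members.mean(axis=0)
        nm = np.linalg.norm(m)
        # a cluster mean can vanish only for perfectly antipodal members;
        # fall back to the first member's direction
        cents[c] = members[0] if nm == 0.0 else m / nm
    return cents


def _repair_empty_clusters(labels: np.ndarray, k: int) -> np.ndarray:
    """Deterministically donate members from the largest clusters to empty ones.

    sklearn's k-means avoids empty clusters on distinct points, but duplicated
    inputs can collapse; the solution contract requires every label present.
    """
    labels = labels.copy()
    present, counts = np.unique(labels, return_counts=True)
    missing = sorted(set(range(k)) - set(present.tolist()))
    for empty in missing:
        present, counts = np.unique(labels, return_counts=True)
        donor = present[np.argmax(counts)]
        idx = int(np.nonzero(labels == donor)[0][0])
        labels[idx] = empty
    return labels


def cluster_contexts(
    vectors: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> ClusterSolution:
    """Best-of-``n_restarts`` k-means on unit-normalized vectors (k-means++ init)."""
    unit = _unit_rows(vectors)
    n = unit.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, n_vectors={n}]")
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, init="k-means++")
        labels = km.fit_predict(unit)
        labels = _repair_empty_clusters(labels, k)
    cents = _normalized_centroids(unit, labels, k)
    return ClusterSolution(k=k, assignments=labels, centroids=cents,
                           sse=_cosine_sse(unit, labels, cents))


def sse_profile(
    vectors: np.ndarray,
    k_max: int = DEFAULT_K_MAX,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> SseProfile:
    """SSE for k = 1..min(k_max, n), monotone-repaired.

    Restart noise can leave a worse optimum at a larger k; the repair
    sse[k] <- min(sse[k], sse[k-1]) restores the theoretical monotonicity.
    """
    unit = _unit_rows(vectors)
    n = unit.shape[0]
    if n < 2:
        raise ValueError("need at least two vectors for an SSE profile")
    ks = np.arange(1, min(k_max, n) + 1)
    sse = np.empty(len(ks))
    for i, k in enumerate(ks):
        sse[i] = cluster_contexts(unit, int(k), seed=seed, n_restarts=n_restarts).sse
        if i > 0 and sse[i] > sse[i - 1]:
            sse[i] = sse[i - 1]
    return SseProfile(k_values=ks, sse=sse)


def select_k(profile: SseProfile, threshold: float = DEFAULT_SSE_THRESHOLD) -> int:
    """Smallest k achieving ``threshold`` of the attainable SSE reduction.

    The reduction is measured relative to the range sse[1] - sse[k_max]; a
    flat profile selects k = 1.
    """
    sse = profile.sse
    total_drop = sse[0] - sse[-1]
    if total_drop <= 1e-12 * max(1.0, sse[0]):  # flat profile
        return 1
    target = threshold * total_drop
    drops = sse[0] - sse
    idx = int(np.argmax(drops >= target))
    return int(profile.k_values[idx])


def within_group_distance(sol: ClusterSolution, vectors: np.ndarray) -> float:
    """Mean cosine distance of members to their own centroid (pooled, so
    clusters weight by size)."""
    unit = _unit_rows(vectors)
    sims = np.einsum("ij,ij->i", unit, sol.centroids[sol.assignments])
    return float(np.mean(np.maximum(1.0 - sims, 0.0)))


def between_group_distance(sol: ClusterSolution) -> float | None:
    """Mean cosine distance over all unordered centroid pairs (unweighted)."""
    if sol.k < 2:
        logger.warning("between-group distance undefined for k < 2")
        return None
    g = sol.centroids @ sol.centroids.T
    iu = np.triu_indices(sol.k, k=1)
    return float(np.mean(np.maximum(1.0 - g[iu], 0.0)))


def semantic_variability(
    space: SemanticSpace,
    cs: ContextSet,
    k_max: int = DEFAULT_K_MAX,
    sse_threshold: float = DEFAULT_SSE_THRESHOLD,
    n_restarts: int = DEFAULT_N_RESTARTS,
    min_contexts: int = DEFAULT_MIN_CONTEXTS,
    seed: int = 0,
) -> SemVarResult:
    """Full SemVar pipeline for one word's (already capped) context set."""
    n = len(cs)
    if n < min_contexts:
        return SemVarResult(cs.word, None, None, None, None, n,
                            missing_reason="insufficient contexts")
    vectors = space.context_rows(list(cs.context_ids))
    try:
        unit = _unit_rows(vectors)
    except ValueError:
        return SemVarResult(cs.word, None, None, None, None, n,
                            missing_reason="zero-norm context vector")
    profile = sse_profile(unit, k_max=k_max, seed=seed, n_restarts=n_restarts)
    k_best = select_k(profile, threshold=sse_threshold)
    reselected = False
    if k_best < 2:
        # a between-group distance needs at least two clusters; restart the
        # search at k = 2
        candidates = profile.k_values[profile.k_values >= 2]
        if len(candidates) == 0:
            return SemVarResult(cs.word, None, None, None, None, n,
                                missing_reason="too few contexts for k >= 2")
        drops = profile.sse[0] - profile.sse
        target = sse_threshold * (profile.sse[0] - profile.sse[-1])
        ok = [int(k) for k in candidates if drops[int(k) - 1] >= target]
        k_best = ok[0] if ok else 2
        reselected = True
    sol = cluster_contexts(unit, k_best, seed=seed, n_restarts=n_restarts)
    within = within_group_distance(sol, unit)
    between = between_group_distance(sol)
    if between is None or between == 0.0:
        return SemVarResult(cs.word, k_best, within, between, None, n,
                            missing_reason="degenerate between-group distance",
                            k_reselected=reselected)
    return SemVarResult(cs.word, k_best, within, between, within / between, n,
                        k_reselected=reselected)


def residualize_semvar(
    semvar: dict[str, float | None],
    log_cd: dict[str, float],
) -> ResidualizedScores:
    """OLS of SemVar on log CD across the lexicon; per-word residuals.

    Words with a missing SemVar get a missing residual and do not enter the
    fit.  The residuals sum to zero and are uncorrelated with log CD by
    construction.
    """
    words = [w for w, v in semvar.items() if v is not None]
    if len(words) < 3:
        raise ValueError("need at least 3 words with non-missing SemVar")
    x = np.array([log_cd[w] for w in words], dtype=np.float64)
    y = np.array([semvar[w] for w in words], dtype=np.float64)
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate regressor: log CD is constant")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    fitted = intercept + slope * x
    res = dict(zip(words, (y - fitted).tolist()))
    residuals: dict[str, float | None] = {
        w: res.get(w) for w in semvar
    }
    return ResidualizedScores(slope=slope, intercept=intercept, residuals=residuals)
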