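"""Contextual diversity (CD) and semantic diversity (SemD).

CD simply counts the contexts in which a word occurs at least once; it is
reported alongside its log10.  SemD measures how dissimilar those contexts
are to one another: the mean pairwise cosine between the word's context
vectors, log-transformed with the sign reversed, so that higher scores mean
more diverse usage.  When a word occurs in more than ``cap`` (default 2,000)
contexts, the computation keeps the contexts where the word occurs most
often, purely for tractability; CD itself is always counted uncapped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .space import CooccurrenceMatrix, SemanticSpace

logger = logging.getLogger(__name__)

__all__ = ["ContextSet", "context_set", "contextual_diversity", "semantic_diversity",
           "mean_pairwise_cosine"]

DEFAULT_CONTEXT_CAP = 2000


@dataclass(frozen=True)
class ContextSet:
    """The contexts containing one target word, with per-context occurrence counts."""

    word: str
    context_ids: tuple[str, ...]
    occ_counts: tuple[int, ...]
    cap: int

    def __len__(self) -> int:
        return len(self.context_ids)


def _word_row(m: CooccurrenceMatrix, word: str) -> int:
    try:
        return m.row_index[word]
    except KeyError:
        raise KeyError(f"word {word!r} not in vocabulary") from None


def context_set(m: CooccurrenceMatrix, word: str, cap: int = DEFAULT_CONTEXT_CAP) -> ContextSet:
    """Contexts with >= 1 occurrence of ``word``, capped at the ``cap`` with
    the highest within-context occurrence counts (ties broken by context order)."""
    i = _word_row(m, word)
    row = m.counts.getrow(i)
    cols = row.indices
    counts = row.data.astype(int)
    order = np.argsort(cols)  # stable context order
    cols, counts = cols[order], counts[order]
    if len(cols) > cap:
        # highest occurrence counts first; earlier context wins ties
        sel = np.argsort(-counts, kind="stable")[:cap]
        sel.sort()
        cols, counts = cols[sel], counts[sel]
    return ContextSet(
        word=word,
        context_ids=tuple(m.context_ids[j] for j in cols),
        occ_counts=tuple(int(n) for n in counts),
        cap=cap,
    )


def contextual_diversity(m: CooccurrenceMatrix, word: str, log_base: float = 10.0) -> tuple[int, float]:
    """(cd, log cd): the uncapped number of contexts containing ``word``."""
    i = _word_row(m, word)
    cd = int(m.counts.getrow(i).nnz)
    return cd, math.log(cd, log_base)


def mean_pairwise_cosine(vectors: np.ndarray) -> float:
    """Mean cosine over all unordered pairs of row vectors."""
    v = np.asarray(vectors, dtype=np.float64)
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least two vectors")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm context vector")
    u = v / norms[:, None]
    g = u @ u.T
    iu = np.triu_indices(n, k=1)
    return float(g[iu].mean())


def semantic_diversity(
    space: SemanticSpace,
    cs: ContextSet,
    log_base: float = 10.0,
) -> float | None:
    """SemD = -log(mean pairwise cosine) over the word's context vectors.

    Returns None (a missing value) when the word has fewer than two contexts
    or the mean cosine is non-positive, which can occur in reduced spaces.
    """
    if len(cs) < 2:
        logger.warning("SemD undefined for %r: fewer than 2 contexts", cs.word)
        return None
    vecs = space.context_rows(list(cs.context_ids))
    mean_cos = mean_pairwise_cosine(vecs)
    if mean_cos <= 0.0:
        logger.warning("SemD undefined for %r: mean pairwise cosine %.4g <= 0", cs.word, mean_cos)
        return None
    return -math.log(mean_cos, log_base)
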