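"""LSA semantic space: word-by-context counts, log weighting, truncated SVD.

The co-occurrence matrix has one row per retained vocabulary type and one
column per context; entry (w, c) counts occurrences of w in c.  Counts are
damped with ln(1 + c) so that high-frequency types do not dominate, and the
matrix is reduced to ``d`` dimensions (default 300) with a truncated SVD
X ~ U S V'.  Word vectors are rows of U.S and context vectors rows of V.S;
scaling by the singular values makes cosines between full-rank context
vectors identical to cosines between the raw weighted columns, which gives
the reduction a directly testable oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

from .corpus import ContextCollection, Vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "CooccurrenceMatrix",
    "SemanticSpace",
    "build_cooccurrence",
    "weight_matrix",
    "reduce_dimensions",
    "cosine",
]

#: below this max(n_rows, n_cols) an exact dense SVD is used instead of the
#: seeded randomized solver
DENSE_SVD_THRESHOLD = 600


@dataclass(frozen=True)
class CooccurrenceMatrix:
    counts: sp.csr_matrix
    words: tuple[str, ...]
    context_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n_rows, n_cols = self.counts.shape
        if n_rows != len(self.words) or n_cols != len(self.context_ids):
            raise ValueError("matrix shape does not match index lengths")

    @property
    def row_index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.words)}

    @property
    def col_index(self) -> dict[str, int]:
        return {c: j for j, c in enumerate(self.context_ids)}


@dataclass(frozen=True)
class SemanticSpace:
    """Reduced-dimension word and context vectors with their singular values."""

    word_vectors: np.ndarray  # (n_words, d)
    context_vectors: np.ndarray  # (n_contexts, d)
    singular_values: np.ndarray  # (d,), non-increasing
    words: tuple[str, ...]
    context_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        s = self.singular_values
        if np.any(np.diff(s) > 1e-9 * max(1.0, float(s[0]))):
            raise ValueError("singular values must be non-increasing")
        if not (np.all(np.isfinite(self.word_vectors)) and np.all(np.isfinite(self.context_vectors))):
            raise ValueError("non-finite entries in reduced vectors")

    @property
    def d(self) -> int:
        return int(self.singular_values.shape[0])

    def context_rows(self, context_ids: list[str]) -> np.ndarray:
        idx = self.col_index
        return self.context_vectors[[idx[c] for c in context_ids]]

    @property
    def col_index(self) -> dict[str, int]:
        return {c: j for j, c in enumerate(self.context_ids)}

    # -- serialization (plain-text directory layout) --------------------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "singular_values.tsv", self.singular_values, fmt="%.12g")
        np.savetxt(outdir / "word_vectors.tsv", self.word_vectors, fmt="%.12g", delimiter="\t")
        np.savetxt(outdir / "context_vectors.tsv", self.context_vectors, fmt="%.12g", delimiter="\t")
        (outdir / "words.txt").write_text("\n".join(self.words) + "\n", encoding="utf-8")
        (outdir / "context_ids.txt").write_text("\n".join(self.context_ids) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, indir: str | Path) -> "SemanticSpace":
        indir = Path(indir)
        sv = np.atleast_1d(np.loadtxt(indir / "singular_values.tsv"))
        wv = np.atleast_2d(np.loadtxt(indir / "word_vectors.tsv", delimiter="\t"))
        cv = np.atleast_2d(np.loadtxt(indir / "context_vectors.tsv", delimiter="\t"))
        words = tuple((indir / "words.txt").read_text(encoding="utf-8").splitlines())
        ctx = tuple((indir / "context_ids.txt").read_text(encoding="utf-8").splitlines())
        return cls(wv, cv, sv, words, ctx)


def build_cooccurrence(contexts: ContextCollection, vocab: Vocabulary) -> CooccurrenceMatrix:
    """Count retained-word occurrences per context; drop all-OOV columns."""
    widx = vocab.index
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    kept_ids: list[str] = []
    j = 0
    for c in contexts.contexts:
        cell: dict[int, int] = {}
        for t in c.tokens:
            i = widx.get(t)
            if i is not None:
                cell[i] = cell.get(i, 0) + 1
        if not cell:
            logger.warning("context %s has no in-vocabulary token; column dropped", c.context_id)
            continue
        for i, n in sorted(cell.items()):
            rows.append(i)
            cols.append(j)
            data.append(n)
        kept_ids.append(c.context_id)
        j += 1
    m = sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), (rows, cols)),
        shape=(len(vocab), j),
    )
    return CooccurrenceMatrix(m, vocab.types, tuple(kept_ids))


def weight_matrix(m: CooccurrenceMatrix) -> sp.csr_matrix:
    """ln(1 + count) damping; zeros stay zero so sparsity is preserved."""
    w = m.counts.copy().astype(np.float64)
    w.data = np.log1p(w.data)
    return w


def reduce_dimensions(
    weighted: sp.spmatrix | np.ndarray,
    d: int = 300,
    seed: int = 0,
    words: tuple[str, ...] | None = None,
    context_ids: tuple[str, ...] | None = None,
) -> SemanticSpace:
    """Truncated SVD of the weighted matrix into a ``d``-dimensional space.

    ``d`` is capped at min(n_words, n_contexts) with a warning.  Small
    matrices are decomposed exactly (dense LAPACK SVD); larger ones use the
    seeded randomized solver.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    n_rows, n_cols = weighted.shape
    cap = min(n_rows, n_cols)
    if d > cap:
        logger.warning("d=%d exceeds min(matrix shape)=%d; capping", d, cap)
        d = cap
    if max(n_rows, n_cols) <= DENSE_SVD_THRESHOLD:
        dense = weighted.toarray() if sp.issparse(weighted) else np.asarray(weighted, float)
        U, s, Vt = np.linalg.svd(dense, full_matrices=False)
        U, s, Vt = U[:, :d], s[:d], Vt[:d]
    else:
        U, s, Vt = randomized_svd(weighted, n_components=d, random_state=seed, n_iter=7)
    if not np.all(np.isfinite(s)):
        raise FloatingPointError("SVD produced non-finite singular values")
    words = words if words is not None else tuple(f"w{i}" for i in range(n_rows))
    context_ids = context_ids if context_ids is not None else tuple(f"c{j}" for j in range(n_cols))
    return SemanticSpace(
        word_vectors=U * s,
        context_vectors=Vt.T * s,
        singular_values=s,
        words=words,
        context_ids=context_ids,
    )


def reduce_cooccurrence(m: CooccurrenceMatrix, d: int = 300, seed: int = 0) -> SemanticSpace:
    """Convenience: weight then reduce, carrying word/context indices along."""
    return reduce_dimensions(weight_matrix(m), d=d, seed=seed, words=m.words, context_ids=m.context_ids)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two vectors; errors on a zero-norm input."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))
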