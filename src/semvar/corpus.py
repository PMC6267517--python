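"""Corpus ingestion, token filtering, chunking into contexts, and vocabulary building.

The unit of analysis throughout the package is the *context*: a fixed-size
chunk (default 150 tokens) cut from a pre-segmented document.  All diversity
measures downstream are defined over contexts, not documents, so that very
long documents do not dominate the co-occurrence statistics.
"""

from __future__ import annotations

import logging
import math
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TokenizedCorpus",
    "TokenFilterSpec",
    "Context",
    "ContextCollection",
    "Vocabulary",
    "read_corpus",
    "preprocess",
    "chunk_documents",
    "build_vocabulary",
]


class CorpusError(ValueError):
    """Raised for unreadable, empty, or structurally invalid corpus input."""


@dataclass(frozen=True)
class TokenizedCorpus:
    """An ordered collection of whitespace-tokenized documents."""

    documents: tuple[tuple[str, ...], ...]
    doc_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.documents) != len(self.doc_ids):
            raise CorpusError("documents and doc_ids length mismatch")
        if len(set(self.doc_ids)) != len(self.doc_ids):
            raise CorpusError("doc_ids must be unique")
        for did, doc in zip(self.doc_ids, self.documents):
            if not doc:
                raise CorpusError(f"empty document: {did!r}")

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_tokens(self) -> int:
        return sum(len(d) for d in self.documents)


_MARKUP_RE = re.compile(r"^</?[A-Za-z][^>]*/?>$")
_NUMERIC_RE = re.compile(r"^[+-]?[\d.,%:/]*\d[\d.,%:/]*$")
_ALPHA_RE = re.compile(r"^[A-Za-z]+$")

#: Token classes recognised by the default classifier.
TOKEN_CLASSES = ("markup", "numeric", "alphabetic", "punctuation", "symbol", "name", "word")

#: Classes removed by default before building the space: numbers, symbols,
#: markup tags, names, punctuation and bare alphabetic strings.
DEFAULT_DROP_CLASSES = frozenset(
    {"numeric", "symbol", "markup", "name", "punctuation", "alphabetic"}
)


def _char_category_class(token: str) -> str | None:
    """Classify by uniform Unicode major category: P* -> punctuation, S* -> symbol."""
    cats = {unicodedata.category(ch)[0] for ch in token}
    if cats == {"P"}:
        return "punctuation"
    if cats == {"S"}:
        return "symbol"
    if cats <= {"P", "S"}:
        return "symbol"
    return None


@dataclass(frozen=True)
class TokenFilterSpec:
    """Rule-based token classification and the set of classes to drop.

    The classifier is total: every token maps to exactly one class.  Named
    entities cannot be detected from the surface string alone, so the
    ``name`` class is driven by an optional user-supplied stoplist.
    """

    drop_classes: frozenset[str] = DEFAULT_DROP_CLASSES
    name_stoplist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.drop_classes) - set(TOKEN_CLASSES)
        if unknown:
            raise CorpusError(f"unknown token classes in drop_classes: {sorted(unknown)}")

    def classify(self, token: str) -> str:
        if _MARKUP_RE.match(token):
            return "markup"
        if _NUMERIC_RE.match(token):
            return "numeric"
        if _ALPHA_RE.match(token):
            return "alphabetic"
        cat = _char_category_class(token)
        if cat is not None:
            return cat
        if token in self.name_stoplist:
            return "name"
        return "word"


@dataclass(frozen=True)
class Context:
    """One chunk of one document; the atomic unit of the semantic space."""

    doc_id: str
    chunk_index: int
    tokens: tuple[str, ...]

    @property
    def context_id(self) -> str:
        return f"{self.doc_id}#{self.chunk_index}"


@dataclass(frozen=True)
class ContextCollection:
    contexts: tuple[Context, ...]
    chunk_size: int

    def __post_init__(self) -> None:
        for c in self.contexts:
            if not c.tokens:
                raise CorpusError(f"empty context {c.context_id}")

    @property
    def n_contexts(self) -> int:
        return len(self.contexts)

    def context_ids(self) -> list[str]:
        return [c.context_id for c in self.contexts]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("context_id\tdoc_id\tchunk_index\tn_tokens\ttokens\n")
            for c in self.contexts:
                fh.write(
                    f"{c.context_id}\t{c.doc_id}\t{c.chunk_index}\t{len(c.tokens)}\t"
                    + " ".join(c.tokens)
                    + "\n"
                )


@dataclass(frozen=True)
class Vocabulary:
    """Retained word types after the frequency filters.

    Types occurring fewer than ``min_count`` times are removed first; then the
    ``ceil(top_fraction * n_remaining)`` most frequent remaining types are
    excluded, with frequency ties broken lexicographically (earlier token
    treated as more frequent) so the cut is deterministic.
    """

    types: tuple[str, ...]
    total_counts: Mapping[str, int]
    top_fraction: float
    min_count: int
    index: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", {w: i for i, w in enumerate(self.types)})

    def __len__(self) -> int:
        return len(self.types)

    def __contains__(self, word: str) -> bool:
        return word in self.index


def read_corpus(path: str | Path, layout: str = "lines") -> TokenizedCorpus:
    """Read a whitespace-tokenized UTF-8 corpus.

    layout="lines": one document per non-blank line of a single file.
    layout="files": one document per file in a directory, ordered by filename.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"corpus path does not exist: {path}")
    docs: list[tuple[str, ...]] = []
    ids: list[str] = []
    if layout == "lines":
        if path.is_dir():
            raise CorpusError(f"layout 'lines' needs a file, got directory: {path}")
        try:
            text = path.read_text(encoding="utf-8")
        except (OSError, UnicodeDecodeError) as exc:
            raise CorpusError(f"unreadable corpus file {path}: {exc}") from exc
        for i, line in enumerate(text.splitlines()):
            toks = tuple(line.split())
            if toks:
                docs.append(toks)
                ids.append(f"{path.stem}:{i:06d}")
    elif layout == "files":
        if not path.is_dir():
            raise CorpusError(f"layout 'files' needs a directory, got file: {path}")
        for fp in sorted(p for p in path.iterdir() if p.is_file()):
            try:
                toks = tuple(fp.read_text(encoding="utf-8").split())
            except (OSError, UnicodeDecodeError) as exc:
                raise CorpusError(f"unreadable corpus file {fp}: {exc}") from exc
            if toks:
                docs.append(toks)
                ids.append(fp.name)
    else:
        raise CorpusError(f"unknown layout {layout!r}; expected 'lines' or 'files'")
    if not docs:
        raise CorpusError(f"empty corpus: {path}")
    return TokenizedCorpus(tuple(docs), tuple(ids))


def preprocess(corpus: TokenizedCorpus, spec: TokenFilterSpec | None = None) -> TokenizedCorpus:
    """Remove tokens whose class is in ``spec.drop_classes``; drop emptied documents."""
    spec = spec if spec is not None else TokenFilterSpec()
    docs: list[tuple[str, ...]] = []
    ids: list[str] = []
    for did, doc in zip(corpus.doc_ids, corpus.documents):
        kept = tuple(t for t in doc if spec.classify(t) not in spec.drop_classes)
        if kept:
            docs.append(kept)
            ids.append(did)
        else:
            logger.warning("document %r emptied by token filtering; dropped", did)
    if not docs:
        raise CorpusError("all documents emptied by token filtering")
    return TokenizedCorpus(tuple(docs), tuple(ids))


def chunk_documents(corpus: TokenizedCorpus, chunk_size: int = 150) -> ContextCollection:
    """Cut each document into consecutive non-overlapping ``chunk_size`` blocks.

    A final remainder block of any positive length is kept as its own context,
    so re-concatenating a document's chunks restores it token-for-token.
    """
    if chunk_size < 1:
        raise CorpusError(f"chunk_size must be >= 1, got {chunk_size}")
    contexts: list[Context] = []
    for did, doc in zip(corpus.doc_ids, corpus.documents):
        for ci, start in enumerate(range(0, len(doc), chunk_size)):
            contexts.append(Context(did, ci, tuple(doc[start : start + chunk_size])))
    return ContextCollection(tuple(contexts), chunk_size)


def build_vocabulary(
    contexts: ContextCollection,
    top_fraction: float = 0.03,
    min_count: int = 5,
) -> Vocabulary:
    if contexts.n_contexts == 0:
        raise CorpusError("cannot build a vocabulary from an empty context collection")
    if not 0.0 <= top_fraction < 1.0:
        raise CorpusError(f"top_fraction must be in [0, 1), got {top_fraction}")
    counts = Counter()
    for c in contexts.contexts:
        counts.update(c.tokens)
    eligible = [(w, n) for w, n in counts.items() if n >= min_count]
    # sort: most frequent first; lexicographically earlier token wins ties
    eligible.sort(key=lambda wn: (-wn[1], wn[0]))
    n_cut = math.ceil(top_fraction * len(eligible))
    retained = eligible[n_cut:]
    if not retained:
        raise CorpusError(
            f"vocabulary empty after filtering (min_count={min_count}, "
            f"top_fraction={top_fraction})"
        )
    return Vocabulary(
        types=tuple(w for w, _ in retained),
        total_counts={w: n for w, n in retained},
        top_fraction=top_fraction,
        min_count=min_count,
    )
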