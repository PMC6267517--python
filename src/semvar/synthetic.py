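"""Synthetic topic-structured corpora with planted ambiguity ground truth.

The generator emulates the geometry the ambiguity measures assume: documents
are drawn from unigram topic distributions; topics belong to *families* of
related topics whose distributions are convexly mixed (total sibling weight
``topic_correlation``), so contexts from the same family overlap; topics in
different families share no vocabulary.  Planted words come in three
classes:

- ``unambiguous``: emitted in documents of a single topic (one tight cloud);
- ``polyseme``: emitted in documents of several correlated topics of one
  family (one broad, connected cloud — many related senses);
- ``homonym``: emitted in documents of two topics from *different* families
  (two unrelated context clusters — distinct meanings).

Both ambiguous classes spread over wide regions of the space, so both are
highly semantically diverse; what distinguishes them is substructure: the
homonym region is split in two, the polyseme region is connected.  Per-class
emission rates are set so the expected number of contexts (contextual
diversity) is matched between homonyms and polysemes, making any SemVar
difference a matter of cluster geometry alone.

Tokens are plain ASCII identifiers; nothing downstream is script-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import TokenizedCorpus

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedWord",
    "SyntheticSpec",
    "GroundTruth",
    "SeparationReport",
    "default_spec",
    "generate_corpus",
    "sample_directional_clusters",
    "evaluate_separation",
]

CLASSES = ("unambiguous", "polyseme", "homonym")


@dataclass(frozen=True)
class PlantedWord:
    """A planted word, its class, its generating topics and their weights.

    ``weights`` (normalized internally) set how the word's occurrences are
    apportioned across its topics: unbalanced homonyms have a dominant
    meaning, polysemes may favour core senses.  Uniform when omitted.
    """

    word: str
    word_class: str  # one of CLASSES
    topics: tuple[int, ...]
    weights: tuple[float, ...] | None = None

    def topic_weights(self) -> tuple[float, ...]:
        if self.weights is None:
            return tuple(1.0 / len(self.topics) for _ in self.topics)
        if len(self.weights) != len(self.topics) or min(self.weights) <= 0:
            raise ValueError(f"{self.word}: weights must be positive, one per topic")
        s = sum(self.weights)
        return tuple(w / s for w in self.weights)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; the defaults define the standard study corpus."""

    n_topics: int = 8
    family_size: int = 4
    vocab_per_topic: int = 100
    n_documents: int = 240
    doc_length: int = 300
    topic_correlation: float = 0.4
    target_rate: float = 0.005
    planted_words: tuple[PlantedWord, ...] = ()
    chunk_size: int = 150
    min_contexts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family_size < 1 or self.n_topics % self.family_size != 0:
            raise ValueError("n_topics must be a multiple of family_size >= 1")
        if not 0.0 <= self.topic_correlation <= 1.0:
            raise ValueError("topic_correlation must be in [0, 1]")
        for pw in self.planted_words:
            if pw.word_class not in CLASSES:
                raise ValueError(f"unknown planted class {pw.word_class!r}")
            fams = {t // self.family_size for t in pw.topics}
            if pw.word_class == "unambiguous" and len(pw.topics) != 1:
                raise ValueError(f"{pw.word}: unambiguous words take exactly 1 topic")
            if pw.word_class == "homonym" and (len(pw.topics) != 2 or len(fams) != 2):
                raise ValueError(f"{pw.word}: homonyms take 2 topics from different families")
            if pw.word_class == "polyseme" and (len(pw.topics) < 2 or len(fams) != 1):
                raise ValueError(f"{pw.word}: polysemes take >= 2 topics of one family")

    @property
    def n_families(self) -> int:
        return self.n_topics // self.family_size

    def emission_rates(self, pw: PlantedWord) -> dict[int, float]:
        """Per-topic token emission rates for one planted word.

        With per-context hit probability p(r) = 1 - (1 - r)^chunk_size, a
        word expects sum_t n_topic_contexts * p(r_t) contexts.  Rates are
        solved so that sum_t p(r_t) = 2 * p(target_rate) for every word —
        the balanced two-topic baseline — keeping expected contextual
        diversity matched across classes and weight profiles.
        """
        p_base = 1.0 - (1.0 - self.target_rate) ** self.chunk_size
        rates: dict[int, float] = {}
        for t, w in zip(pw.topics, pw.topic_weights()):
            p_want = min(0.95, 2.0 * p_base * w)
            rates[t] = 1.0 - (1.0 - p_want) ** (1.0 / self.chunk_size)
        return rates


@dataclass(frozen=True)
class GroundTruth:
    """Per planted word: class and generating topics; per document: base topic."""

    planted: tuple[PlantedWord, ...]
    doc_topics: dict[str, int] = field(default_factory=dict)

    def classes(self) -> dict[str, str]:
        return {p.word: p.word_class for p in self.planted}

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("word\tclass\ttopics\n")
            for p in self.planted:
                fh.write(f"{p.word}\t{p.word_class}\t{','.join(map(str, p.topics))}\n")


def default_spec(
    n_homonyms: int = 30,
    n_polysemes: int = 30,
    n_unambiguous: int = 15,
    seed: int = 0,
    **overrides,
) -> SyntheticSpec:
    """The standard planted-word layout: 8 topics in 2 families of 4.

    The planted lexicon is deliberately heterogeneous, as real lexicons are:
    homonyms vary in meaning dominance (50/50 to 80/20 between their two
    unrelated meanings) and polysemes vary in number of senses (2 up to
    family_size correlated topics), so within-class score variance reflects
    genuine lexical variety rather than sampling noise alone.
    """
    base = SyntheticSpec(seed=seed, **overrides)
    fs, nf = base.family_size, base.n_families
    planted: list[PlantedWord] = []
    # homonyms: one topic from each of two different families, cycling over
    # all (family pair, member, member) combinations and dominance profiles
    fam_pairs = [(a, b) for a in range(nf) for b in range(a + 1, nf)]
    combos = [
        (fa * fs + i, fb * fs + j)
        for fa, fb in fam_pairs
        for i in range(fs)
        for j in range(fs)
    ]
    dominance = (0.5, 0.6, 0.7, 0.8)
    for i in range(n_homonyms):
        alpha = dominance[i % len(dominance)]
        planted.append(PlantedWord(
            f"hom{i:03d}", "homonym", combos[i % len(combos)], (alpha, 1.0 - alpha)
        ))
    sense_counts = tuple(range(2, fs + 1))
    for i in range(n_polysemes):
        f = i % nf
        k = sense_counts[i % len(sense_counts)]
        start = (i // nf) % fs
        planted.append(PlantedWord(
            f"pol{i:03d}", "polyseme",
            tuple(f * fs + (start + j) % fs for j in range(k)),
        ))
    for i in range(n_unambiguous):
        planted.append(PlantedWord(f"una{i:03d}", "unambiguous", (i % base.n_topics,)))
    return replace(base, planted_words=tuple(planted))


def _topic_distributions(spec: SyntheticSpec) -> tuple[list[str], np.ndarray]:
    """Vocabulary and per-base-topic token distributions (planted mass included)."""
    vocab: list[str] = []
    for t in range(spec.n_topics):
        vocab.extend(f"t{t}w{j:03d}" for j in range(spec.vocab_per_topic))
    planted_names = [p.word for p in spec.planted_words]
    vocab.extend(planted_names)
    v_index = {w: i for i, w in enumerate(vocab)}

    # mildly skewed within-topic unigram so the corpus has a frequency spread
    j = np.arange(spec.vocab_per_topic, dtype=float)
    base_w = (j + 1.0) ** -0.8
    base_w /= base_w.sum()

    topic_bg = np.zeros((spec.n_topics, len(vocab)))
    for t in range(spec.n_topics):
        lo = t * spec.vocab_per_topic
        topic_bg[t, lo : lo + spec.vocab_per_topic] = base_w

    rho = spec.topic_correlation
    fs = spec.family_size
    dists = np.zeros_like(topic_bg)
    for t in range(spec.n_topics):
        fam = t // fs
        siblings = [s for s in range(fam * fs, (fam + 1) * fs) if s != t]
        if siblings:
            mixed = (1.0 - rho) * topic_bg[t]
            for s in siblings:
                mixed = mixed + (rho / len(siblings)) * topic_bg[s]
        else:
            mixed = topic_bg[t]  # singleton family: nothing to mix with
        planted_here = [p for p in spec.planted_words if t in p.topics]
        rates = {p.word: spec.emission_rates(p)[t] for p in planted_here}
        planted_mass = sum(rates.values())
        if planted_mass >= 1.0:
            raise ValueError("target_rate too high: planted mass >= 1 for a topic")
        dists[t] = mixed * (1.0 - planted_mass)
        for p in planted_here:
            dists[t, v_index[p.word]] = rates[p.word]
    return vocab, dists


def _emit(spec: SyntheticSpec, seed: int) -> tuple[TokenizedCorpus, GroundTruth]:
    rng = np.random.default_rng(seed)
    vocab, dists = _topic_distributions(spec)
    vocab_arr = np.asarray(vocab, dtype=object)
    docs: list[tuple[str, ...]] = []
    ids: list[str] = []
    doc_topics: dict[str, int] = {}
    for i in range(spec.n_documents):
        t = i % spec.n_topics  # balanced topic coverage
        toks = rng.choice(vocab_arr, size=spec.doc_length, p=dists[t])
        did = f"doc{i:05d}"
        docs.append(tuple(toks))
        ids.append(did)
        doc_topics[did] = t
    corpus = TokenizedCorpus(tuple(docs), tuple(ids))
    return corpus, GroundTruth(planted=spec.planted_words, doc_topics=doc_topics)


def _planted_context_counts(spec: SyntheticSpec, corpus: TokenizedCorpus) -> dict[str, int]:
    counts = {p.word: 0 for p in spec.planted_words}
    for doc in corpus.documents:
        for start in range(0, len(doc), spec.chunk_size):
            chunk = set(doc[start : start + spec.chunk_size])
            for w in counts:
                if w in chunk:
                    counts[w] += 1
    return counts


def generate_corpus(
    spec: SyntheticSpec, max_retries: int = 3
) -> tuple[TokenizedCorpus, GroundTruth]:
    """Emit a corpus; regenerate (bounded) if a planted word is under-represented."""
    last_bad: dict[str, int] = {}
    for attempt in range(max_retries):
        corpus, truth = _emit(spec, seed=spec.seed + 1_000_003 * attempt)
        counts = _planted_context_counts(spec, corpus)
        bad = {w: n for w, n in counts.items() if n < spec.min_contexts}
        if not bad:
            return corpus, truth
        last_bad = bad
        logger.warning("attempt %d: %d planted words below min_contexts; retrying",
                       attempt, len(bad))
    raise ValueError(
        "infeasible synthetic spec: planted words cannot reach "
        f"min_contexts={spec.min_contexts} at target_rate={spec.target_rate} "
        f"(worst offenders: {dict(sorted(last_bad.items())[:5])})"
    )


def sample_directional_clusters(
    g: int,
    n_per: int | tuple[int, int],
    d: int,
    noise: float = 0.15,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors from ``g`` well-separated directional clusters.

    Cluster means are g rows of a random orthogonal matrix (mutually
    orthogonal directions); members are mean + isotropic Gaussian noise,
    re-normalized.  Returns (vectors, labels).  Requires d >= g.
    """
    if d < g:
        raise ValueError(f"need d >= g, got d={d}, g={g}")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    means = q[:g]
    sizes = (
        np.full(g, n_per, dtype=int)
        if isinstance(n_per, int)
        else rng.integers(n_per[0], n_per[1] + 1, size=g)
    )
    vecs: list[np.ndarray] = []
    labels: list[int] = []
    for c in range(g):
        pts = means[c] + noise * rng.standard_normal((int(sizes[c]), d))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        vecs.append(pts)
        labels.extend([c] * int(sizes[c]))
    return np.vstack(vecs), np.asarray(labels)


@dataclass(frozen=True)
class SeparationReport:
    """Homonym-vs-polyseme separation of SemVar and SemD on planted words."""

    class_means: dict[str, dict[str, float]]  # measure -> class -> mean
    p_semvar_one_sided: float  # H1: SemVar(homonym) < SemVar(polyseme)
    p_semd_two_sided: float
    d_semvar: float  # standardized (polyseme - homonym) difference
    d_semd: float
    semvar_direction_ok: bool
    stronger_measure: str  # which measure separates the classes more

    def summary(self) -> str:
        lines = ["separation report (planted homonyms vs polysemes)"]
        for measure, means in self.class_means.items():
            per = ", ".join(f"{cls}={m:.4f}" for cls, m in sorted(means.items()))
            lines.append(f"  mean {measure}: {per}")
        lines.append(
            f"  SemVar hom<poly one-sided rank-sum p = {self.p_semvar_one_sided:.3g}"
            f" (direction {'ok' if self.semvar_direction_ok else 'REVERSED'})"
        )
        lines.append(f"  SemD two-sided rank-sum p = {self.p_semd_two_sided:.3g}")
        lines.append(
            f"  standardized differences: SemVar {self.d_semvar:.3f}, "
            f"SemD {self.d_semd:.3f} -> {self.stronger_measure} separates more strongly"
        )
        return "\n".join(lines)


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled == 0.0:
        return float("inf") if a.mean() != b.mean() else 0.0
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def evaluate_separation(records: pd.DataFrame, truth: GroundTruth) -> SeparationReport:
    """Compare planted homonyms and polysemes on SemVar and SemD.

    ``records`` is an ambiguity table with at least columns word, semd,
    semvar.  Requires >= 10 planted words per compared class and < 50%
    missing measures among planted words.
    """
    classes = truth.classes()
    df = records[records["word"].isin(classes)].copy()
    df["word_class"] = df["word"].map(classes)
    for cls in ("homonym", "polyseme"):
        if (df["word_class"] == cls).sum() < 10:
            raise ValueError(f"need >= 10 planted words of class {cls!r}")
    n_missing = df[["semd", "semvar"]].isna().any(axis=1).sum()
    if n_missing > 0.5 * len(df):
        raise ValueError(f"measures missing for {n_missing}/{len(df)} planted words")

    hom = df[df["word_class"] == "homonym"].dropna(subset=["semvar", "semd"])
    pol = df[df["word_class"] == "polyseme"].dropna(subset=["semvar", "semd"])
    sv_h, sv_p = hom["semvar"].to_numpy(), pol["semvar"].to_numpy()
    sd_h, sd_p = hom["semd"].to_numpy(), pol["semd"].to_numpy()

    p_sv = stats.mannwhitneyu(sv_h, sv_p, alternative="less").pvalue
    p_sd = stats.mannwhitneyu(sd_h, sd_p, alternative="two-sided").pvalue
    d_sv = _cohens_d(sv_p, sv_h)
    d_sd = _cohens_d(sd_p, sd_h)

    means: dict[str, dict[str, float]] = {"semvar": {}, "semd": {}}
    for cls, grp in df.groupby("word_class"):
        means["semvar"][str(cls)] = float(grp["semvar"].mean())
        means["semd"][str(cls)] = float(grp["semd"].mean())

    return SeparationReport(
        class_means=means,
        p_semvar_one_sided=float(p_sv),
        p_semd_two_sided=float(p_sd),
        d_semvar=d_sv,
        d_semd=d_sd,
        semvar_direction_ok=bool(sv_h.mean() < sv_p.mean()),
        stronger_measure="semvar" if abs(d_sv) >= abs(d_sd) else "semd",
    )
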