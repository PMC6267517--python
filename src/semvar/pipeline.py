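"""End-to-end pipeline: corpus -> space -> per-word ambiguity records.

The ambiguity record table has one row per requested word with CD, log CD,
SemD, the selected cluster count, within/between distances, SemVar, and
SemVarRes (SemVar residualized on log CD across the measured set).  Missing
values carry a reason code and are written as "NA" in the TSV output.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corpus as cio
from . import diversity, space as sp, variability
from .synthetic import SeparationReport, SyntheticSpec, evaluate_separation, generate_corpus

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "BuiltSpace", "build_space", "compute_measures",
           "simulate", "write_records", "SIMULATION_CONFIG"]

RECORD_COLUMNS = [
    "word", "cd", "log_cd", "semd", "k_best", "within", "between",
    "semvar", "semvar_res", "n_contexts_used", "missing_reason",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline knobs; serialized into every output directory for provenance."""

    chunk_size: int = 150
    top_fraction: float = 0.03
    min_count: int = 5
    svd_dim: int = 300
    context_cap: int = 2000
    k_max: int = 200
    sse_threshold: float = 0.9
    n_restarts: int = 10
    min_contexts: int = 10
    seed: int = 0
    log_base: float = 10.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


#: reduced-scale configuration used for synthetic-corpus studies (smaller
#: space and cluster search matched to corpora of a few hundred contexts)
SIMULATION_CONFIG = RunConfig(svd_dim=100, k_max=12, n_restarts=2)


@dataclass(frozen=True)
class BuiltSpace:
    matrix: sp.CooccurrenceMatrix
    space: sp.SemanticSpace
    vocab: cio.Vocabulary
    contexts: cio.ContextCollection


def build_space(corpus: cio.TokenizedCorpus, config: RunConfig = RunConfig(),
                filter_spec: cio.TokenFilterSpec | None = None) -> BuiltSpace:
    """Filter, chunk, count, weight, and reduce a corpus into an LSA space."""
    if filter_spec is not None:
        corpus = cio.preprocess(corpus, filter_spec)
    contexts = cio.chunk_documents(corpus, chunk_size=config.chunk_size)
    vocab = cio.build_vocabulary(contexts, top_fraction=config.top_fraction,
                                 min_count=config.min_count)
    matrix = sp.build_cooccurrence(contexts, vocab)
    weighted = sp.weight_matrix(matrix)
    space = sp.reduce_dimensions(weighted, d=config.svd_dim, seed=config.seed,
                                 words=matrix.words, context_ids=matrix.context_ids)
    logger.info("built space: %d words x %d contexts -> %d dims",
                len(matrix.words), len(matrix.context_ids), space.d)
    return BuiltSpace(matrix=matrix, space=space, vocab=vocab, contexts=contexts)


def _word_seed(config_seed: int, word: str) -> int:
    # stable per-word clustering seed, independent of wordlist order
    return (config_seed * 1_000_003 + zlib.crc32(word.encode("utf-8"))) % (2**31)


def compute_measures(
    built: BuiltSpace,
    words: list[str] | None = None,
    config: RunConfig = RunConfig(),
) -> tuple[pd.DataFrame, list[str]]:
    """Ambiguity records for ``words`` (default: the whole vocabulary).

    Returns (records, rejects): rejects are requested words absent from the
    vocabulary; the run continues without them.
    """
    if words is None:
        words = list(built.vocab.types)
    rejects = [w for w in words if w not in built.vocab]
    kept = [w for w in words if w in built.vocab]
    if rejects:
        logger.warning("%d requested words not in vocabulary", len(rejects))

    rows: list[dict] = []
    semvar_by_word: dict[str, float | None] = {}
    log_cd_by_word: dict[str, float] = {}
    for w in kept:
        cd, log_cd = diversity.contextual_diversity(built.matrix, w, log_base=config.log_base)
        cs = diversity.context_set(built.matrix, w, cap=config.context_cap)
        semd = diversity.semantic_diversity(built.space, cs, log_base=config.log_base)
        res = variability.semantic_variability(
            built.space, cs,
            k_max=config.k_max,
            sse_threshold=config.sse_threshold,
            n_restarts=config.n_restarts,
            min_contexts=config.min_contexts,
            seed=_word_seed(config.seed, w),
        )
        semvar_by_word[w] = res.semvar
        log_cd_by_word[w] = log_cd
        rows.append({
            "word": w, "cd": cd, "log_cd": log_cd, "semd": semd,
            "k_best": res.k_best, "within": res.within, "between": res.between,
            "semvar": res.semvar, "semvar_res": None,
            "n_contexts_used": res.n_contexts_used,
            "missing_reason": res.missing_reason,
        })

    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    n_ok = sum(v is not None for v in semvar_by_word.values())
    if n_ok >= 3 and len({round(v, 12) for w, v in log_cd_by_word.items()
                          if semvar_by_word[w] is not None}) > 1:
        scores = variability.residualize_semvar(semvar_by_word, log_cd_by_word)
        df["semvar_res"] = df["word"].map(scores.residuals)
    else:
        logger.warning("SemVarRes skipped: need >= 3 non-missing SemVar values "
                       "and a non-constant log CD")
    return df, rejects


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV serialization; missing values written as NA."""
    out = df.copy()
    for col in ("log_cd", "semd", "within", "between", "semvar", "semvar_res"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.10g}")
    for col in ("k_best",):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out["missing_reason"] = out["missing_reason"].map(lambda v: "NA" if pd.isna(v) else v)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Correlation matrix of log CD, SemD and SemVar over non-missing rows."""
    sub = df[["log_cd", "semd", "semvar"]].dropna()
    return sub.corr(method="pearson")


def simulate(
    spec: SyntheticSpec,
    config: RunConfig = SIMULATION_CONFIG,
    words: list[str] | None = None,
) -> tuple[pd.DataFrame, SeparationReport, "BuiltSpace"]:
    """Generate a planted-ambiguity corpus, run the pipeline, and evaluate
    homonym/polyseme separation.  ``words`` defaults to the planted words."""
    config = replace(config, seed=spec.seed, chunk_size=spec.chunk_size,
                     min_contexts=spec.min_contexts)
    corpus, truth = generate_corpus(spec)
    built = build_space(corpus, config)
    if words is None:
        words = [p.word for p in spec.planted_words]
    df, rejects = compute_measures(built, words=words, config=config)
    if rejects:
        logger.warning("planted words filtered out of vocabulary: %s", rejects)
    report = evaluate_separation(df, truth)
    return df, report, built
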