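"""From raw text to ambiguity scores, step by step.

Writes a small synthetic corpus to disk in the standard one-document-per-line
layout, then walks the library pipeline explicitly: read -> chunk -> filter
vocabulary -> count co-occurrences -> log-weight -> SVD -> per-word measures.
"""

import tempfile
from pathlib import Path

from semvar import (
    RunConfig,
    build_space,
    compute_measures,
    default_spec,
    generate_corpus,
    read_corpus,
)

# build a corpus file as a user of the tool would supply it
spec = default_spec(n_homonyms=10, n_polysemes=10, n_unambiguous=5,
                    n_documents=120, seed=7)
corpus, truth = generate_corpus(spec)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "corpus.txt"
    path.write_text(
        "\n".join(" ".join(doc) for doc in corpus.documents), encoding="utf-8"
    )

    corpus = read_corpus(path, layout="lines")
    print(f"read {corpus.n_documents} documents, {corpus.n_tokens} tokens")

    config = RunConfig(svd_dim=80, k_max=12, n_restarts=2, seed=7)
    built = build_space(corpus, config)
    print(f"contexts: {len(built.matrix.context_ids)} "
          f"(chunk size {config.chunk_size} tokens)")
    print(f"vocabulary: {len(built.vocab)} types "
          f"(min count {config.min_count}, top {config.top_fraction:.0%} removed)")
    print(f"space: {built.space.d} dimensions, "
          f"leading singular values {built.space.singular_values[:3].round(2)}")

    words = [p.word for p in spec.planted_words[:6]]
    records, rejects = compute_measures(built, words=words, config=config)
    print()
    print(records[["word", "cd", "log_cd", "semd", "k_best", "semvar"]]
          .to_string(index=False))
    print()
    print("cd = number of ~150-token contexts containing the word;")
    print("semd = -log10(mean pairwise context cosine): higher = more diverse;")
    print("semvar = within/between cluster distance ratio at the selected k.")
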