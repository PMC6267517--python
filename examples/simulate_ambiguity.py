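"""Planted homonyms vs polysemes: can the measures tell them apart?

Generates a topic-structured corpus in which 30 words have two unrelated
meanings (homonyms), 30 have several related senses (polysemes) and 15 are
unambiguous, runs the full pipeline (chunking, LSA, CD/SemD/SemVar), and
prints the separation report.

Expected pattern: homonyms and polysemes get similar, high SemD (both are
used in dissimilar contexts), but homonyms get clearly *lower* SemVar —
their contexts form tight, mutually distant clusters, while polyseme
contexts form one diffuse cloud.
"""

from semvar import default_spec, simulate

spec = default_spec(seed=42)
records, report, built = simulate(spec)

print(f"corpus: {spec.n_documents} documents, "
      f"{len(built.matrix.context_ids)} contexts, "
      f"{len(built.vocab)} vocabulary types, {built.space.d}-dim space")
print(report.summary())
print()
print(records[["word", "cd", "semd", "k_best", "semvar", "semvar_res"]]
      .head(8).to_string(index=False))
print("...")
print("Each row is one planted word: cd counts its contexts, semd its")
print("contextual dissimilarity, k_best the selected cluster count, and")
print("semvar the within/between cluster distance ratio (low = homonym-like).")
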