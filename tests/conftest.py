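import dataclasses

import numpy as np
import pytest

from semvar import SemanticSpace, default_spec
from semvar.pipeline import SIMULATION_CONFIG, build_space, compute_measures, simulate
from semvar.synthetic import generate_corpus


def make_space(context_vectors: np.ndarray, context_ids=None) -> SemanticSpace:
    """Wrap raw context vectors in a SemanticSpace for measure-level tests."""
    v = np.asarray(context_vectors, dtype=float)
    n, d = v.shape
    ids = tuple(context_ids) if context_ids is not None else tuple(f"c{i}" for i in range(n))
    return SemanticSpace(
        word_vectors=np.zeros((1, d)),
        context_vectors=v,
        singular_values=np.ones(d),
        words=("w0",),
        context_ids=ids,
    )


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic-corpus run (seed 1): records, report, built space."""
    return simulate(default_spec(seed=1))


@pytest.fixture(scope="session")
def built_default():
    """Built space for the default synthetic corpus (seed 1), without measures."""
    spec = default_spec(seed=1)
    cfg = dataclasses.replace(SIMULATION_CONFIG, seed=1)
    corpus, truth = generate_corpus(spec)
    return build_space(corpus, cfg), spec, truth, cfg
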