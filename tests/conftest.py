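import numpy as np
import pytest

from cohera.coherence import Response
from cohera.semantic_space import Corpus, SemanticSpace, build_space
from cohera.synthetic import DriftSpec, TopicModelSpec, generate_corpus, generate_responses


@pytest.fixture(scope="session")
def toy_space() -> SemanticSpace:
    """Hand-built 3-word orthogonal space for exact arithmetic checks."""
    return SemanticSpace(
        vocabulary={"alpha": 0, "beta": 1, "gamma": 2},
        vectors=np.array([[2.0, 0.0], [0.0, 2.0], [1.0, 1.0]]),
        k=2,
        weighting_stats={"alpha": 1.0, "beta": 1.0, "gamma": 1.0},
    )


@pytest.fixture(scope="session")
def two_topic_corpus() -> tuple[Corpus, list[int]]:
    spec = TopicModelSpec(n_topics=2, vocab_per_topic=30)
    return generate_corpus(spec, n_docs=20, seed=11)


@pytest.fixture(scope="session")
def topic_spec() -> TopicModelSpec:
    return TopicModelSpec()


@pytest.fixture(scope="session")
def trained_space(topic_spec) -> SemanticSpace:
    corpus, _ = generate_corpus(topic_spec, n_docs=64, seed=5)
    return build_space(corpus, k=10)


@pytest.fixture(scope="session")
def drifting_responses(topic_spec) -> list[Response]:
    responses, _ = generate_responses(
        0, DriftSpec(), n_participants=6, seed=7, topic_spec=topic_spec
    )
    return responses
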