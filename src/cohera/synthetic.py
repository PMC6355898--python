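"""Synthetic inputs with known ground truth for every pipeline stage.

Topic-structured corpora stand in for the training text behind the
semantic space; drifting responses emulate speakers who start on topic
and wander off as a 50-s production period progresses (about 10 words
per 5-s block); norms tables and measure tables with planted factor
structure feed the lexical and factor analyses; and BOLD volumes are
generated from a known design with spatially varying planted betas and
AR(1) noise, so recovery can be checked exactly.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coherence import Response
from .design import DesignMatrix
from .glm import BoldDataset
from .semantic_space import Corpus
from .speech_measures import NormsTable, NOUN_NORMS

__all__ = [
    "TopicModelSpec",
    "DriftSpec",
    "BoldSimSpec",
    "generate_corpus",
    "generate_responses",
    "generate_norms",
    "generate_factor_table",
    "generate_bold",
    "DEFAULT_FACTOR_LOADINGS",
]


@dataclass
class TopicModelSpec:
    """Per-topic unigram vocabularies with optional shared words."""

    n_topics: int = 8
    vocab_per_topic: int = 40
    shared_fraction: float = 0.0
    concentration: float = 1.0  # Dirichlet concentration of emission probs

    def __post_init__(self) -> None:
        if self.n_topics < 2:
            raise ValueError("need at least 2 topics")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")


@dataclass
class DriftSpec:
    """Linear decay of the on-topic word proportion across blocks.

    Defaults follow the elicitation protocol: 10 blocks of 5 s per
    response at roughly 10 words per block, starting fully on topic and
    losing 8% of on-topic probability per block.
    """

    p0: float = 1.0
    delta: float = 0.08
    words_per_block: int = 10
    n_blocks: int = 10
    block_length: float = 5.0
    excursion_length: int = 5  # off-topic words come in runs, not i.i.d.

    def __post_init__(self) -> None:
        if self.p0 - (self.n_blocks - 1) * self.delta < -1e-12:
            raise ValueError("drift would push the on-topic proportion below 0")


@dataclass
class BoldSimSpec:
    """Small-grid BOLD simulation with planted effects."""

    dims: tuple[int, int, int] = (20, 20, 20)
    tr: float = 2.2
    betas: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    ar1: float = 0.3
    active_fraction: float = 0.5  # fraction of voxels carrying the effect


def _topic_words(spec: TopicModelSpec) -> tuple[list[list[str]], list[str]]:
    n_shared = int(round(spec.vocab_per_topic * spec.shared_fraction))
    shared = [f"shared{j}" for j in range(n_shared)]
    topics = []
    for t in range(spec.n_topics):
        own = [f"t{t}w{j}" for j in range(spec.vocab_per_topic - n_shared)]
        topics.append(own + shared)
    return topics, shared


def generate_corpus(
    spec: TopicModelSpec, n_docs: int, seed: int,
    doc_length: int = 80,
) -> tuple[Corpus, list[int]]:
    """Documents drawn from per-topic unigram distributions.

    Returns the corpus and the ground-truth topic label of each
    document. Topics cycle deterministically so every topic is equally
    represented.
    """
    rng = np.random.default_rng(seed)
    topics, _ = _topic_words(spec)
    emission = [
        rng.dirichlet(np.full(len(words), spec.concentration))
        for words in topics
    ]
    docs, labels = [], []
    for d in range(n_docs):
        t = d % spec.n_topics
        words = rng.choice(topics[t], size=doc_length, p=emission[t])
        docs.append(list(words))
        labels.append(t)
    return Corpus(documents=docs), labels


def generate_responses(
    prompt_topic: int,
    drift: DriftSpec,
    n_participants: int,
    seed: int,
    topic_spec: TopicModelSpec | None = None,
    prompt_id: str = "prompt0",
) -> tuple[list[Response], pd.DataFrame]:
    """Drifting responses to one prompt, with per-block ground truth.

    Each word is on topic with probability p0 - (b-1)*delta for block b;
    off-topic words are drawn from one random alternative topic per
    excursion (runs of ``excursion_length`` words), so local coherence
    within an excursion stays high while global coherence falls. Word
    onsets are uniform at the words-per-block rate. Returns the
    responses and a table of true per-block on-topic proportions.
    """
    rng = np.random.default_rng(seed)
    topic_spec = topic_spec or TopicModelSpec()
    topics, _ = _topic_words(topic_spec)
    other_topics = [t for t in range(topic_spec.n_topics) if t != prompt_topic]
    period = drift.n_blocks * drift.block_length
    rate = drift.words_per_block / drift.block_length

    responses, truth_rows = [], []
    for p in range(n_participants):
        tokens: list[str] = []
        onsets: list[float] = []
        excursion_left = 0
        excursion_topic = prompt_topic
        for b in range(drift.n_blocks):
            p_on = max(0.0, drift.p0 - b * drift.delta)
            # off-topic words arrive in runs of excursion_length, so the
            # excursion-start hazard is deflated to keep the expected
            # off-topic share at 1 - p_on
            q = 1.0 - p_on
            L = drift.excursion_length
            hazard = q / (L - q * (L - 1))
            n_on = 0
            for w in range(drift.words_per_block):
                if excursion_left > 0:
                    topic = excursion_topic
                    excursion_left -= 1
                elif rng.random() >= hazard:
                    topic = prompt_topic
                else:
                    topic = int(rng.choice(other_topics))
                    excursion_topic = topic
                    excursion_left = L - 1
                if topic == prompt_topic:
                    n_on += 1
                tokens.append(str(rng.choice(topics[topic])))
                onsets.append((b * drift.words_per_block + w) / rate)
            truth_rows.append({
                "participant_id": f"p{p}",
                "block_index": b + 1,
                "true_on_topic": n_on / drift.words_per_block,
            })
        responses.append(Response(
            participant_id=f"p{p}",
            prompt_id=prompt_id,
            tokens=tokens,
            word_onsets=np.array(onsets),
            period_length=period,
        ))
    return responses, pd.DataFrame(truth_rows)


DEFAULT_FACTOR_LOADINGS = pd.DataFrame(
    {
        # four latent dimensions of spontaneous speech: lexical
        # complexity, semantic specificity, coherence, verbosity
        "complexity": [0.0, 0.0, 0.0, -0.75, 0.0, 0.75, 0.0, 0.75, 0.0, 0.0],
        "specificity": [0.0, 0.0, -0.75, 0.0, 0.75, 0.0, 0.75, 0.0, 0.0, 0.0],
        "coherence": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.75, 0.75],
        "verbosity": [0.75, -0.75, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    },
    index=[
        "n_words",
        "type_token_ratio",
        "closed_class_proportion",
        "noun_frequency_mean",
        "noun_concreteness_mean",
        "noun_aoa_mean",
        "noun_semd_mean",
        "noun_phonlen_mean",
        "local_coherence",
        "global_coherence",
    ],
)


def generate_norms(vocabulary: list[str], seed: int) -> NormsTable:
    """Random but reproducible lexical norms over a vocabulary.

    Roughly a third of the words are designated nouns and a disjoint
    fifth closed-class, mimicking the mix of function words and content
    words in running speech.
    """
    rng = np.random.default_rng(seed)
    vocab = sorted(set(vocabulary))
    n = len(vocab)
    norms = pd.DataFrame(
        {
            "frequency": rng.normal(3.0, 1.0, n),  # Zipf-style log scale
            "concreteness": rng.uniform(1.0, 5.0, n),
            "age_of_acquisition": rng.uniform(2.0, 12.0, n),
            "semantic_diversity": rng.uniform(0.5, 2.5, n),
            "phoneme_length": rng.integers(2, 12, n).astype(float),
        },
        index=vocab,
    )
    shuffled = list(rng.permutation(vocab))
    n_nouns = n // 3
    n_closed = n // 5
    return NormsTable(
        norms=norms,
        noun_list=set(shuffled[:n_nouns]),
        closed_class_list=set(shuffled[n_nouns:n_nouns + n_closed]),
    )


def generate_factor_table(
    n_blocks: int,
    seed: int,
    loadings: pd.DataFrame | None = None,
    noise_sd: float = 0.85,
    factor_corr: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure table with planted oblique factor structure.

    Block scores on k modestly correlated latent factors are projected
    through the planted loading matrix and unique noise is added, so a
    correctly implemented components analysis should recover the
    planted loadings. Returns (table, planted loadings).
    """
    rng = np.random.default_rng(seed)
    L = (loadings if loadings is not None else DEFAULT_FACTOR_LOADINGS)
    k = L.shape[1]
    phi = np.full((k, k), factor_corr)
    np.fill_diagonal(phi, 1.0)
    F = rng.multivariate_normal(np.zeros(k), phi, size=n_blocks)
    X = F @ L.to_numpy().T + rng.normal(0.0, noise_sd, (n_blocks, L.shape[0]))
    return pd.DataFrame(X, columns=L.index), L


def generate_bold(
    design: DesignMatrix, spec: BoldSimSpec, seed: int,
    effect_columns: dict[str, float] | None = None,
) -> tuple[BoldDataset, dict[str, np.ndarray]]:
    """BOLD volumes generated from a design with planted betas.

    ``effect_columns`` (or ``spec.betas``) maps design column names to
    planted amplitudes; each effect is carried by a reproducible random
    subset of voxels (``active_fraction``), zero elsewhere, giving
    spatially varying ground-truth beta images. AR(1) Gaussian noise of
    ``noise_sd`` is added. Returns the dataset and the beta images.
    """
    rng = np.random.default_rng(seed)
    X = design.matrix.to_numpy(dtype=float)
    n_vol = X.shape[0]
    dims = spec.dims
    n_vox = int(np.prod(dims))
    betas = effect_columns if effect_columns is not None else spec.betas
    beta_maps: dict[str, np.ndarray] = {}
    signal = np.zeros((n_vol, n_vox))
    for name, amp in betas.items():
        j = design.names.index(name)
        bmap = np.zeros(n_vox)
        active = rng.random(n_vox) < spec.active_fraction
        bmap[active] = amp
        beta_maps[name] = bmap.reshape(dims)
        signal += np.outer(X[:, j], bmap)
    noise = rng.standard_normal((n_vol, n_vox)) * spec.noise_sd
    if spec.noise_sd > 0 and abs(spec.ar1) > 0:
        for t in range(1, n_vol):
            noise[t] += spec.ar1 * noise[t - 1]
    data = (signal + noise).T.reshape(dims + (n_vol,))
    return (
        BoldDataset(
            data=data,
            affine=np.diag([2.0, 2.0, 2.0, 1.0]),
            mask=np.ones(dims, dtype=bool),
            tr=spec.tr,
        ),
        beta_maps,
    )
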