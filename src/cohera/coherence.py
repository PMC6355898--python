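"""Global and local coherence of connected speech.

Global coherence quantifies how strongly a stretch of speech relates to
the topic under discussion. For each word in a response, the passage
vector of the 20-word window ending at that word is compared, by cosine
similarity, with a prototype vector: the mean passage vector of all
OTHER speakers' responses to the same prompt (leave-one-out). Cosines
are clamped at zero and multiplied by 100, so 100 means speech identical
in semantic content to the typical response and 0 means no semantic
relationship with the topic.

Local coherence compares each window with the immediately preceding
non-overlapping window, capturing whether adjoining stretches of speech
relate to one another. The windowing of the local measure is this
package's reconstruction of the standard approach; see docs/methods.md.

For the imaging analysis each 50-s speech period is divided into 5-s
blocks and per-word values are averaged within blocks; the first block
of a response, which lacks enough prior speech, takes the second
block's value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .semantic_space import (
    PassageVector,
    SemanticSpace,
    cosine_similarity,
    passage_vector,
)

__all__ = [
    "Response",
    "PrototypeVector",
    "CoherenceSeries",
    "BlockCoherence",
    "prototype_vector",
    "global_coherence_series",
    "local_coherence_series",
    "block_coherence",
    "participant_mean_coherence",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 20  # words
DEFAULT_BLOCK_LENGTH = 5.0  # seconds
DEFAULT_PERIOD_LENGTH = 50.0  # seconds


class InsufficientDataError(ValueError):
    pass


@dataclass
class Response:
    """One participant's transcribed answer to one prompt.

    ``word_onsets`` are seconds from the start of the speech period; if
    absent, a uniform speaking rate over ``period_length`` is assumed.
    """

    participant_id: str
    prompt_id: str
    tokens: list[str]
    word_onsets: np.ndarray | None = None
    period_length: float = DEFAULT_PERIOD_LENGTH

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("tokens must be non-empty")
        if self.word_onsets is not None:
            self.word_onsets = np.asarray(self.word_onsets, dtype=float)
            if len(self.word_onsets) != len(self.tokens):
                raise ValueError("one onset per token required")
            if np.any(np.diff(self.word_onsets) < 0):
                raise ValueError("onsets must be non-decreasing")
            if self.word_onsets[0] < 0 or self.word_onsets[-1] > self.period_length:
                raise ValueError("onsets must lie within [0, period_length]")

    def onsets(self) -> np.ndarray:
        """Onsets, falling back to a uniform rate of n/period_length."""
        if self.word_onsets is not None:
            return self.word_onsets
        n = len(self.tokens)
        return np.arange(n) * (self.period_length / n)


@dataclass
class PrototypeVector:
    """Composite vector of the typical semantic content for a prompt."""

    prompt_id: str
    values: np.ndarray
    n_responses_averaged: int
    excluded_response_id: str | None = None


@dataclass
class CoherenceSeries:
    """Per-word coherence on the 0-100 scale.

    ``values[i]`` is defined only when a full window of prior words is
    available (index >= window_length - 1); undefined entries are NaN.
    ``raw_cosine`` keeps the unclamped cosine, which may be negative.
    """

    values: np.ndarray
    raw_cosine: np.ndarray
    window_length: int
    kind: str = "global"

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class BlockCoherence:
    block_index: int  # 1-based within the speech period
    value: float
    n_words_in_block: int
    substituted: bool = False


def prototype_vector(
    responses_to_prompt: list[Response],
    exclude: str,
    space: SemanticSpace,
) -> PrototypeVector:
    """Leave-one-out composite vector for a prompt.

    One passage vector per non-excluded response, averaged with equal
    weight per response (not per word). The excluded response's tokens
    contribute nothing.
    """
    vecs = []
    prompt_ids = {r.prompt_id for r in responses_to_prompt}
    if len(prompt_ids) > 1:
        raise ValueError(f"responses span multiple prompts: {sorted(prompt_ids)}")
    for r in responses_to_prompt:
        if r.participant_id == exclude:
            continue
        pv = passage_vector(space, r.tokens)
        if pv.defined:
            vecs.append(pv.values)
    if not vecs:
        raise InsufficientDataError(
            f"no eligible responses for prompt {prompt_ids} excluding {exclude}"
        )
    if len(vecs) == 1:
        warnings.warn(
            "prototype built from a single other response", stacklevel=2
        )
    return PrototypeVector(
        prompt_id=next(iter(prompt_ids)),
        values=np.mean(vecs, axis=0),
        n_responses_averaged=len(vecs),
        excluded_response_id=exclude,
    )


def _scored(cos: float) -> float:
    """Published reporting scale: clamp negative cosines, x100."""
    return 100.0 * max(0.0, cos)


def global_coherence_series(
    response: Response,
    prototype: PrototypeVector,
    space: SemanticSpace,
    window: int = DEFAULT_WINDOW,
) -> CoherenceSeries:
    """Moving-window global coherence, one value per word.

    For word index i (0-based), the window is tokens[i-window+1 .. i];
    the value is assigned to the final word of the window. Indices
    without a full window are undefined (NaN). A window whose tokens are
    all out of vocabulary yields an undefined value and is logged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(response.tokens)
    values = np.full(n, np.nan)
    raw = np.full(n, np.nan)
    for i in range(window - 1, n):
        pv = passage_vector(space, response.tokens[i - window + 1 : i + 1])
        if not pv.defined:
            logger.warning(
                "all-OOV window at word %d of %s/%s",
                i,
                response.participant_id,
                response.prompt_id,
            )
            continue
        c = cosine_similarity(pv.values, prototype.values)
        raw[i] = c
        values[i] = _scored(c)
    return CoherenceSeries(values=values, raw_cosine=raw, window_length=window,
                           kind="global")


def local_coherence_series(
    response: Response,
    space: SemanticSpace,
    window: int = DEFAULT_WINDOW,
) -> CoherenceSeries:
    """Window-to-previous-window local coherence.

    The window ending at word i is compared with the immediately
    preceding non-overlapping window (ending at i - window); values are
    defined from index 2*window - 1 onward.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(response.tokens)
    values = np.full(n, np.nan)
    raw = np.full(n, np.nan)
    for i in range(2 * window - 1, n):
        cur = passage_vector(space, response.tokens[i - window + 1 : i + 1])
        prev = passage_vector(
            space, response.tokens[i - 2 * window + 1 : i - window + 1]
        )
        if not (cur.defined and prev.defined):
            logger.warning("all-OOV window at word %d", i)
            continue
        c = cosine_similarity(cur.values, prev.values)
        raw[i] = c
        values[i] = _scored(c)
    return CoherenceSeries(values=values, raw_cosine=raw, window_length=window,
                           kind="local")


def block_coherence(
    series: CoherenceSeries,
    response: Response,
    block_length: float = DEFAULT_BLOCK_LENGTH,
) -> list[BlockCoherence]:
    """Average per-word values within 5-s blocks of the speech period.

    Words are assigned to blocks by onset time (half-open intervals
    [start, end)), with a uniform-rate fallback when onsets are absent.
    Block 1 always receives block 2's value, because too little prior
    speech exists for reliable estimates there. Any other block with no
    defined word values receives the nearest later defined block's
    value (logged).
    """
    n_blocks = int(np.ceil(response.period_length / block_length))
    if n_blocks < 2:
        raise InsufficientDataError("response period shorter than 2 blocks")
    onsets = response.onsets()
    block_of_word = np.minimum(
        (onsets / block_length).astype(int), n_blocks - 1
    )
    raw_means: list[float | None] = []
    counts: list[int] = []
    for b in range(n_blocks):
        in_block = series.values[block_of_word == b]
        in_block = in_block[~np.isnan(in_block)]
        counts.append(int(np.sum(block_of_word == b)))
        raw_means.append(float(np.mean(in_block)) if in_block.size else None)

    # first-block rule, then fill any undefined block from the nearest
    # later defined block
    filled: list[float] = [np.nan] * n_blocks
    substituted = [False] * n_blocks
    defined_idx = [b for b in range(n_blocks) if raw_means[b] is not None]
    if not defined_idx:
        raise InsufficientDataError("no block has a defined coherence value")
    for b in range(n_blocks):
        if b == 0 or raw_means[b] is None:
            later = [d for d in defined_idx if d >= max(b, 1)]
            src = later[0] if later else defined_idx[-1]
            if raw_means[b] is None and b > 0:
                logger.info("block %d undefined; using block %d", b + 1, src + 1)
            filled[b] = raw_means[src]  # type: ignore[assignment]
            substituted[b] = src != b
        else:
            filled[b] = raw_means[b]  # type: ignore[assignment]
    return [
        BlockCoherence(
            block_index=b + 1,
            value=filled[b],
            n_words_in_block=counts[b],
            substituted=substituted[b],
        )
        for b in range(n_blocks)
    ]


def participant_mean_coherence(
    all_block_values: list[list[BlockCoherence]],
) -> float:
    """Grand mean over all responses' block values, equal weight per block.

    Used as the individual-differences covariate at the second level.
    """
    if not all_block_values:
        raise InsufficientDataError("at least one response required")
    pooled = [b.value for blocks in all_block_values for b in blocks]
    return float(np.mean(pooled))
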