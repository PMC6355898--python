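"""Non-coherence speech characteristics per 5-s block.

For each block of speech: number of words, type:token ratio, proportion
of closed-class words, and the mean frequency, concreteness, age of
acquisition, semantic diversity and phoneme length of the nouns
produced. Nouns are identified by membership in a supplied noun list
(no POS tagger dependency), and lexical properties come from a norms
table keyed by the same token normalization as the semantic space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .semantic_space import normalize_token

__all__ = ["NormsTable", "BlockMeasures", "block_measures", "measure_correlations",
           "MEASURE_COLUMNS"]

NOUN_NORMS = ("frequency", "concreteness", "age_of_acquisition",
              "semantic_diversity", "phoneme_length")

MEASURE_COLUMNS = (
    "n_words",
    "type_token_ratio",
    "closed_class_proportion",
    "noun_frequency_mean",
    "noun_concreteness_mean",
    "noun_aoa_mean",
    "noun_semd_mean",
    "noun_phonlen_mean",
)


@dataclass
class NormsTable:
    """Lexical norms plus closed-class and noun word lists."""

    norms: pd.DataFrame  # index: word; columns: NOUN_NORMS
    closed_class_list: set[str]
    noun_list: set[str]

    def __post_init__(self) -> None:
        missing = [c for c in NOUN_NORMS if c not in self.norms.columns]
        if missing:
            raise ValueError(f"norms table missing columns: {missing}")
        if not np.isfinite(self.norms[list(NOUN_NORMS)].to_numpy()).all():
            raise ValueError("norms contain non-finite values")
        self.norms.index = [normalize_token(w) for w in self.norms.index]
        self.closed_class_list = {normalize_token(w) for w in self.closed_class_list}
        self.noun_list = {normalize_token(w) for w in self.noun_list}


@dataclass
class BlockMeasures:
    n_words: int
    type_token_ratio: float
    closed_class_proportion: float
    noun_frequency_mean: float  # NaN when the block has no listed nouns
    noun_concreteness_mean: float
    noun_aoa_mean: float
    noun_semd_mean: float
    noun_phonlen_mean: float
    local_coherence: float = np.nan
    global_coherence: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "n_words": self.n_words,
            "type_token_ratio": self.type_token_ratio,
            "closed_class_proportion": self.closed_class_proportion,
            "noun_frequency_mean": self.noun_frequency_mean,
            "noun_concreteness_mean": self.noun_concreteness_mean,
            "noun_aoa_mean": self.noun_aoa_mean,
            "noun_semd_mean": self.noun_semd_mean,
            "noun_phonlen_mean": self.noun_phonlen_mean,
            "local_coherence": self.local_coherence,
            "global_coherence": self.global_coherence,
        }


def block_measures(block_tokens: list[str], norms: NormsTable) -> BlockMeasures:
    """Lexical measures for one block of speech.

    Noun means average over tokens that are both in the noun list and
    present in the norms table; with no such token the noun means are
    NaN (flagged undefined, handled pairwise downstream).
    """
    if not block_tokens:
        raise ValueError("empty block")
    toks = [normalize_token(t) for t in block_tokens]
    n = len(toks)
    ttr = len(set(toks)) / n
    closed = sum(t in norms.closed_class_list for t in toks) / n
    nouns = [t for t in toks if t in norms.noun_list and t in norms.norms.index]
    if nouns:
        sub = norms.norms.loc[nouns, list(NOUN_NORMS)]
        means = sub.mean(axis=0)
    else:
        means = pd.Series({c: np.nan for c in NOUN_NORMS})
    return BlockMeasures(
        n_words=n,
        type_token_ratio=ttr,
        closed_class_proportion=closed,
        noun_frequency_mean=float(means["frequency"]),
        noun_concreteness_mean=float(means["concreteness"]),
        noun_aoa_mean=float(means["age_of_acquisition"]),
        noun_semd_mean=float(means["semantic_diversity"]),
        noun_phonlen_mean=float(means["phoneme_length"]),
    )


def measure_correlations(block_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between measures.

    A column with no variance gets NaN off-diagonal entries flagged via
    a unit diagonal: the diagonal is forced to 1 so the matrix remains
    interpretable, and constant columns are reported in the ``attrs``.
    """
    numeric = block_table.select_dtypes(include=[np.number])
    corr = numeric.corr(method="pearson", min_periods=3)
    constant = [c for c in numeric.columns
                if numeric[c].dropna().nunique() <= 1]
    np.fill_diagonal(corr.values, 1.0)
    corr.attrs["constant_columns"] = constant
    return corr
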