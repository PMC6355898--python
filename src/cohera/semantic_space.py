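"""Latent semantic analysis vector space for words and passages.

The space is built by singular value decomposition of a log-entropy
weighted term-document count matrix. Each retained vocabulary word is
represented by a k-dimensional row vector (left singular vectors scaled
by their singular values); a passage is represented by the mean of its
in-vocabulary word vectors. Semantic relatedness between passages is
measured by cosine similarity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import svds

__all__ = [
    "Corpus",
    "SemanticSpace",
    "PassageVector",
    "tokenize",
    "build_space",
    "word_vector",
    "passage_vector",
    "cosine_similarity",
    "save_space",
    "load_space",
]

_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize(text: str) -> list[str]:
    """Lowercase and strip punctuation; no stemming."""
    return _TOKEN_RE.findall(text.lower())


def normalize_token(token: str) -> str:
    """The normalization applied to every token at training and lookup."""
    return token.lower().strip()


@dataclass
class Corpus:
    """An ordered collection of tokenized documents.

    Invariants: at least 2 documents; tokens are non-empty lowercase
    strings (enforced at construction by normalizing).
    """

    documents: list[list[str]]
    doc_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.documents) < 2:
            raise ValueError("a corpus needs at least 2 documents")
        self.documents = [
            [normalize_token(t) for t in doc if normalize_token(t)]
            for doc in self.documents
        ]
        if not self.doc_ids:
            self.doc_ids = [f"doc{i}" for i in range(len(self.documents))]
        if len(self.doc_ids) != len(self.documents):
            raise ValueError("doc_ids length must match documents")

    @classmethod
    def from_lines(cls, path: str | Path) -> "Corpus":
        """One document per line, UTF-8."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        docs = [tokenize(ln) for ln in lines if ln.strip()]
        return cls(documents=docs)

    @classmethod
    def from_directory(cls, path: str | Path, pattern: str = "*.txt") -> "Corpus":
        files = sorted(Path(path).glob(pattern))
        docs = [tokenize(f.read_text(encoding="utf-8")) for f in files]
        return cls(documents=docs, doc_ids=[f.stem for f in files])


@dataclass
class SemanticSpace:
    """Word vectors from the weighted SVD, with the weights retained."""

    vocabulary: dict[str, int]
    vectors: np.ndarray  # |V| x k
    k: int
    weighting_stats: dict[str, float]  # per-term global (entropy) weight

    def __post_init__(self) -> None:
        if self.vectors.shape != (len(self.vocabulary), self.k):
            raise ValueError("vectors shape inconsistent with vocabulary and k")


@dataclass
class PassageVector:
    """Mean word vector of a passage; undefined when nothing contributed."""

    values: np.ndarray
    n_contributing: int

    @property
    def defined(self) -> bool:
        return self.n_contributing > 0


class DimensionalityError(ValueError):
    pass


class UndefinedSimilarityError(ValueError):
    pass


def _log_entropy_weights(counts: sparse.csr_matrix) -> np.ndarray:
    """Global entropy weight per term: 1 + sum_d p log p / log(n_docs).

    Terms appearing in every document with uniform probability get
    weight ~0; terms concentrated in few documents get weight near 1.
    """
    n_docs = counts.shape[1]
    gf = np.asarray(counts.sum(axis=1)).ravel()  # global frequency per term
    c = counts.tocoo()
    p = c.data / gf[c.row]  # stored entries are strictly positive
    plogp = np.zeros(counts.shape[0])
    np.add.at(plogp, c.row, p * np.log(p))
    return 1.0 + plogp / np.log(n_docs)


def build_space(
    corpus: Corpus,
    k: int,
    min_doc_freq: int = 1,
    weighting: str = "log-entropy",
) -> SemanticSpace:
    """Build the LSA space from a corpus.

    With the default ``log-entropy`` weighting the term-document count
    matrix is weighted as log(1 + count) times the per-term entropy
    weight, then decomposed by truncated SVD; word vectors are U * S
    rows. Terms whose entropy weight falls to zero (spread uniformly
    over all documents) are dropped from the vocabulary. ``weighting``
    may also be ``"log"`` (log counts, no global weight) or ``"raw"``.

    The SVD sign ambiguity is fixed by forcing the largest-magnitude
    loading of each component to be positive, so serialization is
    reproducible; cosines are unaffected.
    """
    if k < 1:
        raise DimensionalityError("k must be >= 1")
    # vocabulary by document frequency
    doc_freq: dict[str, int] = {}
    for doc in corpus.documents:
        for t in set(doc):
            doc_freq[t] = doc_freq.get(t, 0) + 1
    vocab = sorted(t for t, df in doc_freq.items() if df >= min_doc_freq)
    if not vocab:
        raise ValueError("empty vocabulary after frequency filtering")
    index = {t: i for i, t in enumerate(vocab)}

    rows, cols, vals = [], [], []
    for j, doc in enumerate(corpus.documents):
        counts: dict[int, int] = {}
        for t in doc:
            i = index.get(t)
            if i is not None:
                counts[i] = counts.get(i, 0) + 1
        for i, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    X = sparse.csr_matrix(
        (np.array(vals, dtype=float), (rows, cols)),
        shape=(len(vocab), len(corpus.documents)),
    )

    if weighting == "log-entropy":
        gweights = _log_entropy_weights(X)
    elif weighting in ("log", "raw"):
        gweights = np.ones(X.shape[0])
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    keep = gweights > 1e-12
    if not np.any(keep):
        raise ValueError("all terms reduced to zero weight")
    vocab = [t for t, kp in zip(vocab, keep) if kp]
    X = X[keep]
    gweights = gweights[keep]

    W = X.copy()
    if weighting != "raw":
        W.data = np.log1p(W.data)
    W = sparse.diags(gweights) @ W

    max_k = min(W.shape)
    if k > max_k:
        raise DimensionalityError(
            f"k={k} exceeds min(|V|, n_docs)={max_k} after filtering"
        )
    if k == max_k:
        # svds requires k < min(shape); fall back to dense SVD
        U, s, _ = np.linalg.svd(W.toarray(), full_matrices=False)
        U, s = U[:, :k], s[:k]
    else:
        # fixed start vector keeps the Lanczos iteration deterministic
        v0 = np.full(min(W.shape), 1.0 / np.sqrt(min(W.shape)))
        U, s, _ = svds(W, k=k, v0=v0)
        order = np.argsort(s)[::-1]
        U, s = U[:, order], s[order]

    # fix sign: largest-magnitude loading of each component positive
    for j in range(k):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]

    vectors = U * s
    return SemanticSpace(
        vocabulary={t: i for i, t in enumerate(vocab)},
        vectors=vectors,
        k=k,
        weighting_stats=dict(zip(vocab, gweights.tolist())),
    )


class OOV:
    """Singleton marker for out-of-vocabulary lookups."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "<OOV>"


OOV_MARKER = OOV()


def word_vector(space: SemanticSpace, token: str):
    """Row lookup after normalization; OOV returns a marker, never zeros."""
    i = space.vocabulary.get(normalize_token(token))
    if i is None:
        return OOV_MARKER
    return space.vectors[i]


def passage_vector(
    space: SemanticSpace, tokens: list[str], stoplist: set[str] | None = None
) -> PassageVector:
    """Mean of in-vocabulary word vectors (bag of words, order-invariant).

    An optional stoplist excludes words from the average without
    removing them from the space; by default nothing is excluded.
    """
    if not tokens:
        raise ValueError("tokens must be non-empty")
    acc = np.zeros(space.k)
    n = 0
    for t in tokens:
        tn = normalize_token(t)
        if stoplist and tn in stoplist:
            continue
        i = space.vocabulary.get(tn)
        if i is not None:
            acc += space.vectors[i]
            n += 1
    if n == 0:
        return PassageVector(values=np.full(space.k, np.nan), n_contributing=0)
    return PassageVector(values=acc / n, n_contributing=n)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Standard cosine in [-1, 1]; symmetric and scale-invariant."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0 or not (np.isfinite(nu) and np.isfinite(nv)):
        raise UndefinedSimilarityError("cosine undefined for zero vector")
    if np.array_equal(u, v):
        return 1.0  # avoid round-off at the exact-identity boundary
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def save_space(space: SemanticSpace, prefix: str | Path) -> None:
    """Two-file format: <prefix>.vocab.tsv and <prefix>.vectors.tsv.

    Vectors are written with full repr precision so the round trip is
    bit-exact.
    """
    prefix = Path(prefix)
    with open(f"{prefix}.vocab.tsv", "w", encoding="utf-8") as fh:
        fh.write("token\tindex\tglobal_weight\n")
        for t, i in sorted(space.vocabulary.items(), key=lambda kv: kv[1]):
            fh.write(f"{t}\t{i}\t{space.weighting_stats[t]:.17g}\n")
    np.savetxt(f"{prefix}.vectors.tsv", space.vectors, delimiter="\t",
               fmt="%.17g")


def load_space(prefix: str | Path) -> SemanticSpace:
    prefix = Path(prefix)
    vocab: dict[str, int] = {}
    weights: dict[str, float] = {}
    with open(f"{prefix}.vocab.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            t, i, w = line.rstrip("\n").split("\t")
            vocab[t] = int(i)
            weights[t] = float(w)
    vectors = np.loadtxt(f"{prefix}.vectors.tsv", delimiter="\t", ndmin=2)
    return SemanticSpace(
        vocabulary=vocab, vectors=vectors, k=vectors.shape[1], weighting_stats=weights
    )
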