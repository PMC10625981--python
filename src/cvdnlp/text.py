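"""Text preprocessing for the visit notes.

The pipeline order is fixed: lowercase → stop-word removal → stemming →
rare-token pruning → minimum-length filter.  The vocabulary is always
built on the training split only; held-out text is encoded against it,
with unseen tokens mapped to a dedicated out-of-vocabulary index.
Token-index sequences are right-padded (index 0) to a fixed length for
the recurrent classifier.
"""

from __future__ import annotations

import hashlib
import math
import string
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._stemmer import ItalianStemmer, stem_italian

__all__ = [
    "load_stopwords",
    "clean_and_stem",
    "Vocabulary",
    "build_vocabulary",
    "encode",
    "TextVectorizer",
    "PAD_INDEX",
    "OOV_INDEX",
    "MIN_TOKENS",
]

PAD_INDEX = 0
OOV_INDEX = 1
#: visits with fewer cleaned tokens than this are flagged not-retained
MIN_TOKENS = 3

_STRIP = string.punctuation + "’“”"


def load_stopwords() -> frozenset[str]:
    """The Italian stop-word list frozen into the package."""
    text = resources.files("cvdnlp").joinpath("data/stopwords_it.txt").read_text("utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def clean_and_stem(
    text: str,
    stopwords: frozenset[str] | set[str] | None = None,
    stemmer: ItalianStemmer | None = None,
) -> list[str]:
    """Lowercase, tokenise on whitespace, drop stop words, stem.

    Stop words are removed before stemming (so inflected stop words are
    matched in surface form, as in the standard lists).  Punctuation is
    stripped from token edges; tokens that vanish are dropped.
    """
    stopwords = load_stopwords() if stopwords is None else stopwords
    stem = (stemmer or _DEFAULT_STEMMER).stem
    out: list[str] = []
    for raw in text.lower().split():
        token = raw.strip(_STRIP)
        if not token or token in stopwords:
            continue
        out.append(stem(token))
    return out


_DEFAULT_STEMMER = ItalianStemmer()


class Vocabulary:
    """Token → index map with index 0 reserved for padding and 1 for OOV.

    Real tokens are indexed contiguously from 2 in order of decreasing
    corpus frequency (ties broken lexicographically).
    """

    def __init__(self, index: dict[str, int], frequency: dict[str, int]):
        self.index = index
        self.frequency = frequency

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def lookup(self, token: str) -> int:
        return self.index.get(token, OOV_INDEX)

    @property
    def size(self) -> int:
        """Number of distinct indices including padding and OOV."""
        return len(self.index) + 2

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for token, idx in sorted(self.index.items(), key=lambda kv: kv[1]):
                fh.write(f"{token}\t{idx}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Vocabulary":
        index: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                token, idx = line.rstrip("\n").split("\t")
                index[token] = int(idx)
        return cls(index, {})

    def checksum(self) -> str:
        """Content hash of the token→index map (leakage guard)."""
        payload = "\n".join(f"{t}\t{i}" for t, i in sorted(self.index.items()))
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def build_vocabulary(corpus: Iterable[Sequence[str]], prune_fraction: float = 0.01) -> Vocabulary:
    """Build a vocabulary from cleaned training-split token lists.

    The ``ceil(prune_fraction * n_distinct)`` lowest-frequency distinct
    tokens are removed (frequency ascending, ties broken by ascending
    lexicographic order).  Remaining tokens are indexed from 2 by
    descending frequency.
    """
    if not 0.0 <= prune_fraction < 1.0:
        raise ValueError("prune_fraction must be in [0, 1)")
    counts: Counter[str] = Counter()
    for tokens in corpus:
        counts.update(tokens)
    if not counts:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    n_drop = math.ceil(prune_fraction * len(counts)) if prune_fraction > 0 else 0
    # rarest first: ascending frequency, lexicographic tie-break
    rarest = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
    dropped = {t for t, _ in rarest[:n_drop]}
    kept = sorted(
        ((t, c) for t, c in counts.items() if t not in dropped),
        key=lambda kv: (-kv[1], kv[0]),
    )
    index = {t: i + 2 for i, (t, _) in enumerate(kept)}
    return Vocabulary(index, {t: c for t, c in kept})


def encode(
    tokens: Sequence[str], vocab: Vocabulary, max_len: int
) -> tuple[np.ndarray, bool]:
    """Encode one cleaned token list to a fixed-length index sequence.

    Returns ``(indices, retained)`` where ``indices`` is right-padded /
    truncated to ``max_len`` and ``retained`` is False when the cleaned
    visit has fewer than ``MIN_TOKENS`` tokens.
    """
    idx = np.full(max_len, PAD_INDEX, dtype=np.int32)
    for j, token in enumerate(tokens[:max_len]):
        idx[j] = vocab.lookup(token)
    return idx, len(tokens) >= MIN_TOKENS


class TextVectorizer(BaseEstimator, TransformerMixin):
    """Fit-on-train text → padded token-index matrix transformer.

    Parameters
    ----------
    prune_fraction : fraction of distinct tokens removed as rare, default 0.01.
    max_len : fixed sequence length; ``None`` uses the 99th percentile of
        training-sequence lengths (at least ``MIN_TOKENS``).

    Fitted attributes: ``vocabulary_``, ``max_len_``, ``stopwords_``.
    """

    def __init__(self, prune_fraction: float = 0.01, max_len: int | None = None):
        self.prune_fraction = prune_fraction
        self.max_len = max_len

    def fit(self, texts: Iterable[str], y=None) -> "TextVectorizer":
        self.stopwords_ = load_stopwords()
        self._stemmer = ItalianStemmer()
        corpus = [clean_and_stem(t, self.stopwords_, self._stemmer) for t in texts]
        self.vocabulary_ = build_vocabulary(corpus, self.prune_fraction)
        if self.max_len is not None:
            self.max_len_ = int(self.max_len)
        else:
            lengths = [len(t) for t in corpus]
            self.max_len_ = max(MIN_TOKENS, int(np.ceil(np.percentile(lengths, 99))))
        return self

    def transform(self, texts: Iterable[str]) -> np.ndarray:
        X, _ = self.transform_with_mask(texts)
        return X

    def transform_with_mask(self, texts: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
        """Encode texts; also return the retained mask (length >= 3)."""
        if not hasattr(self, "vocabulary_"):
            raise RuntimeError("TextVectorizer is not fitted")
        rows, retained = [], []
        for t in texts:
            tokens = clean_and_stem(t, self.stopwords_, self._stemmer)
            idx, keep = encode(tokens, self.vocabulary_, self.max_len_)
            rows.append(idx)
            retained.append(keep)
        X = np.vstack(rows) if rows else np.empty((0, self.max_len_), dtype=np.int32)
        return X, np.asarray(retained, dtype=bool)

    @property
    def vocab_size_(self) -> int:
        return self.vocabulary_.size
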