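"""Word representations: trainable random, frozen static, and contextual.

Three encoder families behind one interface yielding a tokens x d matrix per
sentence: (1) randomly initialized vocabulary-sized tables of d=32 trained
with the model, (2) static pretrained vectors of d=300 loaded from text files
in GloVe format and frozen, and (3) contextual d=768 encoders. For the
contextual case a deterministic hash-based stub is bundled: each token's
vector is a seeded hash embedding mixed with a fixed-weight average of its
left context, so the same token differs across contexts. A real transformer
(with sub-word vectors mean-pooled per word) can be plugged in through the
same callable interface.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .records import SentenceRecord

PAD, UNK = "<pad>", "<unk>"

EMBEDDING_DIMS = {"random": 32, "static_pretrained": 300, "contextual": 768}


@dataclass(frozen=True)
class EmbeddingSpec:
    kind: str
    d: int
    trainable: bool

    @classmethod
    def of(cls, kind: str) -> "EmbeddingSpec":
        if kind not in EMBEDDING_DIMS:
            raise ValueError(f"unknown embedding kind {kind!r}")
        return cls(kind, EMBEDDING_DIMS[kind], trainable=kind != "static_pretrained")


class Vocab:
    """Token inventory with reserved specials (pad=0, unk=1), first-occurrence order."""

    def __init__(self, types: list[str]):
        self.types = [PAD, UNK] + list(types)
        self.index = {t: i for i, t in enumerate(self.types)}

    def __len__(self) -> int:
        return len(self.types)

    def __getitem__(self, token: str) -> int:
        return self.index.get(token, 1)

    def encode(self, tokens: list[str]) -> np.ndarray:
        return np.array([self[t] for t in tokens], dtype=np.int64)


def build_vocab(records: list[SentenceRecord]) -> Vocab:
    if not records:
        raise ValueError("empty corpus")
    seen: dict[str, None] = {}
    for rec in records:
        for tok in rec.tokens:
            seen.setdefault(tok)
    return Vocab(list(seen))


def load_static_embeddings(path, vocab: Vocab, d: int = 300) -> np.ndarray:
    """Read whitespace-separated "token v1 ... vd" lines into a vocab-aligned matrix.

    Out-of-vocabulary tokens (and the pad row) get the zero vector.
    """
    matrix = np.zeros((len(vocab), d))
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            token, values = parts[0], parts[1:]
            if len(values) != d:
                raise ValueError(f"{path}:{lineno}: expected {d} values, got {len(values)}")
            idx = vocab.index.get(token)
            if idx is not None and idx >= 2:
                matrix[idx] = np.asarray(values, dtype=np.float64)
    return matrix


def _hash_vector(token: str, d: int, salt: int) -> np.ndarray:
    digest = hashlib.sha256(f"{salt}:{token}".encode()).digest()
    seed = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(seed).standard_normal(d) / np.sqrt(d)


class HashContextualEncoder:
    """Deterministic stand-in contextual encoder (synthetic, not pretrained).

    vector(i) = (1 - mix) * hash(token_i) + mix * mean(hash(token_j), j < i);
    a single-token sentence reduces to its context-free hash embedding.
    """

    def __init__(self, d: int = 768, mix: float = 0.3, salt: int = 0):
        self.d = d
        self.mix = mix
        self.salt = salt

    def __call__(self, tokens: list[str]) -> np.ndarray:
        if not tokens:
            raise ValueError("empty sentence")
        base = np.stack([_hash_vector(t, self.d, self.salt) for t in tokens])
        out = base.copy()
        for i in range(1, len(tokens)):
            out[i] = (1.0 - self.mix) * base[i] + self.mix * base[:i].mean(axis=0)
        return out


def contextual_encode(tokens: list[str], encoder=None) -> np.ndarray:
    """tokens x 768 matrix from the stub or a plugged-in encoder callable."""
    return (encoder or HashContextualEncoder())(tokens)


def synthetic_static_table(vocab: Vocab, d: int = 300, salt: int = 7) -> np.ndarray:
    """Deterministic synthetic stand-in for a pretrained static table.

    Hash embeddings per vocabulary type, frozen like real pretrained vectors;
    used when no GloVe-format file is supplied (e.g., synthetic corpora).
    Rows 0 (pad) and 1 (unk) are zero.
    """
    table = np.zeros((len(vocab), d))
    for i, token in enumerate(vocab.types[2:], start=2):
        table[i] = _hash_vector(token, d, salt)
    return table
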