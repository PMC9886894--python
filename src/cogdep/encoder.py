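"""Post text encoders: tokenization, vocabulary, and the tiny default encoder.

The model contract only requires that a post's text map to a fixed-length
vector ``h_t``; the default implementation is a trainable word-embedding
table with mean pooling over tokens, built on a whitespace/punctuation
tokenizer and a corpus-derived vocabulary.  This keeps the default path
CPU-only with no downloads.  A ``pretrained`` adapter slot accepts any
object implementing :class:`TextEncoder`, e.g. a transformer wrapper; the
downstream model is agnostic to which is plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus import tokenize_simple

__all__ = [
    "TokenSequence",
    "Vocabulary",
    "TinyEncoder",
    "TextEncoder",
    "build_encoder",
]

PAD_ID = 0
UNK_ID = 1


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple[int, ...]
    length: int
    truncated: bool


@dataclass
class Vocabulary:
    """Token-to-id map with reserved pad/unk slots."""

    token_to_id: dict[str, int] = field(default_factory=dict)

    @classmethod
    def build(
        cls, texts: Sequence[str], max_size: int = 5000, min_count: int = 1
    ) -> "Vocabulary":
        counts: dict[str, int] = {}
        for t in texts:
            for tok in tokenize_simple(t):
                counts[tok] = counts.get(tok, 0) + 1
        # frequency then lexical order for determinism
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        mapping: dict[str, int] = {}
        for tok, c in ranked:
            if c < min_count or len(mapping) + 2 >= max_size:
                break
            mapping[tok] = len(mapping) + 2
        return cls(token_to_id=mapping)

    def __len__(self) -> int:
        return len(self.token_to_id) + 2

    def lookup(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def to_json_dict(self) -> dict:
        return {"token_to_id": self.token_to_id}

    @classmethod
    def from_json_dict(cls, d: dict) -> "Vocabulary":
        return cls(token_to_id=dict(d["token_to_id"]))


@runtime_checkable
class TextEncoder(Protocol):
    """Contract shared by the tiny encoder and any pre-trained adapter."""

    dim: int

    def tokenize(self, text: str) -> TokenSequence: ...

    def encode(self, sequences: Sequence[TokenSequence]) -> np.ndarray: ...


class TinyEncoder:
    """Trainable embedding + mean pooling.

    The embedding matrix ``E`` is the single trainable parameter; gradients
    flow to it through the mean pool during joint training.  Identical texts
    always encode identically (no dropout, no state).
    """

    def __init__(
        self,
        vocab: Vocabulary,
        dim: int = 32,
        max_tokens: int = 64,
        seed: int = 0,
    ):
        self.vocab = vocab
        self.dim = dim
        self.max_tokens = max_tokens
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(dim)
        self.E = rng.normal(0.0, scale, size=(len(vocab), dim))
        self.E[PAD_ID] = 0.0

    def tokenize(self, text: str) -> TokenSequence:
        if not text.strip():
            raise ValueError("cannot tokenize empty text")
        toks = tokenize_simple(text)
        truncated = len(toks) > self.max_tokens
        toks = toks[: self.max_tokens]
        ids = tuple(self.vocab.lookup(t) for t in toks)
        if not ids:  # text was all punctuation
            ids = (UNK_ID,)
        return TokenSequence(tokens=ids, length=len(ids), truncated=truncated)

    def encode_one(self, seq: TokenSequence) -> np.ndarray:
        idx = np.fromiter(seq.tokens, dtype=np.intp)
        return self.E[idx].mean(axis=0)

    def encode(self, sequences: Sequence[TokenSequence]) -> np.ndarray:
        if not sequences:
            return np.zeros((0, self.dim))
        return np.stack([self.encode_one(s) for s in sequences])

    def grad_update(self, seq: TokenSequence, dh: np.ndarray, dE: np.ndarray) -> None:
        """Accumulate d(loss)/dE for one post given d(loss)/dh."""
        idx = np.fromiter(seq.tokens, dtype=np.intp)
        np.add.at(dE, idx, dh / len(idx))


class PretrainedEncoderAdapter:
    """Adapter slot for a large pre-trained sentence encoder.

    Requires the optional ``transformers`` dependency; the default test and
    training path never needs it.
    """

    def __init__(self, model_name: str = "bert-base-uncased", max_tokens: int = 64):
        try:
            from transformers import AutoModel, AutoTokenizer  # type: ignore
        except ImportError as e:  # pragma: no cover - optional path
            raise RuntimeError(
                "encoder type 'pretrained' requires the optional 'transformers' "
                "package; use the default 'tiny' encoder instead"
            ) from e
        self._tok = AutoTokenizer.from_pretrained(model_name)  # pragma: no cover
        self._model = AutoModel.from_pretrained(model_name)  # pragma: no cover
        self.dim = self._model.config.hidden_size  # pragma: no cover
        self.max_tokens = max_tokens  # pragma: no cover


def build_encoder(
    config: dict, texts: Sequence[str] | None = None, seed: int = 0
) -> TextEncoder:
    """Build an encoder from ``{"type": "tiny"|"pretrained", ...}`` config."""
    kind = config.get("type", "tiny")
    if kind == "tiny":
        vocab = Vocabulary.build(
            texts or [],
            max_size=config.get("vocab_size", 5000),
            min_count=config.get("min_count", 1),
        )
        return TinyEncoder(
            vocab,
            dim=config.get("dim", 32),
            max_tokens=config.get("max_tokens", 64),
            seed=seed,
        )
    if kind == "pretrained":
        return PretrainedEncoderAdapter(
            model_name=config.get("model_name", "bert-base-uncased"),
            max_tokens=config.get("max_tokens", 64),
        )
    raise ValueError(f"unknown encoder type {kind!r}")
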