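"""Data model and JSON-lines I/O for post- and user-level corpora.

Two record types flow through the whole package: :class:`Post` (one
social-media message, optionally carrying a gold or pseudo distortion label)
and :class:`UserRecord` (a user's posting history plus an optional binary
depression label, age and cohort).  The interchange format is JSON-lines —
one post or one user per line — chosen because pseudo-label expansion is
append-friendly and corpora stream line by line.

Readers are strict: malformed lines raise :class:`CorpusFormatError` naming
the offending line, and unknown label strings raise
:class:`~cogdep.taxonomy.TaxonomyError` rather than being coerced to NORMAL,
protecting the fixed 12-way output head.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from pydantic import BaseModel, field_validator, model_validator

from .taxonomy import DistortionCategory

__all__ = [
    "Post",
    "UserRecord",
    "CorpusStats",
    "CorpusFormatError",
    "read_posts",
    "write_posts",
    "read_users",
    "write_users",
    "corpus_statistics",
    "tokenize_simple",
]


class CorpusFormatError(ValueError):
    """A corpus file line could not be parsed into the data model."""


class Post(BaseModel):
    post_id: str
    user_id: str
    text: str
    timestamp: Optional[str] = None
    label: Optional[DistortionCategory] = None
    label_source: Literal["gold", "pseudo", "none"] = "none"
    confidence: Optional[float] = None

    @field_validator("text")
    @classmethod
    def _text_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("post text must be non-empty after stripping")
        return v

    @field_validator("label", mode="before")
    @classmethod
    def _label_from_code(cls, v):
        if isinstance(v, str):
            return DistortionCategory.from_code(v)
        return v

    @field_validator("confidence")
    @classmethod
    def _conf_range(cls, v):
        if v is not None and not (0.0 <= v <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _label_source_consistency(self) -> "Post":
        if self.label_source == "pseudo" and self.confidence is None:
            raise ValueError("pseudo-labeled posts must carry a confidence")
        if self.label_source == "gold" and self.confidence not in (None, 1.0):
            raise ValueError("gold labels carry no confidence (or 1.0)")
        if self.label_source in ("gold", "pseudo") and self.label is None:
            raise ValueError(f"label_source={self.label_source!r} requires a label")
        return self

    def to_json_dict(self) -> dict:
        d: dict = {"post_id": self.post_id, "user_id": self.user_id, "text": self.text}
        if self.timestamp is not None:
            d["timestamp"] = self.timestamp
        if self.label is not None:
            d["label"] = self.label.code
        if self.label_source != "none":
            d["label_source"] = self.label_source
        if self.confidence is not None:
            d["confidence"] = self.confidence
        return d


class UserRecord(BaseModel):
    user_id: str
    posts: list[Post]
    depression_label: Optional[int] = None
    age: Optional[int] = None
    cohort: Optional[Literal["depression", "control"]] = None

    @field_validator("depression_label")
    @classmethod
    def _binary(cls, v):
        if v is not None and v not in (0, 1):
            raise ValueError("depression_label must be 0 or 1")
        return v

    @model_validator(mode="after")
    def _consistency(self) -> "UserRecord":
        if not self.posts:
            raise ValueError("a user record must contain at least one post")
        for p in self.posts:
            if p.user_id != self.user_id:
                raise ValueError(
                    f"post {p.post_id!r} has user_id {p.user_id!r}, "
                    f"expected {self.user_id!r}"
                )
        if self.depression_label is not None and self.cohort is not None:
            expected = "depression" if self.depression_label == 1 else "control"
            if self.cohort != expected:
                raise ValueError(
                    f"cohort {self.cohort!r} inconsistent with "
                    f"depression_label={self.depression_label}"
                )
        # chronological order when every post has a timestamp; file order otherwise
        if all(p.timestamp is not None for p in self.posts):
            self.posts.sort(key=lambda p: p.timestamp)
        return self

    def to_json_dict(self) -> dict:
        d: dict = {"user_id": self.user_id}
        if self.depression_label is not None:
            d["depression_label"] = self.depression_label
        if self.age is not None:
            d["age"] = self.age
        if self.cohort is not None:
            d["cohort"] = self.cohort
        d["posts"] = [p.to_json_dict() for p in self.posts]
        return d


class CorpusStats(BaseModel):
    """Corpus composition statistics, broken down per cohort.

    Cohort keys are ``"depression"``, ``"control"`` and ``"unknown"``;
    averages are ``None`` (reported as absent) when a cohort is empty.
    """

    n_users_per_cohort: dict[str, int]
    n_posts_per_cohort: dict[str, int]
    avg_posts_per_user: dict[str, Optional[float]]
    avg_tokens_per_post: dict[str, Optional[float]]
    label_counts: dict[str, int]

    @property
    def n_users(self) -> int:
        return sum(self.n_users_per_cohort.values())

    @property
    def n_posts(self) -> int:
        return sum(self.n_posts_per_cohort.values())

    @property
    def n_labeled(self) -> int:
        return sum(self.label_counts.values())

    @property
    def n_distorted(self) -> int:
        return sum(
            v for k, v in self.label_counts.items()
            if k != DistortionCategory.NORMAL.code
        )


def tokenize_simple(text: str) -> list[str]:
    """Lowercased whitespace/punctuation tokenization used for token counts."""
    out, cur = [], []
    for ch in text.lower():
        if ch.isalnum() or ch == "'":
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


# ---------------------------------------------------------------------------
# JSONL I/O


def _parse_line(line: str, lineno: int, path) -> dict:
    try:
        obj = json.loads(line)
    except json.JSONDecodeError as e:
        raise CorpusFormatError(f"{path}:{lineno}: malformed JSON line: {e}") from e
    if not isinstance(obj, dict):
        raise CorpusFormatError(f"{path}:{lineno}: expected a JSON object")
    return obj


def _resolve_labels(obj: dict, lineno: int, path) -> None:
    """Convert label code strings in-place; unknown codes raise TaxonomyError."""
    from .taxonomy import TaxonomyError

    if isinstance(obj.get("label"), str):
        try:
            obj["label"] = DistortionCategory.from_code(obj["label"])
        except TaxonomyError as e:
            raise TaxonomyError(f"{path}:{lineno}: {e}") from None
    for p in obj.get("posts", []) if isinstance(obj.get("posts"), list) else []:
        if isinstance(p, dict):
            _resolve_labels(p, lineno, path)


def read_posts(path, dialect: str = "jsonl") -> list[Post]:
    """Read a JSON-lines post file, preserving file order."""
    if dialect != "jsonl":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    posts: list[Post] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            obj = _parse_line(line, lineno, path)
            _resolve_labels(obj, lineno, path)
            try:
                posts.append(Post(**obj))
            except CorpusFormatError:
                raise
            except Exception as e:
                raise CorpusFormatError(f"{path}:{lineno}: {e}") from e
    return posts


def write_posts(posts: Iterable[Post], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(json.dumps(p.to_json_dict(), ensure_ascii=False) + "\n")
    return path


def read_users(path, dialect: str = "jsonl") -> list[UserRecord]:
    if dialect != "jsonl":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    users: list[UserRecord] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            obj = _parse_line(line, lineno, path)
            _resolve_labels(obj, lineno, path)
            try:
                users.append(UserRecord(**obj))
            except Exception as e:
                raise CorpusFormatError(f"{path}:{lineno}: {e}") from e
    return users


def write_users(users: Iterable[UserRecord], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for u in users:
            fh.write(json.dumps(u.to_json_dict(), ensure_ascii=False) + "\n")
    return path


# ---------------------------------------------------------------------------
# Statistics


def _cohort_key(u: UserRecord) -> str:
    if u.cohort is not None:
        return u.cohort
    if u.depression_label is not None:
        return "depression" if u.depression_label == 1 else "control"
    return "unknown"


def corpus_statistics(users: Sequence[UserRecord]) -> CorpusStats:
    """Per-cohort user/post counts, averages, and per-category label counts."""
    n_users: dict[str, int] = {}
    n_posts: dict[str, int] = {}
    tok_sum: dict[str, int] = {}
    label_counts: dict[str, int] = {}
    for u in users:
        key = _cohort_key(u)
        n_users[key] = n_users.get(key, 0) + 1
        n_posts[key] = n_posts.get(key, 0) + len(u.posts)
        for p in u.posts:
            tok_sum[key] = tok_sum.get(key, 0) + len(tokenize_simple(p.text))
            if p.label is not None:
                label_counts[p.label.code] = label_counts.get(p.label.code, 0) + 1
    avg_posts = {
        k: (n_posts[k] / n_users[k] if n_users[k] else None) for k in n_users
    }
    avg_tokens = {
        k: (tok_sum.get(k, 0) / n_posts[k] if n_posts.get(k) else None)
        for k in n_users
    }
    return CorpusStats(
        n_users_per_cohort=n_users,
        n_posts_per_cohort=n_posts,
        avg_posts_per_user=avg_posts,
        avg_tokens_per_post=avg_tokens,
        label_counts=label_counts,
    )


def post_statistics(posts: Sequence[Post]) -> CorpusStats:
    """Statistics over a bare post collection (e.g. a seed set)."""
    label_counts: dict[str, int] = {}
    tok = 0
    for p in posts:
        tok += len(tokenize_simple(p.text))
        if p.label is not None:
            label_counts[p.label.code] = label_counts.get(p.label.code, 0) + 1
    n = len(posts)
    users = {p.user_id for p in posts}
    return CorpusStats(
        n_users_per_cohort={"unknown": len(users)},
        n_posts_per_cohort={"unknown": n},
        avg_posts_per_user={"unknown": (n / len(users)) if users else None},
        avg_tokens_per_post={"unknown": (tok / n) if n else None},
        label_counts=label_counts,
    )
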