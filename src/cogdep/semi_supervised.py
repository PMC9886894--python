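"""Semi-supervised corpus expansion by confidence-filtered pseudo-labeling.

A classifier trained on a small gold seed set assigns soft labels to a
large unlabeled pool; pool posts whose top-class probability clears a
confidence threshold are accepted with that pseudo label (NORMAL-predicted
posts are retained the same way, growing the normal class).  Expansion is
single-round — no iterative self-training.

Pseudo-label quality is estimated the way a human inspection would do it:
a simple random sample of the accepted posts (default 100) is scored
against an oracle (the generator's hidden answers in synthetic runs, a
human annotation file in real use), yielding a per-category precision
table.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, model_validator

from .corpus import Post, CorpusStats, post_statistics
from .taxonomy import DistortionCategory

logger = logging.getLogger(__name__)

__all__ = [
    "ExpansionConfig",
    "ExpandedCorpus",
    "PrecisionTable",
    "pseudo_label",
    "estimate_precision",
    "merge_corpora",
]


class ExpansionConfig(BaseModel):
    confidence_threshold: float = 0.9
    max_per_category: Optional[int] = None
    inspection_sample_size: int = 100
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ExpansionConfig":
        # thresholds outside (0,1] are allowed operationally (0 accepts all,
        # >1 accepts none) but must still be a number
        if self.inspection_sample_size <= 0:
            raise ValueError("inspection_sample_size must be positive")
        if self.max_per_category is not None and self.max_per_category < 0:
            raise ValueError("max_per_category must be non-negative")
        return self


class ExpandedCorpus(BaseModel):
    accepted: list[Post]
    rejected_count: int
    per_category_counts: dict[str, int]
    threshold: float

    @model_validator(mode="after")
    def _check(self) -> "ExpandedCorpus":
        for p in self.accepted:
            if p.confidence is None or p.confidence < self.threshold:
                raise ValueError(
                    f"accepted post {p.post_id} below threshold {self.threshold}"
                )
        return self


class PrecisionTable(BaseModel):
    """Sampled-inspection precision per category (fractions in [0,1]).

    Categories absent from the sample have ``precision=None`` (undefined).
    """

    sample_size: int
    overall_precision: Optional[float]
    per_category: dict[str, dict[str, Optional[float]]]

    def as_percent_rows(self) -> list[tuple[str, Optional[float]]]:
        return [
            (code, None if row["precision"] is None
             else round(100.0 * row["precision"], 2))
            for code, row in self.per_category.items()
        ]


def pseudo_label(
    pool: Sequence[Post], model, config: ExpansionConfig
) -> ExpandedCorpus:
    """Label a pool with a trained post classifier and confidence-filter it.

    ``model`` is any object with ``predict_proba(texts) -> (n, 12)``; ties in
    the argmax resolve to the lowest category index.
    """
    if hasattr(model, "is_fitted") and not model.is_fitted:
        raise ValueError("pseudo_label requires a trained classifier")
    if not pool:
        return ExpandedCorpus(accepted=[], rejected_count=0,
                              per_category_counts={},
                              threshold=config.confidence_threshold)
    probs = np.asarray(model.predict_proba([p.text for p in pool]))
    idx = probs.argmax(axis=1)  # lowest index wins ties
    conf = probs[np.arange(len(pool)), idx]
    candidates: list[Post] = []
    for p, i, c in zip(pool, idx, conf):
        if c >= config.confidence_threshold:
            candidates.append(
                p.model_copy(update={
                    "label": DistortionCategory.from_index(int(i)),
                    "label_source": "pseudo",
                    "confidence": float(c),
                })
            )
    if config.max_per_category is not None:
        kept: list[Post] = []
        by_cat: dict[str, list[Post]] = {}
        for p in candidates:
            by_cat.setdefault(p.label.code, []).append(p)
        for code, posts in by_cat.items():
            posts.sort(key=lambda p: (-p.confidence, p.post_id))
            kept.extend(posts[: config.max_per_category])
        kept.sort(key=lambda p: p.post_id)
        candidates = kept
    counts: dict[str, int] = {}
    for p in candidates:
        counts[p.label.code] = counts.get(p.label.code, 0) + 1
    return ExpandedCorpus(
        accepted=candidates,
        rejected_count=len(pool) - len(candidates),
        per_category_counts=counts,
        threshold=config.confidence_threshold,
    )


def estimate_precision(
    expanded: ExpandedCorpus,
    oracle: dict[str, DistortionCategory],
    sample_size: int = 100,
    seed: int = 0,
) -> PrecisionTable:
    """Score a random sample of accepted pseudo labels against an oracle.

    Simple random sampling without replacement; ``sample_size`` larger than
    the accepted count is clamped with a warning.  Precision per category is
    correct/labeled within the sample only — it is an estimator of the true
    pseudo-label precision, unbiased over sampling seeds.
    """
    accepted = expanded.accepted
    if not accepted:
        return PrecisionTable(sample_size=0, overall_precision=None,
                              per_category={c.code: {"precision": None,
                                                     "n_sampled": 0.0,
                                                     "n_correct": 0.0}
                                            for c in DistortionCategory})
    if sample_size > len(accepted):
        logger.warning(
            "inspection sample size %d exceeds accepted count %d; clamping",
            sample_size, len(accepted),
        )
        sample_size = len(accepted)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(accepted), size=sample_size, replace=False)
    stats = {c: [0, 0] for c in DistortionCategory}  # [sampled, correct]
    for i in chosen:
        p = accepted[int(i)]
        if p.post_id not in oracle:
            raise KeyError(f"oracle does not cover sampled post {p.post_id!r}")
        stats[p.label][0] += 1
        if oracle[p.post_id] is p.label:
            stats[p.label][1] += 1
    per = {
        c.code: {
            "n_sampled": float(n),
            "n_correct": float(k),
            "precision": (k / n) if n else None,
        }
        for c, (n, k) in stats.items()
    }
    tot_n = sum(n for n, _ in stats.values())
    tot_k = sum(k for _, k in stats.values())
    return PrecisionTable(
        sample_size=sample_size,
        overall_precision=(tot_k / tot_n) if tot_n else None,
        per_category=per,
    )


def merge_corpora(
    seed_posts: Sequence[Post], expanded: ExpandedCorpus
) -> tuple[list[Post], CorpusStats]:
    """Merge gold seed and accepted pseudo posts; gold wins on id conflicts."""
    merged: dict[str, Post] = {}
    for p in seed_posts:
        merged[p.post_id] = p
    for p in expanded.accepted:
        if p.post_id in merged:
            prev = merged[p.post_id]
            if prev.label is not p.label:
                logger.warning(
                    "post %s has conflicting gold/pseudo labels (%s vs %s); "
                    "gold wins", p.post_id,
                    prev.label.code if prev.label else None, p.label.code,
                )
            continue  # gold (or first copy) takes precedence
        merged[p.post_id] = p
    posts = list(merged.values())
    return posts, post_statistics(posts)
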