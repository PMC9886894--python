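"""Cohort analyses: distortion prevalence, age-group trends, word frequencies.

Prevalence of cognitive distortion in a scope of labeled posts is

    p = N_cogn / (N_normal + N_cogn)

the fraction of posts carrying any distortion label.  The module computes
this overall, per user, per cohort, and per (age group x cohort) cell, with
per-user distributions summarised boxplot-style (quartiles).

Age groups follow a four-bin scheme grounded in schooling/working life
stages: a = early adolescence (10-15, secondary school), b = late
adolescence (16-22, university), c = post-college (23-35), d = 36+
(stable middle age).

Word-frequency tables over distorted posts (lowercased, stopword-filtered)
are the canonical output for content analysis; word-cloud rendering can be
driven from them but is not produced here.  The shipped stopword list
deliberately retains modal and absolutist tokens ("should", "always",
"never", "must") because they are distortion markers, not noise.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from pydantic import BaseModel

from .corpus import Post, UserRecord, tokenize_simple
from .taxonomy import DistortionCategory

logger = logging.getLogger(__name__)

__all__ = [
    "AgeGroupScheme",
    "PrevalenceResult",
    "GroupPrevalence",
    "WordFrequencyTable",
    "STOPWORDS",
    "prevalence",
    "prevalence_by_group",
    "word_frequencies",
    "word_frequencies_by_scope",
]

# Versioned stopword list (v1): function words only; modal/absolutist tokens
# are intentionally NOT stopwords here.
STOPWORDS: frozenset[str] = frozenset("""
a an the and or but if then than that this these those there here
i you he she it we they me him her us them my your his its our their
am is are was were be been being do does did doing have has had having
to of in on at by for with from as about into over after before under
up down out off again further once very so too just not no nor only
own same such both each few more most other some any what which who whom
when where why how s t don now
""".split())


class AgeGroupScheme(BaseModel):
    """Four disjoint, ordered age bins covering every age >= 10."""

    bins: tuple[tuple[str, int, Optional[int]], ...] = (
        ("a", 10, 15),
        ("b", 16, 22),
        ("c", 23, 35),
        ("d", 36, None),
    )

    @property
    def group_labels(self) -> list[str]:
        return [b[0] for b in self.bins]

    def group_of(self, age: int) -> str:
        if age < self.bins[0][1]:
            raise ValueError(f"age {age} below the youngest bin")
        for label, lo, hi in self.bins:
            if age >= lo and (hi is None or age <= hi):
                return label
        raise AssertionError("unreachable: bins cover all ages >= 10")


class PrevalenceResult(BaseModel):
    scope: str
    n_cogn: int
    n_normal: int
    p_popularity: float
    per_category: dict[str, float]

    @property
    def n_posts(self) -> int:
        return self.n_cogn + self.n_normal


class GroupPrevalence(BaseModel):
    """Prevalence summary for one (age group x cohort) cell."""

    group: str
    cohort: str
    result: PrevalenceResult
    per_user_p: list[float]
    mean_user_p: float
    quartiles: tuple[float, float, float]  # q1, median, q3


class WordFrequencyTable(BaseModel):
    scope: str
    counts: dict[str, int]
    top: list[tuple[str, int]]


def prevalence(posts: Sequence[Post], scope: str = "all") -> Optional[PrevalenceResult]:
    """Fraction of labeled posts carrying any distortion label.

    Every post must be labeled (gold or pseudo).  An empty scope is
    undefined and reported as ``None``.
    """
    posts = list(posts)
    if not posts:
        return None
    n_cogn = 0
    cat_counts: dict[str, int] = {c.code: 0 for c in DistortionCategory
                                  if c.is_distortion}
    for p in posts:
        if p.label is None:
            raise ValueError(f"post {p.post_id!r} is unlabeled")
        if p.label.is_distortion:
            n_cogn += 1
            cat_counts[p.label.code] += 1
    total = len(posts)
    return PrevalenceResult(
        scope=scope,
        n_cogn=n_cogn,
        n_normal=total - n_cogn,
        p_popularity=n_cogn / total,
        per_category={k: v / total for k, v in cat_counts.items()},
    )


def _quartiles(values: list[float]) -> tuple[float, float, float]:
    import numpy as np

    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    return float(q1), float(q2), float(q3)


def prevalence_by_group(
    users: Sequence[UserRecord],
    scheme: Optional[AgeGroupScheme] = None,
) -> dict[tuple[str, str], GroupPrevalence]:
    """Prevalence per (age group x cohort), with per-user distributions.

    Users without an age are excluded (their count is logged).  Per-user p
    values support boxplot-style summaries; the cell mean is the mean of
    per-user prevalences ("average frequency of occurrence").
    """
    scheme = scheme or AgeGroupScheme()
    cells: dict[tuple[str, str], list[UserRecord]] = {}
    n_skipped = 0
    for u in users:
        if u.age is None:
            n_skipped += 1
            continue
        cohort = u.cohort or (
            "depression" if u.depression_label == 1 else "control"
            if u.depression_label is not None else "unknown"
        )
        cells.setdefault((scheme.group_of(u.age), cohort), []).append(u)
    if n_skipped:
        logger.info("prevalence_by_group: excluded %d users without age",
                    n_skipped)
    out: dict[tuple[str, str], GroupPrevalence] = {}
    for (group, cohort), cell_users in sorted(cells.items()):
        all_posts = [p for u in cell_users for p in u.posts]
        res = prevalence(all_posts, scope=f"{group}/{cohort}")
        per_user = []
        for u in cell_users:
            r = prevalence(u.posts, scope=u.user_id)
            per_user.append(r.p_popularity)
        out[(group, cohort)] = GroupPrevalence(
            group=group,
            cohort=cohort,
            result=res,
            per_user_p=per_user,
            mean_user_p=sum(per_user) / len(per_user),
            quartiles=_quartiles(per_user),
        )
    return out


def word_frequencies(
    posts: Sequence[Post],
    scope: str = "all",
    top_k: int = 20,
    stopwords: frozenset[str] = STOPWORDS,
) -> WordFrequencyTable:
    """Token counts over distorted posts, stopword-filtered, with top-k.

    ``posts`` must be pre-filtered to non-NORMAL labels; ties in the top-k
    break lexicographically.
    """
    for p in posts:
        if p.label is None or not p.label.is_distortion:
            raise ValueError(
                f"word_frequencies expects distorted posts only; "
                f"{p.post_id!r} is not"
            )
    counts: dict[str, int] = {}
    for p in posts:
        for tok in tokenize_simple(p.text):
            if tok in stopwords:
                continue
            counts[tok] = counts.get(tok, 0) + 1
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return WordFrequencyTable(scope=scope, counts=counts, top=top)


def word_frequencies_by_scope(
    users: Sequence[UserRecord],
    scheme: Optional[AgeGroupScheme] = None,
    top_k: int = 20,
) -> dict[tuple[str, str], WordFrequencyTable]:
    """Word-frequency tables of distorted posts per (age group x cohort)."""
    scheme = scheme or AgeGroupScheme()
    out: dict[tuple[str, str], WordFrequencyTable] = {}
    cells: dict[tuple[str, str], list[Post]] = {}
    for u in users:
        if u.age is None:
            continue
        cohort = u.cohort or "unknown"
        key = (scheme.group_of(u.age), cohort)
        for p in u.posts:
            if p.label is not None and p.label.is_distortion:
                cells.setdefault(key, []).append(p)
    for key, posts in sorted(cells.items()):
        out[key] = word_frequencies(posts, scope=f"{key[0]}/{key[1]}",
                                    top_k=top_k)
    return out
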