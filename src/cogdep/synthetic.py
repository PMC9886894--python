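"""Synthetic social-media corpora with controlled distortion structure.

Real depression-screening corpora (eRisk-style longitudinal post histories
with a minority depressed class) are access-restricted, so every other module
in this package is exercised against generated corpora that reproduce the
statistical structure those analyses assume:

* a minority of users is depressed (``depressed_fraction``);
* depressed users emit cognitively distorted posts at a higher rate than
  controls (``p_distortion_depressed > p_distortion_control``);
* the distortion rate declines with age group (``age_decline_slope``);
* distorted posts draw a category from a per-cohort mixture (defaulting to
  the relative category frequencies of the expanded seed corpus, normalized
  to a simplex);
* at ``signal_strength=1`` every distorted post contains a marker token
  unique to its category, so a keyword lookup is a perfect classifier
  (Bayes-separable); at ``signal_strength=0`` the text is drawn from neutral
  templates regardless of label, so labels are independent of text.

Every generated post carries its gold label; ``generate_seed_and_pool``
additionally withholds pool labels into a companion answer map so
pseudo-label precision can be scored against a known oracle.

The generator emulates label/cohort structure only — not the vocabulary
breadth, code-switching, or pragmatics of real social-media language.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone
from typing import NamedTuple, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .corpus import Post, UserRecord
from .taxonomy import DISTORTIONS, DistortionCategory

__all__ = [
    "GeneratorConfig",
    "TemplateBank",
    "SeedPool",
    "generate_corpus",
    "generate_seed_and_pool",
    "keyword_classify",
    "DEFAULT_CATEGORY_MIXTURE",
]

# Relative category frequencies of the expanded distortion corpus,
# normalized to a simplex (order matches DISTORTIONS).
_EXPANDED_COUNTS = np.array(
    [128, 56, 77, 229, 142, 144, 32, 233, 346, 84, 131], dtype=float
)
DEFAULT_CATEGORY_MIXTURE: tuple[float, ...] = tuple(
    _EXPANDED_COUNTS / _EXPANDED_COUNTS.sum()
)

# One marker token per category, unique across the bank; neutral templates
# and topic/filler vocabulary never use these tokens.
MARKER_TOKENS: dict[DistortionCategory, str] = {
    DistortionCategory.DICHOTOMOUS_REASONING: "either",
    DistortionCategory.DISQUALIFYING_POSITIVE: "fluke",
    DistortionCategory.EMOTIONAL_REASONING: "feelings",
    DistortionCategory.FORTUNE_TELLING: "doomed",
    DistortionCategory.LABELING_MISLABELING: "loser",
    DistortionCategory.MAGNIFICATION_MINIMIZATION: "catastrophe",
    DistortionCategory.MENTAL_FILTERING: "overshadows",
    DistortionCategory.MINDREADING: "thinks",
    DistortionCategory.OVERGENERALIZING: "always",
    DistortionCategory.PERSONALIZATION: "fault",
    DistortionCategory.SHOULD_STATEMENTS: "should",
}

_CATEGORY_TEMPLATES: dict[DistortionCategory, list[str]] = {
    DistortionCategory.DICHOTOMOUS_REASONING: [
        "the {topic} is either perfect or a complete failure no middle ground",
        "with {topic} it is either all good or all bad for me",
    ],
    DistortionCategory.DISQUALIFYING_POSITIVE: [
        "the {topic} went well today but that was just a fluke",
        "people praised my {topic} yet it was a fluke and does not count",
    ],
    DistortionCategory.EMOTIONAL_REASONING: [
        "my feelings tell me the {topic} is hopeless so it must be true",
        "i know the {topic} is bad because my feelings say so",
    ],
    DistortionCategory.FORTUNE_TELLING: [
        "i am sure the {topic} is doomed to go wrong tomorrow",
        "no point trying the {topic} is doomed before it starts",
    ],
    DistortionCategory.LABELING_MISLABELING: [
        "i messed up the {topic} once so i am a loser",
        "after that {topic} everyone can see i am a total loser",
    ],
    DistortionCategory.MAGNIFICATION_MINIMIZATION: [
        "this tiny problem with the {topic} is an absolute catastrophe",
        "one small slip in the {topic} and now everything is a catastrophe",
    ],
    DistortionCategory.MENTAL_FILTERING: [
        "one bad remark about the {topic} overshadows every good thing",
        "the single flaw in the {topic} overshadows all the rest",
    ],
    DistortionCategory.MINDREADING: [
        "nobody said anything but everyone thinks my {topic} was pathetic",
        "i can tell she thinks the {topic} was my worst yet",
    ],
    DistortionCategory.OVERGENERALIZING: [
        "the {topic} failed once so it always fails every single time",
        "things with the {topic} always end badly for me",
    ],
    DistortionCategory.PERSONALIZATION: [
        "the {topic} went wrong and it is entirely my fault",
        "whenever the {topic} breaks i know it is my fault somehow",
    ],
    DistortionCategory.SHOULD_STATEMENTS: [
        "i should have handled the {topic} better i really should",
        "a good person should manage the {topic} without complaining",
    ],
}

_NEUTRAL_TEMPLATES: list[str] = [
    "had a quiet afternoon thinking about the {topic}",
    "posting a small update about the {topic} today",
    "went out earlier and then spent time on the {topic}",
    "made some plans for the {topic} later this week",
    "nothing special just the usual {topic} routine",
    "sharing a photo from the {topic} yesterday",
]

# Topic vocabulary keyed by (cohort, age_group). Adolescent depressed users
# talk about mom / friend / love; adult depressed users about work; controls
# about everyday subjects. None of these collide with marker tokens.
_TOPICS: dict[tuple[str, str], list[str]] = {
    ("depression", "young"): ["mom", "friend", "love", "school", "homework"],
    ("depression", "adult"): ["work", "job", "boss", "deadline", "commute"],
    ("control", "young"): ["music", "game", "school", "weekend", "movie"],
    ("control", "adult"): ["garden", "dinner", "weather", "movie", "market"],
}

_EPOCH = datetime(2020, 1, 1, 12, 0, 0, tzinfo=timezone.utc)

_AGE_GROUP_EDGES = (15, 22, 35)  # a: <=15, b: <=22, c: <=35, d: 36+


def _age_group_index(age: int) -> int:
    for i, hi in enumerate(_AGE_GROUP_EDGES):
        if age <= hi:
            return i
    return 3


class TemplateBank(BaseModel):
    """Per-category phrase templates plus neutral templates.

    At ``signal_strength=1`` each category's rendered text contains that
    category's unique marker token; dropping the signal swaps in a neutral
    template, making the text independent of the label.
    """

    category_templates: dict[DistortionCategory, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in _CATEGORY_TEMPLATES.items()}
    )
    neutral_templates: list[str] = Field(
        default_factory=lambda: list(_NEUTRAL_TEMPLATES)
    )
    markers: dict[DistortionCategory, str] = Field(
        default_factory=lambda: dict(MARKER_TOKENS)
    )

    @model_validator(mode="after")
    def _markers_unique_and_present(self) -> "TemplateBank":
        codes = list(self.markers.values())
        if len(set(codes)) != len(codes):
            raise ValueError("marker tokens must be unique across categories")
        for cat, templates in self.category_templates.items():
            marker = self.markers[cat]
            for t in templates:
                if marker not in t.split() and marker not in t:
                    raise ValueError(
                        f"template for {cat.code} lacks its marker {marker!r}: {t!r}"
                    )
        for t in self.neutral_templates:
            for marker in self.markers.values():
                if marker in t.split():
                    raise ValueError(
                        f"neutral template contains marker {marker!r}: {t!r}"
                    )
        return self

    def render(
        self,
        category: DistortionCategory,
        signal: bool,
        topic: str,
        rng: np.random.Generator,
        marker_variants: int = 1,
        marker_only: bool = False,
    ) -> str:
        distorted = category.is_distortion and signal
        if distorted and not marker_only:
            pool = self.category_templates[category]
        else:
            pool = self.neutral_templates
        template = pool[int(rng.integers(len(pool)))]
        text = template.format(topic=topic)
        base = self.markers[category] if category.is_distortion else None
        if distorted and marker_only:
            # neutral sentence with the marker token embedded: the label is
            # signaled by the marker alone, not by template phrasing
            words = text.split()
            pos = int(rng.integers(len(words) + 1))
            words.insert(pos, base)
            text = " ".join(words)
        if distorted and marker_variants > 1:
            # emulate lexical diversity: each category has marker_variants
            # distinct surface forms, all sharing the category's base marker
            # as a prefix (synthetic vocabulary)
            k = int(rng.integers(marker_variants))
            if k > 0:
                text = " ".join(
                    f"{base}{k}" if tok == base else tok
                    for tok in text.split()
                )
        return text


class GeneratorConfig(BaseModel):
    """Study conditions for corpus generation.

    Defaults encode the structure the cohort analyses assume: a 30% depressed
    minority, a 0.30 vs 0.05 per-post distortion rate contrast between
    cohorts, a distortion rate declining ~15% per age group, and fully
    text-separable labels (``signal_strength=1``).
    """

    n_users: int = 200
    depressed_fraction: float = 0.3
    posts_per_user_mean: float = 50.0
    posts_per_user_dispersion: float = 0.2
    p_distortion_depressed: float = 0.30
    p_distortion_control: float = 0.05
    category_mixture_depressed: tuple[float, ...] = DEFAULT_CATEGORY_MIXTURE
    category_mixture_control: tuple[float, ...] = DEFAULT_CATEGORY_MIXTURE
    age_min: int = 10
    age_max: int = 60
    age_decline_slope: float = 0.15
    signal_strength: float = 1.0
    marker_variants: int = 1
    marker_only_text: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "GeneratorConfig":
        for name in ("depressed_fraction", "p_distortion_depressed",
                     "p_distortion_control", "signal_strength"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("category_mixture_depressed", "category_mixture_control"):
            mix = np.asarray(getattr(self, name), dtype=float)
            if mix.shape != (len(DISTORTIONS),):
                raise ValueError(f"{name} must have {len(DISTORTIONS)} entries")
            if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must be a simplex vector")
        if self.n_users <= 0 or self.posts_per_user_mean <= 0:
            raise ValueError("n_users and posts_per_user_mean must be positive")
        if self.marker_variants < 1:
            raise ValueError("marker_variants must be >= 1")
        if not (10 <= self.age_min <= self.age_max):
            raise ValueError("require 10 <= age_min <= age_max")
        if self.age_decline_slope < 0 or self.age_decline_slope > 1 / 3:
            raise ValueError("age_decline_slope must lie in [0, 1/3]")
        return self

    def rate_for(self, depressed: bool, age: int) -> float:
        base = self.p_distortion_depressed if depressed else self.p_distortion_control
        factor = 1.0 - self.age_decline_slope * _age_group_index(age)
        return max(0.0, base * factor)


def _n_posts(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    # gamma-poisson mixture: mean m, extra-poisson dispersion controlled by
    # posts_per_user_dispersion (0 -> pure poisson)
    m = cfg.posts_per_user_mean
    d = cfg.posts_per_user_dispersion
    lam = m if d <= 0 else rng.gamma(shape=1.0 / d, scale=m * d)
    return max(1, int(rng.poisson(lam)))


def _make_post(
    post_id: str,
    user_id: str,
    category: DistortionCategory,
    cohort: str,
    age: int,
    day: int,
    cfg: GeneratorConfig,
    bank: TemplateBank,
    rng: np.random.Generator,
) -> Post:
    group = "young" if _age_group_index(age) <= 1 else "adult"
    topics = _TOPICS[(cohort, group)]
    topic = topics[int(rng.integers(len(topics)))]
    signal = bool(rng.random() < cfg.signal_strength)
    text = bank.render(category, signal, topic, rng,
                       marker_variants=cfg.marker_variants,
                       marker_only=cfg.marker_only_text)
    if day < 0:
        ts = "2020-01-01T00:00:00+00:00"
    else:
        ts = (_EPOCH + timedelta(days=day)).isoformat()
    return Post(
        post_id=post_id,
        user_id=user_id,
        text=text,
        timestamp=ts,
        label=category,
        label_source="gold",
    )


def generate_corpus(
    config: GeneratorConfig, bank: Optional[TemplateBank] = None
) -> list[UserRecord]:
    """Generate a user corpus; deterministic given ``config.seed``."""
    bank = bank or TemplateBank()
    rng = np.random.default_rng(config.seed)
    mix_dep = np.asarray(config.category_mixture_depressed)
    mix_ctl = np.asarray(config.category_mixture_control)
    users: list[UserRecord] = []
    for i in range(config.n_users):
        depressed = bool(rng.random() < config.depressed_fraction)
        cohort = "depression" if depressed else "control"
        age = int(rng.integers(config.age_min, config.age_max + 1))
        rate = config.rate_for(depressed, age)
        mix = mix_dep if depressed else mix_ctl
        uid = f"u{i:05d}"
        n = _n_posts(config, rng)
        posts = []
        for t in range(n):
            if rng.random() < rate:
                cat = DISTORTIONS[int(rng.choice(len(DISTORTIONS), p=mix))]
            else:
                cat = DistortionCategory.NORMAL
            posts.append(
                _make_post(f"{uid}_p{t:05d}", uid, cat, cohort, age, t, config,
                           bank, rng)
            )
        users.append(
            UserRecord(
                user_id=uid,
                posts=posts,
                depression_label=int(depressed),
                age=age,
                cohort=cohort,
            )
        )
    return users


class SeedPool(NamedTuple):
    """A labeled seed set plus an unlabeled pool with withheld gold labels."""

    seed: list[Post]
    pool: list[Post]
    answers: dict[str, DistortionCategory]


def generate_seed_and_pool(
    config: GeneratorConfig,
    n_seed_distorted: int = 353,
    n_seed_normal: int = 1000,
    pool_size: int = 3000,
    pool_distortion_rate: float = 0.3,
    bank: Optional[TemplateBank] = None,
) -> SeedPool:
    """Emulate seed-corpus construction plus an unlabeled expansion pool.

    The seed is small and fully gold-labeled (default 353 distorted + 1,000
    normal posts, the scale of a hand-collected distortion corpus); the pool
    is emitted unlabeled, with true categories retained in ``answers`` keyed
    by post_id so that sampled-inspection precision can be scored exactly.
    """
    bank = bank or TemplateBank()
    rng = np.random.default_rng(config.seed + 1_000_003)
    mix = np.asarray(config.category_mixture_depressed)

    def draw(post_id: str, category: DistortionCategory, labeled: bool) -> Post:
        cohort = "depression" if category.is_distortion else "control"
        age = int(rng.integers(config.age_min, config.age_max + 1))
        p = _make_post(post_id, "pool" if not labeled else "seed", category,
                       cohort, age, -1, config, bank, rng)
        if not labeled:
            return p.model_copy(update={"label": None, "label_source": "none"})
        return p

    seed: list[Post] = []
    for j in range(n_seed_distorted):
        cat = DISTORTIONS[int(rng.choice(len(DISTORTIONS), p=mix))]
        seed.append(draw(f"seed_d{j:05d}", cat, labeled=True))
    for j in range(n_seed_normal):
        seed.append(draw(f"seed_n{j:05d}", DistortionCategory.NORMAL, labeled=True))

    pool: list[Post] = []
    answers: dict[str, DistortionCategory] = {}
    for j in range(pool_size):
        if rng.random() < pool_distortion_rate:
            cat = DISTORTIONS[int(rng.choice(len(DISTORTIONS), p=mix))]
        else:
            cat = DistortionCategory.NORMAL
        pid = f"pool{j:06d}"
        answers[pid] = cat
        pool.append(draw(pid, cat, labeled=False))
    return SeedPool(seed=seed, pool=pool, answers=answers)


def keyword_classify(
    text: str, markers: Optional[dict[DistortionCategory, str]] = None
) -> DistortionCategory:
    """Marker-token lookup classifier; Bayes-optimal at signal_strength=1.

    Matches marker surface-form variants by prefix (no base marker is a
    prefix of another), so it stays exact for any ``marker_variants``.
    """
    markers = markers or MARKER_TOKENS
    tokens = text.lower().split()
    for cat in DISTORTIONS:  # fixed order => deterministic tie-break
        base = markers[cat]
        for tok in tokens:
            if tok == base or (
                tok.startswith(base) and tok[len(base):].isdigit()
            ):
                return cat
    return DistortionCategory.NORMAL
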