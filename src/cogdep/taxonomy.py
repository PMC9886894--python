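"""The fixed cognitive-distortion taxonomy.

Beck's cognitive model of depression describes systematically biased thought
patterns ("cognitive distortions") that reinforce negative affect.  The
classifier in this package labels every post with one of the eleven classic
distortion categories, or ``NORMAL`` when no distortion is present, for a
fixed 12-way output space.  Category codes double as on-disk label strings
and as output-head indices (``NORMAL`` is always index 11), so the taxonomy
is closed: unknown labels are hard errors, never coerced.
"""

from __future__ import annotations

import enum


class TaxonomyError(ValueError):
    """Raised when a label string is not one of the 12 known codes."""


class DistortionCategory(enum.Enum):
    """The 11 cognitive-distortion categories plus NORMAL.

    The enum value is the stable on-disk code; ``index`` is the position in
    the classifier's 12-way output head.
    """

    DICHOTOMOUS_REASONING = "dichotomous_reasoning"
    DISQUALIFYING_POSITIVE = "disqualifying_the_positive"
    EMOTIONAL_REASONING = "emotional_reasoning"
    FORTUNE_TELLING = "fortune_telling"
    LABELING_MISLABELING = "labeling_and_mislabeling"
    MAGNIFICATION_MINIMIZATION = "magnification_and_minimization"
    MENTAL_FILTERING = "mental_filtering"
    MINDREADING = "mindreading"
    OVERGENERALIZING = "overgeneralizing"
    PERSONALIZATION = "personalization"
    SHOULD_STATEMENTS = "should_statements"
    NORMAL = "normal"

    @property
    def code(self) -> str:
        return self.value

    @property
    def display_name(self) -> str:
        return self.value.replace("_", " ").capitalize()

    @property
    def index(self) -> int:
        return _INDEX[self]

    @property
    def is_distortion(self) -> bool:
        return self is not DistortionCategory.NORMAL

    @classmethod
    def from_code(cls, code: str) -> "DistortionCategory":
        try:
            return cls(code)
        except ValueError:
            raise TaxonomyError(
                f"unknown distortion category {code!r}; expected one of "
                f"{sorted(c.value for c in cls)}"
            ) from None

    @classmethod
    def from_index(cls, index: int) -> "DistortionCategory":
        return _ORDER[index]


_ORDER = list(DistortionCategory)
_INDEX = {c: i for i, c in enumerate(_ORDER)}

#: The 11 distortion categories, excluding NORMAL, in head order.
DISTORTIONS: tuple[DistortionCategory, ...] = tuple(_ORDER[:-1])

#: Number of output classes of the post-level head.
N_CLASSES: int = len(_ORDER)

CATEGORY_DESCRIPTIONS: dict[DistortionCategory, str] = {
    DistortionCategory.DICHOTOMOUS_REASONING: (
        "Sees things in extremes; something is either fantastic or awful."
    ),
    DistortionCategory.DISQUALIFYING_POSITIVE: (
        "Acknowledges positive experiences but rejects them."
    ),
    DistortionCategory.EMOTIONAL_REASONING: "Treats emotions as facts.",
    DistortionCategory.FORTUNE_TELLING: (
        "Draws confident predictions from little or no evidence."
    ),
    DistortionCategory.LABELING_MISLABELING: (
        "Assigns value judgments to self or others from a single instance."
    ),
    DistortionCategory.MAGNIFICATION_MINIMIZATION: (
        "Exaggerates or minimizes the importance or likelihood of events."
    ),
    DistortionCategory.MENTAL_FILTERING: (
        "Focuses on a single negative detail, excluding all positives."
    ),
    DistortionCategory.MINDREADING: (
        "Believes, without evidence, to know what another person thinks."
    ),
    DistortionCategory.OVERGENERALIZING: (
        "Generalizes one instance into an overall pattern."
    ),
    DistortionCategory.PERSONALIZATION: (
        "Takes everything personally or self-assigns blame without reason."
    ),
    DistortionCategory.SHOULD_STATEMENTS: (
        "Rigid 'should'/'must' statements about self or others."
    ),
    DistortionCategory.NORMAL: "No cognitive distortion present.",
}
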