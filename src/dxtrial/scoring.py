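"""Answer keys and correctness rules for the vignette question and the
five-item baseline-knowledge quiz.

Classification is three-way: correct, incorrect, or blank. A blank is an
abstention — an empty answer or an explicit "don't know" — and never counts
as correct. Numeric answers outside [0, 100] are attempts, so they score as
incorrect, not blank.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum
from typing import Literal, Sequence

from .bayes_core import LikelihoodRatios, TestAccuracy

__all__ = [
    "AnswerStatus",
    "QuizKey",
    "QuizResult",
    "parse_answer",
    "score_posttest_answer",
    "quiz_key",
    "score_quiz",
    "classify_management",
    "DEFAULT_MARGIN",
    "SENSITIVITY_MARGIN",
]

#: Primary scoring margin (percentage points, either direction).
DEFAULT_MARGIN = 1.0
#: Wider margin used in the post-hoc sensitivity analysis.
SENSITIVITY_MARGIN = 3.0

_BLANK_STRINGS = {"", "dont know", "don't know", "dk", "na", "n/a", "unknown"}


class AnswerStatus(str, Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    BLANK = "blank"


def parse_answer(raw) -> float | None:
    """Parse a raw percent answer leniently; ``None`` means blank.

    Accepts numbers and strings like "86", "86%", "86.0". Empty strings and
    "don't know" variants map to blank. Non-numeric text also maps to blank
    (the survey widget was a free text box).
    """
    if raw is None:
        return None
    if isinstance(raw, (int, float)):
        if isinstance(raw, float) and math.isnan(raw):
            return None
        return float(raw)
    s = str(raw).strip().lower().replace("’", "'")
    if s in _BLANK_STRINGS:
        return None
    s = s.rstrip("%").strip()
    if re.fullmatch(r"[+-]?\d+(\.\d+)?", s):
        return float(s)
    return None


def score_posttest_answer(answer, key: float, margin: float = DEFAULT_MARGIN) -> AnswerStatus:
    """Score a percent answer against a key with a symmetric margin.

    Correct iff ``|answer - key| <= margin``. Out-of-range numeric answers
    (outside [0, 100]) are incorrect.
    """
    if not (0.0 <= key <= 100.0):
        raise ValueError(f"key must lie in [0, 100], got {key!r}")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    value = parse_answer(answer)
    if value is None:
        return AnswerStatus.BLANK
    if not (0.0 <= value <= 100.0):
        return AnswerStatus.INCORRECT
    # small slack so float noise in a derived key (e.g. 100*(1-0.9)) cannot
    # flip a boundary answer
    return (
        AnswerStatus.CORRECT
        if abs(value - key) <= margin + 1e-9
        else AnswerStatus.INCORRECT
    )


@dataclass(frozen=True)
class QuizKey:
    """Answer key for the five-question baseline-knowledge quiz.

    q1-q4 are whole-percent keys; q5 is categorical (ruling_in/ruling_out).
    q1 = % of diseased missed; q2 = PPV; q3 = false positive rate;
    q4 = % of test-negatives who are diseased; q5 from the stronger LR.
    """

    q1: float
    q2: float
    q3: float
    q4: float
    q5: Literal["ruling_in", "ruling_out"]

    def to_dict(self) -> dict:
        return {"q1": self.q1, "q2": self.q2, "q3": self.q3, "q4": self.q4, "q5": self.q5}


def quiz_key(
    acc: TestAccuracy, ppv: float, npv: float, lrs: LikelihoodRatios
) -> QuizKey:
    """Build the quiz key from a test's accuracy, predictive values and LRs.

    PPV/NPV are passed in (not derived) because the quiz states them
    directly and never states the prevalence they imply.
    """
    if math.isinf(lrs.lr_positive):
        q5: Literal["ruling_in", "ruling_out"] = "ruling_in"
    else:
        strength_in = abs(math.log(lrs.lr_positive)) if lrs.lr_positive > 0 else math.inf
        strength_out = abs(math.log(lrs.lr_negative)) if lrs.lr_negative > 0 else math.inf
        q5 = "ruling_out" if strength_out > strength_in else "ruling_in"
    return QuizKey(
        q1=100.0 * (1.0 - acc.sensitivity),
        q2=100.0 * ppv,
        q3=100.0 * (1.0 - acc.specificity),
        q4=100.0 * (1.0 - npv),
        q5=q5,
    )


@dataclass(frozen=True)
class QuizResult:
    statuses: tuple[AnswerStatus, AnswerStatus, AnswerStatus, AnswerStatus, AnswerStatus]
    total_correct: int


def score_quiz(answers: Sequence, key: QuizKey, margin: float = DEFAULT_MARGIN) -> QuizResult:
    """Score five raw quiz answers against a key.

    q1-q4 use the numeric margin rule; q5 is an exact category match.
    The margin for q1-q4 defaults to the vignette's +/-1 rule (the survey
    itself states no margin for the quiz) and is configurable.
    """
    if len(answers) != 5:
        raise ValueError(f"expected exactly 5 answers, got {len(answers)}")
    statuses = [
        score_posttest_answer(answers[i], k, margin)
        for i, k in enumerate((key.q1, key.q2, key.q3, key.q4))
    ]
    raw5 = "" if answers[4] is None else str(answers[4]).strip().lower().replace("’", "'")
    if raw5 in _BLANK_STRINGS:
        statuses.append(AnswerStatus.BLANK)
    else:
        canon = raw5.replace(" ", "_")
        statuses.append(
            AnswerStatus.CORRECT if canon == key.q5 else AnswerStatus.INCORRECT
        )
    total = sum(1 for s in statuses if s is AnswerStatus.CORRECT)
    return QuizResult(statuses=tuple(statuses), total_correct=total)


_MANAGEMENT_ALIASES = {
    "treat": "treat",
    "not treat": "no_treat",
    "no treat": "no_treat",
    "no_treat": "no_treat",
    "do not treat": "no_treat",
    "order brain biopsy": "biopsy",
    "brain biopsy": "biopsy",
    "biopsy": "biopsy",
}


def classify_management(choice) -> str:
    """Canonicalise a raw management choice to treat|biopsy|no_treat|blank."""
    if choice is None:
        return "blank"
    if isinstance(choice, float) and math.isnan(choice):
        return "blank"
    s = str(choice).strip().lower().replace("“", "").replace("”", "")
    return _MANAGEMENT_ALIASES.get(s, "blank")
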