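"""Synthetic respondent cohorts with the statistical structure the trial
analysis assumes.

The default model is parameterised entirely by the published margins and
arm-level outcome proportions, plus a declared (not published) wrong-answer
mixture and a tutorial-uptake logistic model whose intercept is calibrated
to the published overall uptake. Two generators are provided:

* :func:`sample_cohort` — draws records stochastically from the model;
* :func:`sample_exact_table` — places records so the tabulation equals the
  published outcome counts exactly (the regression fixture).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from . import reference
from .bayes_core import likelihood_ratios
from .records import ResponseRecord
from .reference import ARMS
from .scoring import AnswerStatus, QuizKey, quiz_key, score_quiz

__all__ = [
    "CohortModel",
    "default_model_from_reference",
    "sample_cohort",
    "sample_exact_table",
    "tutorial_design",
    "poisson_binomial_pmf",
]

_ANSWER_STATUSES = ("correct", "incorrect", "blank")


@dataclass(frozen=True)
class CohortModel:
    """Generative model for a respondent cohort.

    All probability vectors are proportions; ``arm_probs`` and the per-arm
    outcome probabilities are stored as exact fractions of the published
    counts in the default model, so exact-table generation is possible.
    """

    n: int
    arm_probs: dict
    management_probs: dict
    answer_probs: dict
    correct_values: tuple = (85, 86, 87)
    wrong_values: tuple = (60, 90, 10, 50)
    wrong_weight: float = 0.6  # rest of the wrong mass is uniform off-key noise
    vignette_key: float = 86.0
    quiz_numeric_keys: tuple = (10.0, 33.0, 50.0, 5.0)
    quiz_q5_key: str = "ruling_out"
    quiz_p_correct: tuple = (0.55, 0.30, 0.45, 0.40, 0.50)
    quiz_p_blank: tuple = (0.15, 0.15, 0.15, 0.15, 0.15)
    age_margin: dict = field(default_factory=lambda: dict(reference.AGE_MARGIN))
    sex_margin: dict = field(default_factory=lambda: dict(reference.SEX_MARGIN))
    status_margin: dict = field(default_factory=lambda: dict(reference.STATUS_MARGIN))
    postgrad_margin: dict = field(default_factory=lambda: dict(reference.POSTGRAD_MARGIN))
    confidence_margin: dict = field(default_factory=lambda: dict(reference.CONFIDENCE_MARGIN))
    tutorial_intercept: float = 0.0
    tutorial_log_or_score: float = math.log(reference.TUTORIAL_OR_PER_CORRECT)
    tutorial_log_or_confidence: float = math.log(reference.TUTORIAL_OR_PER_CONFIDENCE)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be at least 1")
        vectors = [tuple(self.arm_probs[a] for a in ARMS)]
        vectors += [
            tuple(self.management_probs[a][c] for c in ("treat", "biopsy", "no_treat", "blank"))
            for a in ARMS
        ]
        vectors += [tuple(self.answer_probs[a][s] for s in _ANSWER_STATUSES) for a in ARMS]
        for v in vectors:
            if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-12:
                raise ValueError("probability vectors must be non-negative and sum to 1")

    def quiz_key_object(self) -> QuizKey:
        k = self.quiz_numeric_keys
        return QuizKey(q1=k[0], q2=k[1], q3=k[2], q4=k[3], q5=self.quiz_q5_key)  # type: ignore[arg-type]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortModel":
        raw = json.loads(text)
        for key in ("correct_values", "wrong_values", "quiz_numeric_keys",
                    "quiz_p_correct", "quiz_p_blank"):
            raw[key] = tuple(raw[key])
        raw["confidence_margin"] = {int(k): v for k, v in raw["confidence_margin"].items()}
        return cls(**raw)


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """PMF of a sum of independent Bernoulli variables, by dynamic programming."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def _normalised(margin: dict) -> tuple[list, np.ndarray]:
    keys = list(margin)
    w = np.array([float(margin[k]) for k in keys])
    return keys, w / w.sum()


def _calibrate_tutorial_intercept(model: CohortModel, target: float) -> float:
    """Intercept such that expected uptake over the score x confidence grid
    (taken independent) equals ``target``."""
    score_pmf = poisson_binomial_pmf(
        [pc for pc in model.quiz_p_correct]
    )
    conf_keys, conf_w = _normalised(model.confidence_margin)
    scores = np.arange(score_pmf.size)

    def expected_uptake(a: float) -> float:
        total = 0.0
        for ci, cw in zip(conf_keys, conf_w):
            eta = a + model.tutorial_log_or_score * scores + model.tutorial_log_or_confidence * ci
            total += float(cw * np.dot(score_pmf, expit(eta)))
        return total

    return float(brentq(lambda a: expected_uptake(a) - target, -20.0, 20.0, xtol=1e-12))


def default_model_from_reference(n: int = 874, seed: int = 0) -> CohortModel:
    """The cohort model parameterised by the published trial margins.

    Arm allocation and per-arm outcome probabilities are the observed
    proportions; the tutorial intercept is calibrated so that overall
    expected uptake matches the published 36.2%.
    """
    total = sum(reference.ARM_TOTALS.values())
    arm_probs = {a: reference.ARM_TOTALS[a] / total for a in ARMS}
    management_probs = {
        a: {c: reference.MANAGEMENT_COUNTS[a][c] / reference.ARM_TOTALS[a]
            for c in ("treat", "biopsy", "no_treat", "blank")}
        for a in ARMS
    }
    answer_probs = {
        a: {s: reference.CORRECTNESS_COUNTS[a][s] / reference.ARM_TOTALS[a]
            for s in _ANSWER_STATUSES}
        for a in ARMS
    }
    lrs = likelihood_ratios(reference.QUIZ_ACCURACY)
    key = quiz_key(reference.QUIZ_ACCURACY, reference.QUIZ_PPV, reference.QUIZ_NPV, lrs)
    model = CohortModel(
        n=n,
        arm_probs=arm_probs,
        management_probs=management_probs,
        answer_probs=answer_probs,
        quiz_numeric_keys=(key.q1, key.q2, key.q3, key.q4),
        quiz_q5_key=key.q5,
        seed=seed,
    )
    intercept = _calibrate_tutorial_intercept(model, reference.TUTORIAL_UPTAKE_OVERALL)
    return replace(model, tutorial_intercept=intercept)


# backwards-compatible alias used in docs
default_model = default_model_from_reference


def _draw_from_margin(rng: np.random.Generator, margin: dict, size: int) -> list:
    keys, w = _normalised(margin)
    idx = rng.choice(len(keys), size=size, p=w)
    return [keys[i] for i in idx]


def _wrong_answer_values(model: CohortModel, rng: np.random.Generator, size: int) -> np.ndarray:
    """Wrong vignette answers: classic-error mixture plus off-key uniform noise."""
    key = int(model.vignette_key)
    excluded = {key - 1, key, key + 1}
    uniform_support = np.array([v for v in range(0, 101) if v not in excluded])
    values = np.empty(size, dtype=int)
    use_classic = rng.random(size) < model.wrong_weight
    n_classic = int(use_classic.sum())
    classic = np.asarray(model.wrong_values)
    values[use_classic] = classic[rng.integers(0, classic.size, size=n_classic)]
    values[~use_classic] = uniform_support[
        rng.integers(0, uniform_support.size, size=size - n_classic)
    ]
    return values


def sample_cohort(model: CohortModel, seed: Optional[int] = None) -> list[ResponseRecord]:
    """Draw a cohort of ``model.n`` respondent records.

    Reproducible: a fixed (model, seed) pair always yields the same
    records. Demographics are drawn independently of outcomes.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    n = model.n
    arm_idx = rng.choice(len(ARMS), size=n, p=[model.arm_probs[a] for a in ARMS])
    arms = [ARMS[i] for i in arm_idx]

    managements = [""] * n
    answer_status = [""] * n
    mgmt_cats = ("treat", "biopsy", "no_treat", "blank")
    for ai, arm in enumerate(ARMS):
        rows = np.flatnonzero(arm_idx == ai)
        if rows.size == 0:
            continue
        mg = rng.choice(4, size=rows.size, p=[model.management_probs[arm][c] for c in mgmt_cats])
        st = rng.choice(3, size=rows.size,
                        p=[model.answer_probs[arm][s] for s in _ANSWER_STATUSES])
        for j, r in enumerate(rows):
            managements[r] = mgmt_cats[mg[j]]
            answer_status[r] = _ANSWER_STATUSES[st[j]]

    answers = [""] * n
    correct_rows = [i for i, s in enumerate(answer_status) if s == "correct"]
    wrong_rows = [i for i, s in enumerate(answer_status) if s == "incorrect"]
    cv = np.asarray(model.correct_values)
    picked = cv[rng.integers(0, cv.size, size=len(correct_rows))]
    for i, v in zip(correct_rows, picked):
        answers[i] = str(int(v))
    for i, v in zip(wrong_rows, _wrong_answer_values(model, rng, len(wrong_rows))):
        answers[i] = str(int(v))

    ages = _draw_from_margin(rng, model.age_margin, n)
    sexes = _draw_from_margin(rng, model.sex_margin, n)
    statuses = _draw_from_margin(rng, model.status_margin, n)
    postgrads = _draw_from_margin(rng, model.postgrad_margin, n)
    confidences = _draw_from_margin(rng, model.confidence_margin, n)

    # quiz answers, per question: correct / blank / wrong (key shifted off-margin)
    quiz_cols: list[list[str]] = []
    keys = list(model.quiz_numeric_keys) + [model.quiz_q5_key]
    for q in range(5):
        u = rng.random(n)
        pc, pb = model.quiz_p_correct[q], model.quiz_p_blank[q]
        col = []
        for i in range(n):
            if u[i] < pc:
                col.append(str(int(keys[q])) if q < 4 else str(keys[q]))
            elif u[i] < pc + pb:
                col.append("")
            else:
                if q < 4:
                    col.append(str(int((keys[q] + 17) % 101)))
                else:
                    col.append("ruling_in" if keys[q] == "ruling_out" else "ruling_out")
        quiz_cols.append(col)

    scores = np.zeros(n)
    for q in range(5):
        target = str(int(keys[q])) if q < 4 else str(keys[q])
        scores += np.array([1.0 if v == target else 0.0 for v in quiz_cols[q]])

    conf_arr = np.array([float(c) for c in confidences])
    eta = (model.tutorial_intercept
           + model.tutorial_log_or_score * scores
           + model.tutorial_log_or_confidence * conf_arr)
    uptake = rng.random(n) < expit(eta)

    return [
        ResponseRecord(
            id=f"r{i:06d}",
            arm=arms[i],
            posttest_answer=answers[i],
            management="" if managements[i] == "blank" else managements[i],
            age_group=ages[i],
            sex=sexes[i],
            status=statuses[i],
            postgrad_training=postgrads[i],
            confidence=int(confidences[i]),
            q1=quiz_cols[0][i], q2=quiz_cols[1][i], q3=quiz_cols[2][i],
            q4=quiz_cols[3][i], q5=quiz_cols[4][i],
            tutorial_uptake="yes" if uptake[i] else "no",
        )
        for i in range(n)
    ]


def _exact_int(x: float, what: str) -> int:
    r = round(x)
    if abs(x - r) > 1e-9:
        raise ValueError(f"{what} = {x!r} is not integral; exact-table generation impossible")
    return int(r)


def sample_exact_table(model: CohortModel) -> list[ResponseRecord]:
    """Deterministic cohort whose tabulation equals the model's outcome
    counts exactly (counts are placed, not sampled).

    Requires every ``probability x group size`` product to be integral —
    true for the default model, whose probabilities are count fractions.
    Demographics cycle through the margin categories and carry no signal.
    """
    records: list[ResponseRecord] = []
    age_cycle = itertools.cycle(model.age_margin)
    sex_cycle = itertools.cycle(model.sex_margin)
    status_cycle = itertools.cycle(model.status_margin)
    pg_cycle = itertools.cycle(model.postgrad_margin)
    for arm in ARMS:
        n_arm = _exact_int(model.n * model.arm_probs[arm], f"n x arm_probs[{arm}]")
        mgmt_counts = {
            c: _exact_int(n_arm * model.management_probs[arm][c], f"management[{arm}][{c}]")
            for c in ("treat", "biopsy", "no_treat", "blank")
        }
        ans_counts = {
            s: _exact_int(n_arm * model.answer_probs[arm][s], f"answers[{arm}][{s}]")
            for s in _ANSWER_STATUSES
        }
        if sum(mgmt_counts.values()) != n_arm or sum(ans_counts.values()) != n_arm:
            raise ValueError(f"counts for arm {arm!r} do not sum to the arm size")
        mgmt_seq = [c for c in ("treat", "biopsy", "no_treat", "blank")
                    for _ in range(mgmt_counts[c])]
        key = int(model.vignette_key)
        ans_seq = ([str(key)] * ans_counts["correct"]
                   + [str((key + 17) % 101)] * ans_counts["incorrect"]
                   + [""] * ans_counts["blank"])
        for i, (mg, ans) in enumerate(zip(mgmt_seq, ans_seq)):
            records.append(ResponseRecord(
                id=f"{arm}-{i:04d}",
                arm=arm,
                posttest_answer=ans,
                management="" if mg == "blank" else mg,
                age_group=next(age_cycle),
                sex=next(sex_cycle),
                status=next(status_cycle),
                postgrad_training=next(pg_cycle),
                confidence=3,
                q1="", q2="", q3="", q4="", q5="",
                tutorial_uptake="no",
            ))
    return records


def tutorial_design(
    records: Sequence[ResponseRecord], key: QuizKey
) -> tuple[np.ndarray, np.ndarray]:
    """(outcome, design) arrays for the tutorial-uptake logistic model:
    intercept, total quiz score, and self-rated confidence."""
    y = np.array([1.0 if r.tutorial_uptake == "yes" else 0.0 for r in records])
    scores = np.array([
        float(score_quiz([r.q1, r.q2, r.q3, r.q4, r.q5], key).total_correct)
        for r in records
    ])
    conf = np.array([float(r.confidence) for r in records])
    X = np.column_stack([np.ones(len(records)), scores, conf])
    return y, X
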