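"""Trial statistics: arm tabulation, 2x2 odds ratios with Wald CIs,
chi-squared heterogeneity, proportions, IRLS logistic regression, and the
design power calculation.

Outcome coding for odds ratios is target-vs-everything-else (e.g. treat vs
{biopsy, no-treat, blank}; correct vs {incorrect, blank}), with the
text-only arm as reference — the coding that reproduces every published
OR/CI pair from the arm counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, norm

from . import reference
from .records import ResponseRecord
from .reference import ARMS
from .scoring import DEFAULT_MARGIN, AnswerStatus, classify_management, score_posttest_answer

__all__ = [
    "ArmOutcomeTable",
    "OddsRatioResult",
    "ChiSquaredResult",
    "LogisticFit",
    "PowerSpec",
    "ConvergenceWarning",
    "MANAGEMENT_CATEGORIES",
    "CORRECTNESS_CATEGORIES",
    "tabulate",
    "odds_ratio",
    "chi_squared",
    "proportion_correct",
    "logistic_irls",
    "fit_outcome_by_arm",
    "detectable_difference",
    "power_for_difference",
    "arm_odds_ratios",
    "analyze_table",
    "format_p_value",
]

MANAGEMENT_CATEGORIES = ("treat", "biopsy", "no_treat", "blank")
CORRECTNESS_CATEGORIES = ("correct", "incorrect", "blank")

#: Default answer key for the vignette question, in percent.
VIGNETTE_KEY = 86.0

Z_95 = 1.96  # Wald CI critical value, matching the published intervals


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ArmOutcomeTable:
    """Per-arm counts of management choices and answer-correctness categories."""

    management: dict
    correctness: dict
    totals: dict

    def __post_init__(self) -> None:
        for arm in ARMS:
            for name, counts, cats in (
                ("management", self.management, MANAGEMENT_CATEGORIES),
                ("correctness", self.correctness, CORRECTNESS_CATEGORIES),
            ):
                cell = counts.get(arm)
                if cell is None or set(cell) != set(cats):
                    raise ValueError(f"{name} counts for arm {arm!r} malformed")
                if any(v < 0 or v != int(v) for v in cell.values()):
                    raise ValueError(f"{name} counts for arm {arm!r} must be non-negative integers")
                if sum(cell.values()) != self.totals[arm]:
                    raise ValueError(
                        f"{name} counts for arm {arm!r} do not sum to the arm total"
                    )

    @classmethod
    def from_reference(cls) -> "ArmOutcomeTable":
        """The published outcome table, as printed."""
        return cls(
            management={a: dict(reference.MANAGEMENT_COUNTS[a]) for a in ARMS},
            correctness={a: dict(reference.CORRECTNESS_COUNTS[a]) for a in ARMS},
            totals=dict(reference.ARM_TOTALS),
        )

    def to_dict(self) -> dict:
        return {
            "management": {a: dict(self.management[a]) for a in ARMS},
            "correctness": {a: dict(self.correctness[a]) for a in ARMS},
            "totals": dict(self.totals),
        }


def tabulate(
    records: Iterable[ResponseRecord],
    key: float = VIGNETTE_KEY,
    margin: float = DEFAULT_MARGIN,
) -> ArmOutcomeTable:
    """Tabulate respondent records into per-arm outcome counts.

    Management choices are canonicalised and post-test answers scored
    against ``key`` with the given margin.
    """
    management = {a: {c: 0 for c in MANAGEMENT_CATEGORIES} for a in ARMS}
    correctness = {a: {c: 0 for c in CORRECTNESS_CATEGORIES} for a in ARMS}
    totals = {a: 0 for a in ARMS}
    for rec in records:
        if rec.arm not in totals:
            raise ValueError(f"unknown arm label {rec.arm!r}")
        totals[rec.arm] += 1
        management[rec.arm][classify_management(rec.management)] += 1
        status = score_posttest_answer(rec.posttest_answer, key, margin)
        correctness[rec.arm][status.value] += 1
    return ArmOutcomeTable(management=management, correctness=correctness, totals=totals)


# ---------------------------------------------------------------------------
# Odds ratios


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    log_or: float
    se_log: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(OR, low, high) at ``ndigits`` decimals, round-half-even."""
        return (
            round(self.odds_ratio, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


def odds_ratio(event_a: int, total_a: int, event_b: int, total_b: int) -> OddsRatioResult:
    """Cross-product odds ratio of group a vs group b with a Wald 95% CI.

    ``se_log`` is the root of summed reciprocal cell counts. If any cell is
    zero, the Haldane correction adds 0.5 to all four cells (flagged).
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= event_a <= total_a) or not (0 <= event_b <= total_b):
        raise ValueError("event counts must lie within their group totals")
    a, c = float(event_a), float(total_a - event_a)
    b, d = float(event_b), float(total_b - event_b)
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if (a + c) == 0 or (b + d) == 0:
        raise ValueError("degenerate table even after continuity correction")
    log_or = math.log((a / c) / (b / d))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return OddsRatioResult(
        odds_ratio=math.exp(log_or),
        log_or=log_or,
        se_log=se,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        continuity_corrected=corrected,
    )


def arm_odds_ratios(
    table: ArmOutcomeTable,
    family: Literal["management", "correctness"],
    target: str,
    reference_arm: str = "text",
) -> dict:
    """Target-vs-rest odds ratio of each non-reference arm vs the reference."""
    counts = table.management if family == "management" else table.correctness
    ref_events = counts[reference_arm][target]
    ref_total = table.totals[reference_arm]
    out = {}
    for arm in ARMS:
        if arm == reference_arm:
            continue
        out[arm] = odds_ratio(counts[arm][target], table.totals[arm], ref_events, ref_total)
    return out


# ---------------------------------------------------------------------------
# Chi-squared heterogeneity


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float


def chi_squared(table) -> ChiSquaredResult:
    """Pearson chi-squared test of independence on an r x c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ValueError(
            "zero expected cell count; collapse empty rows/columns before testing"
        )
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ChiSquaredResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


def correct_vs_not_table(table: ArmOutcomeTable) -> np.ndarray:
    """4x2 table of correct vs not-correct (incorrect + blank) counts by arm."""
    rows = []
    for arm in ARMS:
        c = table.correctness[arm]["correct"]
        rows.append([c, table.totals[arm] - c])
    return np.array(rows)


def proportion_correct(
    table: ArmOutcomeTable, arm: Optional[str] = None
) -> tuple[int, int, float]:
    """(count, total, percent at 1 dp) of correct answers, per arm or overall."""
    if arm is None:
        count = sum(table.correctness[a]["correct"] for a in ARMS)
        total = sum(table.totals[a] for a in ARMS)
    else:
        if arm not in ARMS:
            raise ValueError(f"unknown arm label {arm!r}")
        count = table.correctness[arm]["correct"]
        total = table.totals[arm]
    if total == 0:
        raise ValueError("cannot compute a proportion over a zero total")
    return count, total, round(100.0 * count / total, 1)


# ---------------------------------------------------------------------------
# Logistic regression by IRLS


@dataclass(frozen=True)
class LogisticFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    iterations: int
    gradient_norm: float
    term_names: tuple[str, ...] = ()

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)


def logistic_irls(
    outcome: Sequence[float],
    design: Sequence[Sequence[float]],
    tol: float = 1e-8,
    max_iter: int = 25,
    term_names: Sequence[str] = (),
) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Converged when the score (gradient) inf-norm drops below ``tol``.
    Non-convergence (including separation, where coefficients diverge) is
    flagged via ``converged=False`` and a :class:`ConvergenceWarning`.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("design must be 2-D with one row per outcome")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcome must be binary (0/1)")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")

    beta = np.zeros(X.shape[1])
    grad_norm = np.inf
    converged = False
    iterations = 0
    H = np.eye(X.shape[1])
    for iterations in range(1, max_iter + 1):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = X.T @ (X * w[:, None])
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step

    # under separation the gradient vanishes while the coefficients diverge,
    # so a small gradient alone is not proof of a maximum
    separated = converged and bool(np.all(np.abs(y - expit(X @ beta)) < 1e-6))
    if separated:
        converged = False
    if not converged:
        warnings.warn(
            "logistic IRLS did not converge"
            + (" (perfect separation)" if separated else " (possible separation)")
            + f"; gradient inf-norm {grad_norm:.3g} after {iterations} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
        se = np.full(X.shape[1], np.nan)
    else:
        se = np.sqrt(np.diag(np.linalg.inv(H)))
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        converged=converged,
        iterations=iterations,
        gradient_norm=grad_norm,
        term_names=tuple(term_names),
    )


def fit_outcome_by_arm(
    table: ArmOutcomeTable,
    family: Literal["management", "correctness"],
    target: str,
    reference_arm: str = "text",
) -> LogisticFit:
    """Logistic fit of a target-vs-rest outcome on the 4-level arm factor.

    Expands the arm counts into individual rows with treatment-coded
    dummies; exponentiated non-intercept coefficients are the arm ORs.
    """
    counts = table.management if family == "management" else table.correctness
    other_arms = [a for a in ARMS if a != reference_arm]
    rows, ys = [], []
    for arm in ARMS:
        dummies = [1.0] + [1.0 if arm == o else 0.0 for o in other_arms]
        events = counts[arm][target]
        total = table.totals[arm]
        for _ in range(events):
            rows.append(dummies)
            ys.append(1.0)
        for _ in range(total - events):
            rows.append(dummies)
            ys.append(0.0)
    return logistic_irls(
        ys, rows, term_names=tuple(["intercept"] + [f"arm[{a}]" for a in other_arms])
    )


# ---------------------------------------------------------------------------
# Power calculation


@dataclass(frozen=True)
class PowerSpec:
    """Two-group comparison design: significance, power, size, baseline."""

    alpha: float = reference.DESIGN_ALPHA
    power: float = reference.DESIGN_POWER
    n_per_arm: int = reference.DESIGN_N_PER_ARM
    baseline_p: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 < self.power < 1.0):
            raise ValueError("power must lie in (0, 1)")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be at least 2")
        if not (0.0 < self.baseline_p < 1.0):
            raise ValueError("baseline_p must lie in (0, 1)")


def detectable_difference(spec: PowerSpec) -> float:
    """Minimal detectable two-proportion difference (normal approximation).

    (z_{1-alpha/2} + z_{power}) * sqrt(2 p (1-p) / n)
    """
    z = norm.ppf(1.0 - spec.alpha / 2.0) + norm.ppf(spec.power)
    return float(z * math.sqrt(2.0 * spec.baseline_p * (1.0 - spec.baseline_p) / spec.n_per_arm))


def power_for_difference(difference: float, spec: PowerSpec) -> float:
    """Power to detect ``difference`` under the same normal approximation."""
    se = math.sqrt(2.0 * spec.baseline_p * (1.0 - spec.baseline_p) / spec.n_per_arm)
    return float(norm.cdf(difference / se - norm.ppf(1.0 - spec.alpha / 2.0)))


# ---------------------------------------------------------------------------
# Report assembly


def format_p_value(p: float) -> str:
    """Three significant figures with a '<0.001' display floor."""
    if p < 0.001:
        return "<0.001"
    return f"{p:.3g}"


def analyze_table(table: ArmOutcomeTable, reference_arm: str = "text") -> dict:
    """Full outcome analysis of an arm table, mirroring the published layout."""
    treat_ors = arm_odds_ratios(table, "management", "treat", reference_arm)
    correct_ors = arm_odds_ratios(table, "correctness", "correct", reference_arm)
    het = chi_squared(correct_vs_not_table(table))
    count, total, pct = proportion_correct(table)
    per_arm = {a: proportion_correct(table, a) for a in ARMS}
    irls_fit = fit_outcome_by_arm(table, "correctness", "correct", reference_arm)

    def or_block(res: OddsRatioResult) -> dict:
        o, lo, hi = res.rounded(2)
        return {
            "odds_ratio": o, "ci_low": lo, "ci_high": hi,
            "continuity_corrected": res.continuity_corrected,
        }

    return {
        "counts": table.to_dict(),
        "treat_odds_ratios": {a: or_block(r) for a, r in treat_ors.items()},
        "correct_odds_ratios": {a: or_block(r) for a, r in correct_ors.items()},
        "heterogeneity": {
            "statistic": round(het.statistic, 2),
            "df": het.df,
            "p_value": het.p_value,
            "p_display": format_p_value(het.p_value),
        },
        "proportion_correct": {
            "overall": {"count": count, "total": total, "percent": pct},
            "per_arm": {
                a: {"count": c, "total": t, "percent": p} for a, (c, t, p) in per_arm.items()
            },
        },
        "logistic_fit": {
            "terms": list(irls_fit.term_names),
            "odds_ratios": [round(float(v), 6) for v in irls_fit.odds_ratios()],
            "converged": irls_fit.converged,
            "iterations": irls_fit.iterations,
        },
        "reference_arm": reference_arm,
    }
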