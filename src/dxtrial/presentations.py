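"""The four presentation formats for diagnostic-test accuracy.

Each format is built as a plain data structure (JSON-exportable) by a
``build_*``/``render_text_summary`` function and can be turned into a
standalone SVG document by :func:`render_svg`. All four encode the same
odds-form Bayesian update, so their readings must agree with
:mod:`dxtrial.bayes_core` — a property the test suite enforces.

Formats:

* text summary — sentence with sensitivity, specificity, LR+, LR- and a
  rule-in/rule-out qualifier;
* Fagan-style nomogram — three parallel base-10 log-odds axes on which the
  update is a straight line;
* probability-modifying plot — post-test vs pre-test probability curves,
  one per test result;
* natural frequency tree — integer branching of a hypothetical cohort by
  disease status then test result.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .bayes_core import (
    TestAccuracy,
    as_proportion,
    likelihood_ratios,
    odds,
    posttest_probability,
    probability_from_odds,
)

__all__ = [
    "FrequencyTree",
    "NomogramGeometry",
    "PMPCurves",
    "TextSummary",
    "apportion",
    "build_frequency_tree",
    "tree_posterior",
    "build_nomogram",
    "build_pmp",
    "render_text_summary",
    "render_svg",
    "format_ratio",
    "DEFAULT_STYLE",
    "load_style",
    "PROBABILITY_TICKS",
    "LR_TICKS",
]


# ---------------------------------------------------------------------------
# Natural frequency tree


@dataclass(frozen=True)
class FrequencyTree:
    """Integer counts of a cohort split by disease status then test result."""

    total: int
    diseased: int
    nondiseased: int
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        counts = (self.total, self.diseased, self.nondiseased,
                  self.tp, self.fn, self.fp, self.tn)
        if any(not isinstance(c, (int, np.integer)) or c < 0 for c in counts):
            raise ValueError("all tree counts must be non-negative integers")
        if self.diseased + self.nondiseased != self.total:
            raise ValueError("diseased + nondiseased must equal total")
        if self.tp + self.fn != self.diseased:
            raise ValueError("tp + fn must equal diseased")
        if self.fp + self.tn != self.nondiseased:
            raise ValueError("fp + tn must equal nondiseased")

    def to_dict(self) -> dict:
        return {
            "total": self.total, "diseased": self.diseased,
            "nondiseased": self.nondiseased, "tp": self.tp,
            "fn": self.fn, "fp": self.fp, "tn": self.tn,
        }


def apportion(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder integer apportionment of ``total`` over ``weights``.

    Floors the exact quotas, then hands the remaining units to the cells
    with the largest fractional parts (ties broken by position). The result
    sums to ``total`` exactly and minimises the L1 distance to the quotas.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    w = [float(x) for x in weights]
    if any(x < 0 for x in w):
        raise ValueError("weights must be non-negative")
    s = sum(w)
    if s <= 0:
        raise ValueError("weights must not all be zero")
    quotas = [total * x / s for x in w]
    base = [math.floor(q) for q in quotas]
    short = total - sum(base)
    order = sorted(range(len(w)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def build_frequency_tree(
    n: int, pretest: float, acc: TestAccuracy, unit: str = "proportion"
) -> FrequencyTree:
    """Build the natural frequency tree for ``n`` patients.

    Expected cell counts (``n * pretest * sensitivity`` etc.) are rounded
    with largest-remainder apportionment at each split, so every branch sum
    holds exactly for any ``n``, divisible or not.
    """
    if n < 1:
        raise ValueError("cohort size n must be at least 1")
    p = as_proportion(pretest, unit)  # type: ignore[arg-type]
    diseased, nondiseased = apportion(n, [p, 1.0 - p])
    tp, fn = apportion(diseased, [acc.sensitivity, 1.0 - acc.sensitivity])
    fp, tn = apportion(nondiseased, [1.0 - acc.specificity, acc.specificity])
    return FrequencyTree(total=n, diseased=diseased, nondiseased=nondiseased,
                         tp=tp, fn=fn, fp=fp, tn=tn)


def tree_posterior(tree: FrequencyTree, result: Literal["positive", "negative"]) -> float:
    """Disease probability among patients with the given test result."""
    if result == "positive":
        margin = tree.tp + tree.fp
        if margin == 0:
            raise ValueError("no such test results in tree: no positives")
        return tree.tp / margin
    if result == "negative":
        margin = tree.fn + tree.tn
        if margin == 0:
            raise ValueError("no such test results in tree: no negatives")
        return tree.fn / margin
    raise ValueError(f"result must be 'positive' or 'negative', got {result!r}")


# ---------------------------------------------------------------------------
# Nomogram

# Classic axis tick sets; the published figure's exact ranges are not stated,
# so these declared defaults cover pre-test 0.1%-99% and LR 0.001-1000.
PROBABILITY_TICKS: tuple[float, ...] = (
    0.001, 0.002, 0.003, 0.005, 0.007, 0.01, 0.02, 0.03, 0.05, 0.07,
    0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.93, 0.95, 0.97, 0.98, 0.99,
)
LR_TICKS: tuple[float, ...] = (
    0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5,
    1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0,
)


@dataclass(frozen=True)
class NomogramGeometry:
    """Three parallel log-odds axes plus the straight update line.

    Axes sit at x = 0, 1/2, 1. Ordinates: left = -log10(odds(p)),
    middle = log10(LR)/2, right = +log10(odds(p)). With this (unique
    affine) scaling the Bayesian update
    log-odds(post) = log-odds(pre) + log10(LR) is exactly the straight
    line through the three marked points.
    """

    left_axis: tuple[tuple[float, float], ...]
    middle_axis: tuple[tuple[float, float], ...]
    right_axis: tuple[tuple[float, float], ...]
    line: tuple[float, float, float]
    pretest: float
    lr: float
    posttest: float

    def to_dict(self) -> dict:
        return {
            "left_axis": [list(t) for t in self.left_axis],
            "middle_axis": [list(t) for t in self.middle_axis],
            "right_axis": [list(t) for t in self.right_axis],
            "line": list(self.line),
            "pretest": self.pretest, "lr": self.lr, "posttest": self.posttest,
        }


def build_nomogram(
    pretest: float,
    acc: TestAccuracy,
    result: Literal["positive", "negative"] = "positive",
    unit: str = "proportion",
) -> NomogramGeometry:
    """Nomogram geometry with the update line for the given test result."""
    p = as_proportion(pretest, unit)  # type: ignore[arg-type]
    if not (0.0 < p < 1.0):
        raise ValueError("pretest probability must lie strictly in (0, 1)")
    lrs = likelihood_ratios(acc)
    lr = lrs.lr_positive if result == "positive" else lrs.lr_negative
    if lr <= 0 or math.isinf(lr):
        raise ValueError("nomogram line requires a finite positive likelihood ratio")
    left_ord = -math.log10(odds(p))
    mid_ord = math.log10(lr) / 2.0
    post = posttest_probability(p, lr).posttest
    right_ord = math.log10(odds(post))
    return NomogramGeometry(
        left_axis=tuple((t, -math.log10(odds(t))) for t in PROBABILITY_TICKS),
        middle_axis=tuple((t, math.log10(t) / 2.0) for t in LR_TICKS),
        right_axis=tuple((t, math.log10(odds(t))) for t in PROBABILITY_TICKS),
        line=(left_ord, mid_ord, right_ord),
        pretest=p, lr=lr, posttest=post,
    )


# ---------------------------------------------------------------------------
# Probability-modifying plot


@dataclass(frozen=True)
class PMPCurves:
    """Post-test probability versus pre-test probability, one curve per result."""

    pretest_grid: tuple[float, ...]
    post_positive: tuple[float, ...]
    post_negative: tuple[float, ...]

    def read(self, pretest: float, result: Literal["positive", "negative"]) -> float:
        """Read the curve at the grid point nearest ``pretest``."""
        grid = np.asarray(self.pretest_grid)
        i = int(np.argmin(np.abs(grid - pretest)))
        curve = self.post_positive if result == "positive" else self.post_negative
        return curve[i]

    def to_dict(self) -> dict:
        return {
            "pretest_grid": list(self.pretest_grid),
            "post_positive": list(self.post_positive),
            "post_negative": list(self.post_negative),
        }


def build_pmp(acc: TestAccuracy, grid_step: float = 0.001) -> PMPCurves:
    """Tabulate both post-test curves on a regular pre-test grid.

    Default step 0.001 keeps reading error well below the 1% answer margin.
    """
    if not (0.0 < grid_step <= 0.01):
        raise ValueError("grid_step must lie in (0, 0.01]")
    lrs = likelihood_ratios(acc)
    m = int(round(1.0 / grid_step))
    grid = np.arange(1, m) * grid_step
    grid = grid[(grid > 0.0) & (grid < 1.0)]
    pre_odds = grid / (1.0 - grid)

    def curve(lr: float) -> np.ndarray:
        if math.isinf(lr):
            return np.ones_like(grid)
        po = pre_odds * lr
        return po / (1.0 + po)

    return PMPCurves(
        pretest_grid=tuple(float(x) for x in grid),
        post_positive=tuple(float(x) for x in curve(lrs.lr_positive)),
        post_negative=tuple(float(x) for x in curve(lrs.lr_negative)),
    )


# ---------------------------------------------------------------------------
# Text summary


@dataclass(frozen=True)
class TextSummary:
    """Sentence-format summary of a test's accuracy."""

    text: str
    sensitivity: float
    specificity: float
    lr_positive: float
    lr_negative: float
    direction: Literal["rule_in", "rule_out", "similar"]

    def to_dict(self) -> dict:
        return {
            "text": self.text,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "lr_positive": self.lr_positive, "lr_negative": self.lr_negative,
            "direction": self.direction,
        }


def format_ratio(x: float) -> str:
    """Display a likelihood ratio: two decimals, trailing zeros stripped."""
    if math.isinf(x):
        return "infinite"
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _format_percent(p: float) -> str:
    return f"{round(100.0 * p, 6):g}%"


def render_text_summary(acc: TestAccuracy, condition: str = "the condition") -> TextSummary:
    """Render the sentence-format summary for a test.

    The rule-in/rule-out qualifier compares the log-scale strength of the
    two likelihood ratios: rule-in when |log LR+| > |log LR-|, rule-out
    when smaller, "similar potential" on a tie.
    """
    lrs = likelihood_ratios(acc)
    strength_in = math.inf if lrs.lr_positive_infinite else (
        abs(math.log(lrs.lr_positive)) if lrs.lr_positive > 0 else math.inf
    )
    strength_out = abs(math.log(lrs.lr_negative)) if lrs.lr_negative > 0 else math.inf
    if math.isclose(strength_in, strength_out, rel_tol=0.0, abs_tol=1e-12) or (
        math.isinf(strength_in) and math.isinf(strength_out)
    ):
        direction: Literal["rule_in", "rule_out", "similar"] = "similar"
        phrase = f"similar potential to rule in or rule out {condition}"
    elif strength_in > strength_out:
        direction = "rule_in"
        phrase = f"greater potential to rule in {condition} rather than to rule out {condition}"
    else:
        direction = "rule_out"
        phrase = f"greater potential to rule out {condition} rather than to rule in {condition}"
    text = (
        f"The test has a sensitivity of {_format_percent(acc.sensitivity)} "
        f"and a specificity of {_format_percent(acc.specificity)}. "
        f"It has a positive likelihood ratio of {format_ratio(lrs.lr_positive)} "
        f"and a negative likelihood ratio of {format_ratio(lrs.lr_negative)} "
        f"suggesting that it has {phrase}."
    )
    return TextSummary(
        text=text,
        sensitivity=acc.sensitivity, specificity=acc.specificity,
        lr_positive=lrs.lr_positive, lr_negative=lrs.lr_negative,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# SVG rendering

DEFAULT_STYLE: dict = {
    "width": 520,
    "height": 420,
    "margin": 48,
    "font_family": "Helvetica, Arial, sans-serif",
    "font_size": 11,
    "axis_color": "#333333",
    "line_color": "#b03a2e",
    "curve_positive_color": "#1f618d",
    "curve_negative_color": "#148f77",
    "node_fill": "#f4f6f7",
    "text_color": "#1b2631",
}


def load_style(path: str) -> dict:
    """Load a style config JSON and merge it over the defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        user = json.load(fh)
    unknown = set(user) - set(DEFAULT_STYLE)
    if unknown:
        raise ValueError(f"unknown style keys: {sorted(unknown)}")
    style = dict(DEFAULT_STYLE)
    style.update(user)
    return style


def _f(x: float) -> str:
    return f"{x:.2f}"


def _svg_header(style: dict) -> str:
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{style["width"]}" height="{style["height"]}" '
        f'viewBox="0 0 {style["width"]} {style["height"]}" '
        f'font-family="{style["font_family"]}" font-size="{style["font_size"]}">\n'
    )


def _text(x: float, y: float, s: str, style: dict, anchor: str = "start") -> str:
    return (
        f'<text x="{_f(x)}" y="{_f(y)}" text-anchor="{anchor}" '
        f'fill="{style["text_color"]}">{s}</text>\n'
    )


def _render_text_svg(payload: TextSummary, style: dict) -> str:
    # naive word wrap at ~55 characters per line
    words = payload.text.split()
    lines: list[list[str]] = [[]]
    for w in words:
        if sum(len(x) + 1 for x in lines[-1]) + len(w) > 55 and lines[-1]:
            lines.append([])
        lines[-1].append(w)
    parts = [_svg_header(style)]
    y = style["margin"]
    for line in lines:
        parts.append(_text(style["margin"], y, " ".join(line), style))
        y += style["font_size"] * 1.6
    parts.append("</svg>\n")
    return "".join(parts)


def _nomogram_scales(style: dict):
    w, h, m = style["width"], style["height"], style["margin"]
    xs = {0.0: m, 0.5: w / 2.0, 1.0: w - m}
    ord_min, ord_max = -3.0, 3.0

    def y(o: float) -> float:
        # larger ordinate (higher post-test probability) towards the top
        return m + (ord_max - o) / (ord_max - ord_min) * (h - 2 * m)

    return xs, y


def _render_nomogram_svg(payload: NomogramGeometry, style: dict) -> str:
    xs, y = _nomogram_scales(style)
    parts = [_svg_header(style)]
    axes = (
        (0.0, payload.left_axis, "end", "pre-test probability"),
        (0.5, payload.middle_axis, "end", "likelihood ratio"),
        (1.0, payload.right_axis, "start", "post-test probability"),
    )
    for xfrac, ticks, anchor, title in axes:
        x = xs[xfrac]
        ords = [o for _, o in ticks]
        parts.append(
            f'<line x1="{_f(x)}" y1="{_f(y(max(ords)))}" x2="{_f(x)}" '
            f'y2="{_f(y(min(ords)))}" stroke="{style["axis_color"]}" stroke-width="1"/>\n'
        )
        dx = -5 if anchor == "end" else 5
        for value, o in ticks:
            parts.append(
                f'<line x1="{_f(x - 3)}" y1="{_f(y(o))}" x2="{_f(x + 3)}" '
                f'y2="{_f(y(o))}" stroke="{style["axis_color"]}" stroke-width="1"/>\n'
            )
            label = _format_percent(value) if xfrac != 0.5 else f"{value:g}"
            parts.append(_text(x + dx, y(o) + 3, label, style, anchor=anchor))
        parts.append(_text(x, style["margin"] / 2.0 + 6, title, style, anchor="middle"))
    lo, mo, ro = payload.line
    parts.append(
        f'<line id="update-line" x1="{_f(xs[0.0])}" y1="{_f(y(lo))}" '
        f'x2="{_f(xs[1.0])}" y2="{_f(y(ro))}" '
        f'stroke="{style["line_color"]}" stroke-width="1.5"/>\n'
    )
    parts.append(
        f'<circle cx="{_f(xs[0.5])}" cy="{_f(y(mo))}" r="2.5" '
        f'fill="{style["line_color"]}"/>\n'
    )
    parts.append("</svg>\n")
    return "".join(parts)


def _render_pmp_svg(payload: PMPCurves, style: dict) -> str:
    w, h, m = style["width"], style["height"], style["margin"]

    def px(p: float) -> float:
        return m + p * (w - 2 * m)

    def py(p: float) -> float:
        return h - m - p * (h - 2 * m)

    parts = [_svg_header(style)]
    parts.append(
        f'<rect x="{_f(m)}" y="{_f(m)}" width="{_f(w - 2 * m)}" height="{_f(h - 2 * m)}" '
        f'fill="none" stroke="{style["axis_color"]}" stroke-width="1"/>\n'
    )
    for frac in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
        parts.append(_text(px(frac), h - m + 16, f"{frac * 100:g}", style, anchor="middle"))
        parts.append(_text(m - 8, py(frac) + 3, f"{frac * 100:g}", style, anchor="end"))
    for name, curve, color in (
        ("positive", payload.post_positive, style["curve_positive_color"]),
        ("negative", payload.post_negative, style["curve_negative_color"]),
    ):
        pts = " ".join(
            f"{_f(px(x))},{_f(py(yv))}" for x, yv in zip(payload.pretest_grid, curve)
        )
        parts.append(
            f'<polyline id="curve-{name}" points="{pts}" fill="none" '
            f'stroke="{color}" stroke-width="1.5"/>\n'
        )
    parts.append(_text(w / 2.0, h - m / 4.0, "pre-test probability (%)", style, anchor="middle"))
    parts.append(_text(m, m / 2.0, "post-test probability (%)", style))
    parts.append("</svg>\n")
    return "".join(parts)


def _render_tree_svg(payload: FrequencyTree, style: dict) -> str:
    w, h, m = style["width"], style["height"], style["margin"]
    col = {0: m + 40, 1: w / 2.0, 2: w - m - 40}
    nodes = {
        "total": (col[0], h / 2.0, f"{payload.total} patients"),
        "diseased": (col[1], h / 4.0, f"{payload.diseased} diseased"),
        "nondiseased": (col[1], 3 * h / 4.0, f"{payload.nondiseased} not diseased"),
        "tp": (col[2], h / 8.0, f"{payload.tp} test positive"),
        "fn": (col[2], 3 * h / 8.0, f"{payload.fn} test negative"),
        "fp": (col[2], 5 * h / 8.0, f"{payload.fp} test positive"),
        "tn": (col[2], 7 * h / 8.0, f"{payload.tn} test negative"),
    }
    edges = (
        ("total", "diseased"), ("total", "nondiseased"),
        ("diseased", "tp"), ("diseased", "fn"),
        ("nondiseased", "fp"), ("nondiseased", "tn"),
    )
    parts = [_svg_header(style)]
    for a, b in edges:
        xa, ya, _ = nodes[a]
        xb, yb, _ = nodes[b]
        parts.append(
            f'<line x1="{_f(xa)}" y1="{_f(ya)}" x2="{_f(xb)}" y2="{_f(yb)}" '
            f'stroke="{style["axis_color"]}" stroke-width="1"/>\n'
        )
    for name, (x, yv, label) in nodes.items():
        parts.append(
            f'<rect id="node-{name}" x="{_f(x - 52)}" y="{_f(yv - 12)}" width="104" '
            f'height="24" rx="4" fill="{style["node_fill"]}" '
            f'stroke="{style["axis_color"]}" stroke-width="1"/>\n'
        )
        parts.append(_text(x, yv + 4, label, style, anchor="middle"))
    parts.append("</svg>\n")
    return "".join(parts)


_RENDERERS = {
    "text": (TextSummary, _render_text_svg),
    "nomogram": (NomogramGeometry, _render_nomogram_svg),
    "pmp": (PMPCurves, _render_pmp_svg),
    "tree": (FrequencyTree, _render_tree_svg),
}


def render_svg(format: str, payload, style: dict | None = None) -> str:
    """Render a built presentation payload to a standalone SVG document.

    Output is deterministic: a fixed (payload, style) pair always yields
    byte-identical SVG.
    """
    if format not in _RENDERERS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_RENDERERS)}")
    expected_type, renderer = _RENDERERS[format]
    if not isinstance(payload, expected_type):
        raise TypeError(
            f"payload for format {format!r} must be {expected_type.__name__}, "
            f"got {type(payload).__name__}"
        )
    return renderer(payload, dict(DEFAULT_STYLE if style is None else style))
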