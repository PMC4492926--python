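import itertools
import math
import xml.etree.ElementTree as ET

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dxtrial.bayes_core import TestAccuracy, likelihood_ratios, posttest_probability
from dxtrial.presentations import (
    DEFAULT_STYLE,
    FrequencyTree,
    apportion,
    build_frequency_tree,
    build_nomogram,
    build_pmp,
    format_ratio,
    load_style,
    render_svg,
    render_text_summary,
    tree_posterior,
)

SVG_NS = "{http://www.w3.org/2000/svg}"


class TestApportion:
    def test_exact_divisible(self):
        assert apportion(1000, [0.5, 0.5]) == [500, 500]
        assert apportion(500, [0.6, 0.4]) == [300, 200]

    def test_brute_force_l1_optimal(self):
        # for a 2-way split, compare against all feasible integer allocations
        for n in range(1, 30):
            for w in (0.6, 0.9, 0.5, 0.123, 0.777):
                got = apportion(n, [w, 1.0 - w])
                quotas = [n * w, n * (1 - w)]
                best = min(
                    ([k, n - k] for k in range(n + 1)),
                    key=lambda a: sum(abs(x - q) for x, q in zip(a, quotas)),
                )
                assert sum(got) == n
                assert sum(abs(x - q) for x, q in zip(got, quotas)) == pytest.approx(
                    sum(abs(x - q) for x, q in zip(best, quotas))
                )

    @given(
        n=st.integers(0, 10_000),
        weights=st.lists(st.floats(0.001, 10.0), min_size=1, max_size=6),
    )
    def test_sums_preserved(self, n, weights):
        parts = apportion(n, weights)
        assert sum(parts) == n
        assert all(p >= 0 for p in parts)

    def test_invalid(self):
        with pytest.raises(ValueError):
            apportion(5, [0.0, 0.0])
        with pytest.raises(ValueError):
            apportion(-1, [1.0])


class TestFrequencyTree:
    def test_vignette_tree(self, vignette_acc):
        tree = build_frequency_tree(1000, 0.5, vignette_acc)
        assert tree == FrequencyTree(total=1000, diseased=500, nondiseased=500,
                                     tp=300, fn=200, fp=50, tn=450)

    def test_perfect_test(self):
        tree = build_frequency_tree(10, 0.5, TestAccuracy(1.0, 1.0))
        assert (tree.tp, tree.fn, tree.fp, tree.tn) == (5, 0, 0, 5)

    def test_non_divisible_conservation(self, vignette_acc):
        tree = build_frequency_tree(7, 0.5, vignette_acc)
        assert tree.diseased + tree.nondiseased == 7
        assert tree.tp + tree.fn == tree.diseased
        assert tree.fp + tree.tn == tree.nondiseased

    @given(n=st.integers(1, 5000), p=st.floats(0.01, 0.99),
           sens=st.floats(0.0, 1.0), spec=st.floats(0.0, 1.0))
    def test_conservation_property(self, n, p, sens, spec):
        tree = build_frequency_tree(n, p, TestAccuracy(sens, spec))
        assert tree.total == n
        assert tree.diseased + tree.nondiseased == n
        assert tree.tp + tree.fn == tree.diseased
        assert tree.fp + tree.tn == tree.nondiseased

    def test_zero_n_rejected(self, vignette_acc):
        with pytest.raises(ValueError):
            build_frequency_tree(0, 0.5, vignette_acc)

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            FrequencyTree(total=10, diseased=6, nondiseased=5, tp=3, fn=3, fp=2, tn=3)


class TestTreePosterior:
    def test_positive(self, vignette_acc):
        tree = build_frequency_tree(1000, 0.5, vignette_acc)
        assert tree_posterior(tree, "positive") == pytest.approx(300 / 350)

    def test_negative(self, vignette_acc):
        tree = build_frequency_tree(1000, 0.5, vignette_acc)
        assert tree_posterior(tree, "negative") == pytest.approx(200 / 650)

    def test_perfect(self):
        tree = build_frequency_tree(10, 0.5, TestAccuracy(1.0, 1.0))
        assert tree_posterior(tree, "positive") == 1.0

    def test_empty_margin(self):
        tree = build_frequency_tree(10, 0.5, TestAccuracy(1.0, 1.0))
        # perfect test on an all-diseased... build a tree with no negatives
        t = FrequencyTree(total=2, diseased=1, nondiseased=1, tp=1, fn=0, fp=1, tn=0)
        with pytest.raises(ValueError, match="no such test results"):
            tree_posterior(t, "negative")


class TestNomogram:
    def test_vignette_line(self, vignette_acc):
        geom = build_nomogram(0.5, vignette_acc)
        lo, mo, ro = geom.line
        assert lo == pytest.approx(0.0, abs=1e-12)
        assert mo == pytest.approx(math.log10(6) / 2, rel=1e-9)
        assert ro == pytest.approx(math.log10(6), rel=1e-9)

    def test_right_axis_reading_gives_86(self, vignette_acc):
        geom = build_nomogram(0.5, vignette_acc)
        post_odds = 10 ** geom.line[2]
        assert round(100 * post_odds / (1 + post_odds)) == 86

    def test_lr_one_horizontal(self):
        geom = build_nomogram(0.5, TestAccuracy(0.5, 0.5))
        assert geom.line == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_tick_coverage(self, vignette_acc):
        geom = build_nomogram(0.5, vignette_acc)
        probs = [t for t, _ in geom.left_axis]
        lrs = [t for t, _ in geom.middle_axis]
        assert min(probs) <= 0.001 and max(probs) >= 0.99
        assert min(lrs) <= 0.001 and max(lrs) >= 1000

    def test_collinearity_random(self):
        # 1000 random (pretest, lr) pairs, lr realised through both the
        # positive and negative likelihood ratios of random accuracies
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(0.01, 0.99)
            sens = rng.uniform(0.05, 0.95)
            spec = rng.uniform(0.05, 0.95)
            result = "positive" if rng.random() < 0.5 else "negative"
            geom = build_nomogram(p, TestAccuracy(sens, spec), result=result)
            (x0, y0), (x1, y1), (x2, y2) = zip((0, 0.5, 1.0), geom.line)
            cross = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
            assert abs(cross) < 1e-9

    def test_out_of_range_pretest(self, vignette_acc):
        with pytest.raises(ValueError):
            build_nomogram(1.0, vignette_acc)


class TestPMP:
    def test_vignette_reading(self, vignette_acc):
        curves = build_pmp(vignette_acc)
        assert curves.read(0.5, "positive") == pytest.approx(6 / 7, abs=1e-9)
        # at plot resolution the reading is 85-86%
        assert 85 <= round(100 * curves.read(0.5, "positive")) <= 86

    def test_lr_one_diagonal(self):
        curves = build_pmp(TestAccuracy(0.5, 0.5))
        np.testing.assert_allclose(curves.post_positive, curves.pretest_grid, atol=1e-12)
        np.testing.assert_allclose(curves.post_negative, curves.pretest_grid, atol=1e-12)

    def test_derived_point(self, vignette_acc):
        curves = build_pmp(vignette_acc)
        assert curves.read(0.2, "positive") == pytest.approx(0.60, abs=1e-9)

    def test_ordering_and_monotone(self, vignette_acc):
        curves = build_pmp(vignette_acc)
        pos = np.asarray(curves.post_positive)
        neg = np.asarray(curves.post_negative)
        grid = np.asarray(curves.pretest_grid)
        assert np.all(pos >= grid) and np.all(grid >= neg)
        assert np.all(np.diff(pos) > 0) and np.all(np.diff(neg) > 0)

    def test_grid_step_validation(self, vignette_acc):
        with pytest.raises(ValueError):
            build_pmp(vignette_acc, grid_step=0.05)


class TestTextSummary:
    def test_vignette_text(self, vignette_acc):
        s = render_text_summary(vignette_acc)
        assert "sensitivity of 60%" in s.text
        assert "specificity of 90%" in s.text
        assert "positive likelihood ratio of 6" in s.text
        assert "0.44" in s.text
        assert s.direction == "rule_in"

    def test_quiz_rule_out(self, quiz_acc):
        s = render_text_summary(quiz_acc)
        assert s.direction == "rule_out"
        assert "rule out" in s.text

    def test_tie(self):
        s = render_text_summary(TestAccuracy(0.5, 0.5))
        assert s.direction == "similar"
        assert "similar potential" in s.text

    def test_numbers_match_display_precision(self, vignette_acc):
        lrs = likelihood_ratios(vignette_acc)
        s = render_text_summary(vignette_acc)
        assert format_ratio(lrs.lr_positive) in s.text
        assert format_ratio(lrs.lr_negative) in s.text


class TestFormatRatio:
    @pytest.mark.parametrize("x,expected", [
        (6.0, "6"), (6.000000000000001, "6"), (0.4444444, "0.44"),
        (1.8, "1.8"), (0.2, "0.2"), (math.inf, "infinite"),
    ])
    def test_cases(self, x, expected):
        assert format_ratio(x) == expected


class TestSvgRendering:
    def test_tree_contains_counts(self, vignette_acc):
        tree = build_frequency_tree(1000, 0.5, vignette_acc)
        svg = render_svg("tree", tree)
        for count in ("500", "300", "200", "50", "450", "1000"):
            assert count in svg

    @pytest.mark.parametrize("fmt,builder", [
        ("tree", lambda acc: build_frequency_tree(1000, 0.5, acc)),
        ("nomogram", lambda acc: build_nomogram(0.5, acc)),
        ("pmp", lambda acc: build_pmp(acc, 0.01)),
        ("text", render_text_summary),
    ])
    def test_deterministic_and_valid_xml(self, fmt, builder, vignette_acc):
        payload = builder(vignette_acc)
        a = render_svg(fmt, payload)
        b = render_svg(fmt, payload)
        assert a == b
        root = ET.fromstring(a)
        assert root.tag == f"{SVG_NS}svg"

    def test_nomogram_line_parse_back(self, vignette_acc):
        geom = build_nomogram(0.5, vignette_acc)
        svg = render_svg("nomogram", geom)
        root = ET.fromstring(svg)
        line = next(e for e in root.iter(f"{SVG_NS}line") if e.get("id") == "update-line")
        w, h, m = DEFAULT_STYLE["width"], DEFAULT_STYLE["height"], DEFAULT_STYLE["margin"]

        def expected_y(o):
            return m + (3.0 - o) / 6.0 * (h - 2 * m)

        assert float(line.get("x1")) == pytest.approx(m, abs=0.1)
        assert float(line.get("x2")) == pytest.approx(w - m, abs=0.1)
        assert float(line.get("y1")) == pytest.approx(expected_y(geom.line[0]), abs=0.1)
        assert float(line.get("y2")) == pytest.approx(expected_y(geom.line[2]), abs=0.1)

    def test_mismatched_payload_rejected(self, vignette_acc):
        with pytest.raises(TypeError):
            render_svg("tree", build_nomogram(0.5, vignette_acc))
        with pytest.raises(ValueError):
            render_svg("scatter", build_pmp(vignette_acc, 0.01))

    def test_style_config(self, tmp_path, vignette_acc):
        style_file = tmp_path / "style.json"
        style_file.write_text('{"line_color": "#000000"}')
        style = load_style(str(style_file))
        assert style["line_color"] == "#000000"
        assert style["width"] == DEFAULT_STYLE["width"]
        svg = render_svg("nomogram", build_nomogram(0.5, vignette_acc), style)
        assert "#000000" in svg

    def test_unknown_style_key_rejected(self, tmp_path):
        style_file = tmp_path / "style.json"
        style_file.write_text('{"comic_sans": true}')
        with pytest.raises(ValueError, match="unknown style"):
            load_style(str(style_file))


class TestCrossFormatAgreement:
    def test_agreement_on_grid(self):
        # tree (10^6 cohort), nomogram right axis, PMP curve, and odds-form
        # Bayes must all tell the same story
        for p10, s10, t10 in itertools.product((2, 5, 8), (3, 6, 9), (5, 7, 9)):
            p, acc = p10 / 10, TestAccuracy(s10 / 10, t10 / 10)
            lrs = likelihood_ratios(acc)
            direct = posttest_probability(p, lrs.lr_positive).posttest
            tree = build_frequency_tree(10**6, p, acc)
            assert tree_posterior(tree, "positive") == pytest.approx(direct, abs=1e-6)
            geom = build_nomogram(p, acc)
            post_odds = 10 ** geom.line[2]
            assert post_odds / (1 + post_odds) == pytest.approx(direct, abs=1e-9)
            curves = build_pmp(acc)
            assert curves.read(p, "positive") == pytest.approx(direct, abs=1e-6)
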