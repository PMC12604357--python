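"""Score mapping, direction-reversing transforms, max-min normalisation and
the composite per-indicator objective."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import welfareopt as w

from conftest import make_db, small_view


class TestAggregation:
    def test_impact_mean_of_constant_high(self):
        rows = [
            ("sp", "cl", "h1", "c1", "i", "High", "Easy", "Easy"),
            ("sp", "cl", "h1", "c2", "i", "High", "Easy", "Easy"),
        ]
        assert w.aggregate_impact(make_db(rows).view("sp"), "i") == 2.0

    def test_impact_mean_of_mixed(self):
        rows = [
            ("sp", "cl", "h1", "c1", "i", "Low", "Easy", "Easy"),
            ("sp", "cl", "h1", "c2", "i", "High", "Easy", "Easy"),
        ]
        assert w.aggregate_impact(make_db(rows).view("sp"), "i") == 1.5

    def test_impact_over_distinct_consequences_not_rows(self):
        # the same consequence linked through two hazards counts once
        rows = [
            ("sp", "cl", "h1", "c1", "i", "High", "Easy", "Easy"),
            ("sp", "cl", "h2", "c1", "i", "High", "Easy", "Easy"),
            ("sp", "cl", "h2", "c2", "i", "Low", "Easy", "Easy"),
        ]
        assert w.aggregate_impact(make_db(rows).view("sp"), "i") == 1.5

    def test_mitigation_single_easy_hazard(self):
        rows = [("sp", "cl", "h1", "c1", "i", "High", "Easy", "Easy")]
        assert w.aggregate_mitigation(make_db(rows).view("sp"), "i") == 3.0

    def test_mitigation_mean_easy_difficult(self):
        rows = [
            ("sp", "cl", "h1", "c1", "i", "High", "Easy", "Easy"),
            ("sp", "cl", "h2", "c1", "i", "High", "Difficult", "Easy"),
        ]
        assert w.aggregate_mitigation(make_db(rows).view("sp"), "i") == 2.0

    @pytest.mark.parametrize("ease, expected", [("Easy", 3.0), ("Moderate", 2.0),
                                                ("Difficult", 1.0)])
    def test_easiness_transform(self, ease, expected):
        rows = [("sp", "cl", "h1", "c1", "i", "High", "Easy", ease)]
        assert w.easiness_score(make_db(rows).view("sp"), "i") == expected

    def test_unknown_indicator_raises(self, pig_view):
        with pytest.raises(w.UnknownEntityError):
            w.aggregate_impact(pig_view, "nope")


class TestMinMax:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ({"a": 1.0, "b": 2.0, "c": 3.0}, {"a": 0.0, "b": 0.5, "c": 1.0}),
            ({"a": 2.0, "b": 2.0, "c": 2.0}, {"a": 0.0, "b": 0.0, "c": 0.0}),
            ({"a": 4.0, "b": 2.0}, {"a": 1.0, "b": 0.0}),
        ],
    )
    def test_known_vectors(self, raw, expected):
        assert w.minmax_normalise(raw).normalised_values == expected

    def test_empty_input_is_error(self):
        with pytest.raises(w.DataValidationError):
            w.minmax_normalise({})

    def test_non_finite_is_error(self):
        with pytest.raises(w.DataValidationError):
            w.minmax_normalise({"a": float("nan"), "b": 1.0})

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    def test_outputs_in_unit_interval_with_attained_endpoints(self, values):
        fv = w.minmax_normalise({str(i): v for i, v in enumerate(values)})
        outs = list(fv.normalised_values.values())
        assert all(0.0 <= v <= 1.0 for v in outs)
        if fv.x_max > fv.x_min:
            assert min(outs) == 0.0 and max(outs) == 1.0

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=20),
        st.floats(0.01, 100.0),
        st.floats(-100.0, 100.0),
    )
    def test_affine_invariance(self, values, a, b):
        """a*x + b (a > 0) normalises identically -- this is why the two
        printed variants of the ease transform offset are equivalent."""
        # coarsen inputs so the affine map cannot absorb a sub-epsilon span
        values = [round(v, 3) for v in values]
        a, b = round(a, 2) or 0.01, round(b, 1)
        raw = {str(i): v for i, v in enumerate(values)}
        shifted = {k: a * v + b for k, v in raw.items()}
        base = w.minmax_normalise(raw).normalised_values
        other = w.minmax_normalise(shifted).normalised_values
        assert all(math.isclose(base[k], other[k], abs_tol=1e-9) for k in raw)

    def test_idempotent_on_normalised_vectors(self):
        fv = w.minmax_normalise({"a": 3.0, "b": 7.0, "c": 5.0})
        again = w.minmax_normalise(fv.normalised_values)
        assert again.normalised_values == fv.normalised_values


class TestObjective:
    def test_all_zero_weights_give_zero_objectives(self, pig_view):
        weights = w.WeightConfig(w_coverage=0, w_easiness=0, w_impact=0, w_mitigation=0)
        assert all(s.objective == 0.0 for s in w.score_indicators(pig_view, weights))

    def test_hazard_coverage_only_hits_unit_endpoint(self):
        rows = [
            ("sp", "cl", h, "c1", "broad", "High", "Easy", "Easy")
            for h in ("h1", "h2", "h3")
        ] + [("sp", "cl", "h1", "c1", "narrow", "High", "Easy", "Easy")]
        view = make_db(rows).view("sp")
        weights = w.WeightConfig(alpha=1, beta=0, w_coverage=1, w_easiness=0,
                                 w_impact=0, w_mitigation=0)
        scores = {s.indicator: s.objective for s in w.score_indicators(view, weights)}
        assert scores["broad"] == 1.0 and scores["narrow"] == 0.0

    def test_matches_independent_recomputation(self):
        """Balanced weights on a 5-indicator synthetic view must match a
        spreadsheet-style re-evaluation done directly from the records."""
        view = small_view(seed=42, n_indicators=5)
        weights = w.WeightConfig(alpha=1, beta=1, w_coverage=2, w_easiness=2,
                                 w_impact=2, w_mitigation=2)

        # independent arithmetic: raw factors straight from the records
        raw = {name: {} for name in ("hc", "cc", "eas", "imp", "mit")}
        for ind in view.indicators:
            recs = [r for r in view.records if r.indicator == ind]
            hazards = {r.hazard for r in recs}
            consequences = {r.consequence for r in recs}
            raw["hc"][ind] = len(hazards)
            raw["cc"][ind] = len(consequences)
            raw["eas"][ind] = 4 - recs[0].ease_of_indicator_use
            imp = {r.consequence: r.impact_of_consequence for r in recs}
            raw["imp"][ind] = sum(imp.values()) / len(consequences)
            mit = {r.hazard: 4 - r.ease_of_mitigation for r in recs}
            raw["mit"][ind] = sum(mit.values()) / len(hazards)

        def norm(d):
            lo, hi = min(d.values()), max(d.values())
            return {k: 0.0 if hi == lo else (v - lo) / (hi - lo) for k, v in d.items()}

        n = {name: norm(vals) for name, vals in raw.items()}
        expected = {
            ind: 2 * (n["hc"][ind] + n["cc"][ind]) + 2 * n["eas"][ind]
            + 2 * n["imp"][ind] + 2 * n["mit"][ind]
            for ind in view.indicators
        }
        actual = {s.indicator: s.objective for s in w.score_indicators(view, weights)}
        assert actual.keys() == expected.keys()
        for ind in expected:
            assert actual[ind] == pytest.approx(expected[ind], abs=1e-12)

    def test_zero_weight_factor_is_irrelevant(self):
        """Permuting the ease-of-use ratings changes nothing when its weight
        is zero."""
        rows = [
            ("sp", "cl", "h1", "c1", "i1", "High", "Easy", "Easy"),
            ("sp", "cl", "h2", "c1", "i2", "High", "Easy", "Moderate"),
            ("sp", "cl", "h1", "c2", "i3", "Low", "Easy", "Difficult"),
        ]
        permuted = [r[:7] + (e,) for r, e in zip(rows, ("Difficult", "Easy", "Moderate"))]
        weights = w.WeightConfig(w_easiness=0.0)
        a = {s.indicator: s.objective
             for s in w.score_indicators(make_db(rows).view("sp"), weights)}
        b = {s.indicator: s.objective
             for s in w.score_indicators(make_db(permuted).view("sp"), weights)}
        assert a == b

    def test_ease_transform_offset_variants_select_identically(self):
        """(L+1)-value vs 5-value: raw scores differ by a constant, so the
        normalised factors and every downstream selection agree."""
        view = small_view(seed=7, n_indicators=10)
        raw_l3 = {i: 4 - view.ease_of_use(i) for i in view.indicators}
        raw_l4 = {i: 5 - view.ease_of_use(i) for i in view.indicators}
        assert (
            w.minmax_normalise(raw_l3).normalised_values
            == w.minmax_normalise(raw_l4).normalised_values
        )

    def test_weight_config_rejects_negative_weight(self):
        with pytest.raises(w.DataValidationError):
            w.WeightConfig(w_coverage=-1.0)

    def test_weight_config_yaml_roundtrip(self, tmp_path):
        import yaml

        cfg = w.WeightConfig(alpha=2.0, w_coverage=5.0, max_indicators=4)
        path = tmp_path / "weights.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert w.WeightConfig.from_yaml(path) == cfg
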