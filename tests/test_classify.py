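import math

import pandas as pd
import pytest

from multistress.classify import (
    classify_database,
    classify_range,
    classify_record,
    degree_of_asymmetry,
    frequency_table,
    select_best_model,
)
from multistress.effects import EffectSize
from multistress.nullmodels import predict_all
from multistress.simulate import SyntheticConfig, generate_database

from conftest import make_record


def _effects(dvals):
    return {
        m: EffectSize(m, d, 0.5, 0.9, 1.0)
        for m, d in dvals.items()
    }


class TestClassifyRange:
    @pytest.mark.parametrize("observed,expected", [
        (16.0, "within"),
        (20.0, "above"),
        (14.0, "below"),
        (18.0, "within"),  # equal to max prediction: closed interval
        (15.0, "within"),  # equal to min prediction
    ])
    def test_positions(self, observed, expected):
        ps = predict_all(make_record(c=10, sa=12, sb=15))  # {15, 17, 18}
        assert classify_range(observed, ps) == expected

    def test_undefined_models_excluded_from_range(self):
        # multiplicative undefined (c=0); defined range is [3, 5]
        ps = predict_all(make_record(c=0, sa=2, sb=3))
        assert classify_range(4.9, ps) == "within"
        assert classify_range(5.1, ps) == "above"


class TestSelectBestModel:
    def test_argmin(self):
        best, _ = select_best_model(
            _effects({"additive": 1.2, "multiplicative": 0.9, "dominance": 0.3})
        )
        assert best == "dominance"

    def test_near_tie_is_undefined(self):
        best, _ = select_best_model(
            _effects({"additive": 0.50, "multiplicative": 0.50 + 1e-12,
                      "dominance": 2.0}),
            tie_tol=1e-6,
        )
        assert best == "undefined"

    def test_coinciding_predictions_give_undefined(self):
        # sa = c: all three nulls coincide, so all |d| are equal.
        rec = make_record(c=10, sa=10, sb=13, xo=12)
        cr = classify_record(rec)
        assert cr.best_model == "undefined"
        ds = list(cr.deviations.values())
        assert max(ds) - min(ds) < 1e-12

    def test_raw_deviation_fallback_on_zero_variance(self):
        rec = make_record(c=10, sa=12, sb=15, xo=15.2, sd=0.0)
        cr = classify_record(rec)
        assert cr.best_model == "dominance"

    def test_rescaling_invariance(self):
        rec = make_record(c=10, sa=12, sb=15, xo=16)
        k = 7.3
        scaled = make_record(c=10 * k, sa=12 * k, sb=15 * k, xo=16 * k, sd=k)
        assert classify_record(rec).best_model == classify_record(scaled).best_model


class TestDegreeOfAsymmetry:
    def test_formula_direct(self):
        res = degree_of_asymmetry(10, 15, 11)
        assert res.pct_effect_temp == pytest.approx(50)
        assert res.pct_effect_b == pytest.approx(10)
        assert res.degree == pytest.approx(40)
        assert not res.asymmetric
        assert res.prevailing == "none"

    def test_asymmetric_with_temperature_prevailing(self):
        res = degree_of_asymmetry(10, 18, 11)
        assert res.degree == pytest.approx(70)
        assert res.asymmetric
        assert res.prevailing == "temperature"

    def test_symmetric_effects(self):
        res = degree_of_asymmetry(10, 14, 14)
        assert res.degree == 0
        assert res.prevailing == "none"

    def test_strong_negative_effect_prevails_over_weak_positive(self):
        res = degree_of_asymmetry(10, 11, 2)  # +10% vs -80%
        assert res.asymmetric
        assert res.prevailing == "stressor_b"

    def test_swap_invariance_of_degree(self):
        a = degree_of_asymmetry(10, 18, 11)
        b = degree_of_asymmetry(10, 11, 18)
        assert a.degree == pytest.approx(b.degree)
        assert b.prevailing == "stressor_b"

    def test_zero_control_undefined(self):
        res = degree_of_asymmetry(0, 1, 2)
        assert not res.defined
        assert math.isnan(res.degree)


class TestFrequencyTable:
    def test_single_level_all_dominance(self):
        df = pd.DataFrame(
            {
                "grp": ["x"] * 4,
                "range_position": ["within"] * 4,
                "best_model": ["dominance"] * 4,
            }
        )
        tab = frequency_table(df, "grp", min_n=1)
        assert tab.loc[0, "pct_best_dominance"] == 100
        assert tab.loc[0, "pct_within"] == 100

    def test_percentages_sum_to_100_and_match_brute_tally(self):
        db, _ = generate_database(SyntheticConfig(seed=9, n_studies=40))
        cls = classify_database(db)
        tab = frequency_table(cls, "organisation_level", min_n=8)
        for _, row in tab.iterrows():
            sub = cls[cls["organisation_level"] == row["level"]]
            assert row["n"] == len(sub) >= 8
            assert row["pct_within"] + row["pct_below"] + row["pct_above"] == (
                pytest.approx(100)
            )
            best_cols = [c for c in tab.columns if c.startswith("pct_best_")]
            # brute-force tally per level
            for c in best_cols:
                model = c.removeprefix("pct_best_")
                expected = (sub["best_model"] == model).mean() * 100
                assert row[c] == pytest.approx(expected)

    def test_small_levels_omitted(self):
        df = pd.DataFrame(
            {
                "grp": ["x"] * 9 + ["y"] * 7,
                "range_position": ["within"] * 16,
                "best_model": ["additive"] * 16,
            }
        )
        tab = frequency_table(df, "grp", min_n=8)
        assert list(tab["level"]) == ["x"]

    def test_unknown_grouping(self):
        with pytest.raises(ValueError):
            frequency_table(pd.DataFrame({"a": []}), "nope")
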