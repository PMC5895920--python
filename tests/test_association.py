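"""Normalized shares, the Pearson/Bonferroni screen, and the placebo envelope."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import adaudit as ad
from adaudit.association import (
    FB_INT,
    FB_POP,
    AnalysisConfig,
    CorrelationRecord,
    InterestPrevalenceScreen,
    correlation_screen,
    format_p,
)
from adaudit.errors import (
    ConfigurationError,
    DegenerateInputError,
    InvalidArgumentError,
    UndefinedShareError,
)
from adaudit.world import generate_world, marker_recovery_config


def pearson_brute_force(xs, ys):
    """Definition-level product-moment coefficient (independent oracle)."""
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


class TestNormalizedShare:
    def test_self_normalization_is_one(self, us_snapshot):
        assert ad.normalized_share(us_snapshot, "Facebook", "US", scheme=FB_INT) == 1.0

    def test_us_facebook_share_of_all_users(self, us_snapshot):
        share = ad.normalized_share(us_snapshot, "Facebook", "US", scheme=FB_POP)
        assert share == pytest.approx(83_000_000 / 194_000_000)
        assert share == pytest.approx(0.4278, abs=5e-5)

    def test_zero_reference_raises_named_cell(self):
        base = ad.AudienceQuery(geography="US")
        snap = ad.AudienceSnapshot(
            [
                ad.AudienceEstimate(query=base, count=0),
                ad.AudienceEstimate(query=base.with_interests(["x"]), count=100),
            ],
            granularity=20,
        )
        with pytest.raises(UndefinedShareError, match="US"):
            ad.normalized_share(snap, "x", "US", scheme=FB_POP)


class TestPearson:
    def test_perfect_linearity(self):
        xs = [1.0, 2.0, 3.0, 4.0]
        assert ad.pearson_correlation(xs, [2 * x + 1 for x in xs]) == pytest.approx(1.0)
        assert ad.pearson_correlation(xs, [-x for x in xs]) == pytest.approx(-1.0)

    def test_orthogonal_after_centering(self):
        assert ad.pearson_correlation([1, 0, -1, 0], [0, 1, 0, -1]) == pytest.approx(0.0, abs=1e-15)

    def test_symmetry(self):
        xs, ys = [0.1, 0.9, 0.4, 0.7], [3.0, 1.0, 2.0, 5.0]
        assert ad.pearson_correlation(xs, ys) == ad.pearson_correlation(ys, xs)

    @pytest.mark.parametrize("xs,ys", [([1, 1, 1], [1, 2, 3]), ([1, 2], [3, 4])])
    def test_degenerate_inputs(self, xs, ys):
        with pytest.raises((DegenerateInputError, InvalidArgumentError)):
            ad.pearson_correlation(xs, ys)

    @settings(max_examples=300, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(-50, 50), st.integers(-50, 50)), min_size=3, max_size=8
        )
    )
    def test_matches_definition_level_oracle(self, data):
        xs = [float(x) for x, _ in data]
        ys = [float(y) for _, y in data]
        if max(xs) == min(xs) or max(ys) == min(ys):
            return
        assert ad.pearson_correlation(xs, ys) == pytest.approx(
            pearson_brute_force(xs, ys), abs=1e-12
        )


class TestPValue:
    @pytest.mark.parametrize(
        "r,n,printed,places",
        [
            (-0.39, 50, 0.005, 3),  # published placebo cell that recomputes
            (0.24, 50, 0.09, 2),  # published placebo cell that recomputes
        ],
    )
    def test_published_cells_recompute_after_display_rounding(self, r, n, printed, places):
        assert round(ad.correlation_p_value(r, n), places) == printed

    @pytest.mark.parametrize("r", [0.67, 0.54, 0.47])
    def test_published_strong_cells_are_below_tier_bound(self, r):
        assert ad.correlation_p_value(r, 50) < 0.001

    def test_null_and_perfect_values(self):
        assert ad.correlation_p_value(0.0, 50) == pytest.approx(1.0)
        assert ad.correlation_p_value(1.0, 50) == 0.0
        assert ad.correlation_p_value(-1.0, 10) == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            ad.correlation_p_value(0.5, 2)
        with pytest.raises(InvalidArgumentError):
            ad.correlation_p_value(1.5, 50)

    def test_matches_scipy_pearsonr_p(self):
        rng = np.random.default_rng(0)
        xs, ys = rng.normal(size=30), rng.normal(size=30)
        res = stats.pearsonr(xs, ys)
        assert ad.correlation_p_value(res.statistic, 30) == pytest.approx(res.pvalue, rel=1e-10)

    def test_strictly_decreasing_in_abs_r_and_n(self):
        ps = [ad.correlation_p_value(r, 50) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        pn = [ad.correlation_p_value(0.3, n) for n in (10, 25, 50, 100)]
        assert all(a > b for a, b in zip(pn, pn[1:]))


class TestTiersAndThreshold:
    @pytest.mark.parametrize(
        "p,tier",
        [
            (0.0005, "<.001"),
            (0.001, "<.01"),  # boundaries are exclusive
            (0.005, "<.01"),
            (0.03, "<.05"),
            (0.05, "ns"),
            (0.7, "ns"),
        ],
    )
    def test_tier_bounds(self, p, tier):
        assert ad.significance_tier(p) == tier

    def test_bonferroni_threshold(self):
        assert ad.bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
        assert ad.bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
        with pytest.raises(InvalidArgumentError):
            ad.bonferroni_threshold(0.05, 0)

    def test_display_rounding(self):
        assert format_p(0.0932) == ".09"
        assert format_p(0.00511) == ".005"
        assert format_p(0.0005) == "<.001"


class TestScreen:
    def test_cardinality_and_k(self, small_world):
        config = AnalysisConfig(normalizations=("FB_pop", "FB_int"))
        results = InterestPrevalenceScreen(
            small_world, small_world.taxonomy, small_world.health_table, config
        ).fit()
        # 2 screened interests (reference role excluded) x 1 condition x 2 norms
        assert len(results.records) == 4
        assert results.k == 4
        assert results.threshold == pytest.approx(0.05 / 4)

    def test_planted_marker_is_bonferroni_significant(self):
        world = generate_world(marker_recovery_config(seed=4))
        records = correlation_screen(world, world.taxonomy, world.health_table)
        marker = next(r for r in records if r.role == "marker")
        assert marker.bonferroni_significant
        assert marker.r > 0.5
        assert marker.tier == "<.001"

    def test_degenerate_share_vector_drops_single_record(self, small_world):
        taxonomy = small_world.taxonomy + [
            ad.InterestSpec(name="flatline", role="placebo")
        ]

        class ConstantShareProvider:
            granularity = small_world.granularity

            def audience(self, query):
                if "flatline" in query.interests:
                    return 100
                return small_world.audience(query)

        records = correlation_screen(
            ConstantShareProvider(), taxonomy, small_world.health_table
        )
        assert {r.interest for r in records} == {"plus-size clothing", "technology"}

    def test_k_override_changes_verdicts(self, small_world):
        base = InterestPrevalenceScreen(
            small_world, small_world.taxonomy, small_world.health_table
        ).fit()
        strict = InterestPrevalenceScreen(
            small_world,
            small_world.taxonomy,
            small_world.health_table,
            AnalysisConfig(k_override=10_000_000),
        ).fit()
        assert strict.threshold < base.threshold
        assert not any(r.bonferroni_significant for r in strict.records)


def _rec(interest, role, r, condition="obesity", norm="FB_pop"):
    p = ad.correlation_p_value(r, 50)
    return CorrelationRecord(
        interest=interest,
        role=role,
        condition=condition,
        normalization=norm,
        n=50,
        r=r,
        p=p,
        tier=ad.significance_tier(p),
        bonferroni_significant=False,
    )


class TestPlaceboEnvelope:
    def test_marker_exceeding_envelope(self):
        records = [
            _rec("plus-size clothing", "marker", 0.74),
            _rec("technology", "placebo", 0.68),
            _rec("reading", "placebo", -0.35),
        ]
        report = ad.placebo_envelope_report(records)
        env = report[("obesity", "FB_pop")]
        assert env.envelope == pytest.approx(0.68)
        assert env.markers[0].exceeds_placebo

    def test_marker_within_envelope(self):
        records = [_rec("m", "marker", 0.30), _rec("p", "placebo", -0.39)]
        env = ad.placebo_envelope_report(records)[("obesity", "FB_pop")]
        assert env.envelope == pytest.approx(0.39)
        assert not env.markers[0].exceeds_placebo

    def test_zero_envelope_every_nonzero_marker_exceeds(self):
        records = [_rec("m", "marker", 0.05), _rec("p", "placebo", 0.0)]
        env = ad.placebo_envelope_report(records)[("obesity", "FB_pop")]
        assert env.envelope == 0.0
        assert env.markers[0].exceeds_placebo

    def test_baselines_reported_separately(self):
        records = [
            _rec("m", "marker", 0.5),
            _rec("p", "placebo", 0.2),
            _rec("fitness", "baseline", 0.4),
        ]
        env = ad.placebo_envelope_report(records)[("obesity", "FB_pop")]
        assert [b.interest for b in env.baselines] == ["fitness"]
        assert env.envelope == pytest.approx(0.2)  # baselines don't widen it

    def test_missing_placebos_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            ad.placebo_envelope_report([_rec("m", "marker", 0.5)])


def test_screen_results_render(small_world, tmp_path):
    results = InterestPrevalenceScreen(
        small_world, small_world.taxonomy, small_world.health_table
    ).fit()
    text = results.summary()
    assert "placebo envelope" in text
    results.to_csv(tmp_path / "records.csv")
    results.to_tsv(tmp_path / "wide.tsv")
    import pandas as pd

    back = pd.read_csv(tmp_path / "records.csv")
    assert len(back) == len(results.records)
    wide = pd.read_csv(tmp_path / "wide.tsv", sep="\t")
    assert "FB_pop" in wide.columns
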