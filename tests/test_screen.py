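import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from devswitch.candidates import CandidatePair
from devswitch.datatypes import ExpressionMatrix, Sample
from devswitch.screen import fdr_bh, range_filter, screen_region, trend_correlation

from _oracles import bh_adjust_reference


class TestRangeFilter:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([5.0, 5.0, 5.0], False),          # constant
            ([5.0, 5.7, 6.4], False),          # range 1.4: still excluded
            ([5.0, 5.75, 6.5], True),          # range 1.5: boundary kept
            ([1.0, 4.0], True),
        ],
    )
    def test_boundary_decisions(self, make_profile, values, expected):
        profile = make_profile(values, 70 + 30 * np.arange(len(values)))
        assert range_filter(profile) is expected

    def test_empty_profile_errors(self, make_profile):
        with pytest.raises(ValueError):
            range_filter(make_profile([5.0], [70.0]))


class TestTrendCorrelation:
    def test_identical_profiles_give_rho_one(self, make_profile):
        ages = [70, 100, 200, 400, 800]
        x = make_profile([1, 2, 3, 2, 5], ages)
        for method in ("pearson", "spearman"):
            assert trend_correlation(x, x, method).rho == pytest.approx(1.0)

    def test_negated_affine_gives_rho_minus_one(self, make_profile):
        ages = [70, 100, 200, 400, 800]
        x = make_profile([1.0, 2, 3, 2, 5], ages)
        y = make_profile(-x.values + 7, ages)
        for method in ("pearson", "spearman"):
            assert trend_correlation(x, y, method).rho == pytest.approx(-1.0)

    def test_spearman_hand_ranked_value(self, make_profile):
        # ranks of y: (2,1,4,3,5); sum d^2 = 4; rho = 1 - 6*4/(5*24) = 0.8
        ages = [70, 100, 200, 400, 800]
        x = make_profile([1, 2, 3, 4, 5], ages)
        y = make_profile([2, 1, 4, 3, 5], ages)
        assert trend_correlation(x, y, "spearman").rho == pytest.approx(0.8)

    def test_mismatched_samples_error(self, make_profile):
        x = make_profile([1, 2, 3, 4], [70, 100, 200, 400])
        y = make_profile([1, 2, 3, 4], [71, 100, 200, 400])
        with pytest.raises(ValueError, match="mismatched"):
            trend_correlation(x, y)

    def test_zero_variance_error(self, make_profile):
        ages = [70, 100, 200, 400]
        x = make_profile([1, 2, 3, 4], ages)
        y = make_profile([2, 2, 2, 2], ages)
        with pytest.raises(ValueError, match="zero variance"):
            trend_correlation(x, y)

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        method=st.sampled_from(["pearson", "spearman"]),
    )
    @settings(
        max_examples=30, deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_affine_invariance(self, make_profile, a, b, method):
        ages = [70, 100, 200, 400, 800, 1600]
        rng = np.random.default_rng(3)
        xv = rng.normal(size=6)
        yv = rng.normal(size=6)
        base = trend_correlation(make_profile(xv, ages), make_profile(yv, ages), method)
        scaled = trend_correlation(
            make_profile(xv, ages), make_profile(a * yv + b, ages), method
        )
        assert scaled.rho == pytest.approx(base.rho, abs=1e-9)
        assert scaled.p_value == pytest.approx(base.p_value, abs=1e-9)
        flipped = trend_correlation(
            make_profile(xv, ages), make_profile(-a * yv + b, ages), method
        )
        assert flipped.rho == pytest.approx(-base.rho, abs=1e-9)


class TestFdrBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_all_ones(self):
        assert fdr_bh([0.37]) == pytest.approx([0.37])
        np.testing.assert_allclose(fdr_bh([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                fdr_bh(bad)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_reference_and_dominates_p(self, p):
        q = fdr_bh(p)
        np.testing.assert_allclose(q, bh_adjust_reference(p), rtol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


def build_matrix(gene_values, ages, region="CBC"):
    samples = [
        Sample(f"s{i}", f"s{i}", region, float(a)) for i, a in enumerate(ages)
    ]
    genes = list(gene_values)
    values = np.array([gene_values[g] for g in genes], dtype=float)
    return ExpressionMatrix(genes=genes, samples=samples, values=values)


class TestScreenRegion:
    def test_planted_mirror_pair_is_unique_hit(self):
        rng = np.random.default_rng(11)
        n = 40
        ages = np.sort(rng.uniform(70, 10000, n))
        trend = np.linspace(0, 4, n)
        gene_values = {
            "UP": trend + rng.normal(0, 0.1, n),
            "DOWN": 4 - trend + rng.normal(0, 0.1, n),
        }
        for i in range(6):
            gene_values[f"N{i}"] = rng.normal(0, 1.0, n)
        matrix = build_matrix(gene_values, ages)
        pairs = [CandidatePair("DOWN", "UP", 0.9)]
        pairs += [
            CandidatePair(f"N{i}", f"N{j}", 0.9)
            for i in range(6) for j in range(i + 1, 6)
        ]
        records = screen_region(matrix, pairs, "CBC")
        hits = [r for r in records if r.significant_anticorrelation]
        assert len(hits) == 1
        assert hits[0].pair.key == ("DOWN", "UP")

    def test_all_constant_genes_filtered(self):
        ages = [70, 100, 300, 900]
        matrix = build_matrix({"A": [5] * 4, "B": [6] * 4}, ages)
        records = screen_region(matrix, [CandidatePair("A", "B", 1.0)], "CBC")
        assert records[0].trend is None
        assert not any(records[0].passed_range_filter.values())

    def test_range_failure_skips_correlation(self):
        rng = np.random.default_rng(0)
        ages = np.linspace(70, 5000, 20)
        matrix = build_matrix(
            {"FLAT": 5 + rng.normal(0, 0.1, 20), "VAR": np.linspace(0, 4, 20)},
            ages,
        )
        rec = screen_region(matrix, [CandidatePair("FLAT", "VAR", 1.0)], "CBC")[0]
        assert rec.passed_range_filter == {"FLAT": False, "VAR": True}
        assert rec.trend is None

    def test_too_few_samples_errors(self):
        matrix = build_matrix({"A": [1, 2, 3], "B": [3, 2, 1]}, [70, 100, 200])
        with pytest.raises(ValueError, match="need >= 4"):
            screen_region(matrix, [CandidatePair("A", "B", 1.0)], "CBC")

    def test_null_false_positive_rate_controlled(self):
        # 1000 disjoint i.i.d.-noise pairs: q < 0.01 fraction within 3 SE
        rng = np.random.default_rng(99)
        n = 30
        ages = np.sort(rng.uniform(70, 20000, n))
        gene_values = {f"G{i}": rng.normal(0, 1, n) for i in range(2000)}
        matrix = build_matrix(gene_values, ages)
        pairs = [
            CandidatePair(f"G{2*i}", f"G{2*i+1}", 0.9) for i in range(1000)
        ]
        records = screen_region(matrix, pairs, "CBC")
        frac = np.mean([r.significant_correlation for r in records if r.trend])
        assert frac <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / 1000)
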