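import itertools

import numpy as np
import pytest

from algalmeta.ems import (BoundaryClumpResult, NullDistribution,
                           NullModelConfig, StructureLabel, boundary_clumping,
                           classify_structure, count_embedded_absences,
                           count_replacements, ems_analysis, fill_ranges,
                           generate_null_matrices, null_test,
                           shift_ranges_null, zscore)
from algalmeta.matrix_io import ValidationError
from conftest import make_incidence
from helpers_oracle import (brute_embedded_absences, brute_fill,
                            brute_replacements)


class TestEmbeddedAbsences:
    def test_perfectly_coherent_matrix_is_zero(self):
        a = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1], [0, 0, 1]])
        assert count_embedded_absences(a) == 0

    def test_worked_example_both_axes(self):
        a = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 0, 0]])
        assert count_embedded_absences(a) == 3
        assert count_embedded_absences(a, mode="columns_only") == 2

    def test_exhaustive_3x4_against_oracle(self):
        for bits in itertools.product((0, 1), repeat=12):
            a = np.array(bits, dtype=np.int8).reshape(3, 4)
            assert count_embedded_absences(a) == brute_embedded_absences(a)
            assert (count_embedded_absences(a, mode="columns_only")
                    == brute_embedded_absences(a, both_axes=False))

    def test_random_matrices_against_oracle(self, rng):
        for _ in range(50):
            a = (rng.random((10, 8)) < rng.uniform(0.2, 0.7)).astype(np.int8)
            assert count_embedded_absences(a) == brute_embedded_absences(a)


class TestFillRanges:
    def test_single_gap_filled(self):
        assert fill_ranges(np.array([[1], [0], [1]])).tolist() == [[1], [1], [1]]

    def test_coherent_matrix_unchanged(self):
        a = np.array([[1, 0], [1, 1], [0, 1]], dtype=np.int8)
        np.testing.assert_array_equal(fill_ranges(a), a)

    def test_filled_matrix_has_no_column_gaps(self, rng):
        for _ in range(20):
            a = (rng.random((9, 6)) < 0.3).astype(np.int8)
            filled = fill_ranges(a)
            assert brute_embedded_absences(filled, both_axes=False) == 0
            np.testing.assert_array_equal(filled, brute_fill(a))


class TestReplacements:
    def test_identical_columns_contribute_zero(self):
        a = np.array([[1, 1], [1, 1], [0, 0]])
        assert count_replacements(a) == 0

    def test_worked_example(self):
        # ranges A=rows1-3, B=rows2-4, C=rows3-4 over 4 sites
        a = np.array([[1, 0, 0], [1, 1, 0], [1, 1, 1], [0, 1, 1]])
        assert count_replacements(a) == 3

    def test_nested_matrix_is_zero(self):
        a = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        assert count_replacements(a) == 0

    def test_random_matrices_against_oracle(self, rng):
        for _ in range(50):
            a = (rng.random((10, 8)) < 0.4).astype(np.int8)
            assert count_replacements(a) == brute_replacements(a)


class TestNullModel:
    def test_2x2_identity_class_fully_explored(self):
        m = make_incidence(np.eye(2))
        cfg = NullModelConfig(seed=3, n_sims=100)
        seen = {nm.presence.tobytes() for nm in generate_null_matrices(m, cfg)}
        assert seen == {np.eye(2, dtype=np.int8).tobytes(),
                        np.array([[0, 1], [1, 0]], dtype=np.int8).tobytes()}

    def test_margins_always_preserved(self, rng):
        a = (rng.random((10, 8)) < 0.4).astype(np.int8)
        a[a.sum(1) == 0, 0] = 1
        a[0, a.sum(0) == 0] = 1
        m = make_incidence(a)
        cfg = NullModelConfig(seed=5, n_sims=200)
        for nm in generate_null_matrices(m, cfg):
            np.testing.assert_array_equal(nm.presence.sum(0), a.sum(0))
            np.testing.assert_array_equal(nm.presence.sum(1), a.sum(1))

    def test_reproducible_from_seed(self, rng):
        a = (rng.random((8, 6)) < 0.5).astype(np.int8)
        a[a.sum(1) == 0, 0] = 1
        a[0, a.sum(0) == 0] = 1
        m = make_incidence(a)
        d1 = generate_null_matrices(m, NullModelConfig(seed=11, n_sims=10))
        d2 = generate_null_matrices(m, NullModelConfig(seed=11, n_sims=10))
        for x, y in zip(d1, d2):
            np.testing.assert_array_equal(x.presence, y.presence)

    def test_frozen_staircase_warns(self):
        # a perfect staircase has no checkerboard: its class is a singleton
        a = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        with pytest.warns(UserWarning, match="unique matrix"):
            nulls = generate_null_matrices(make_incidence(a),
                                           NullModelConfig(seed=1, n_sims=5))
        for nm in nulls:
            np.testing.assert_array_equal(nm.presence, a)


class TestNullDistribution:
    def test_moments_z_and_empirical_p(self):
        sims = np.array([10.0, 12.0, 14.0, 16.0, 18.0])
        nd = NullDistribution(observed=10.0, sims=sims)
        assert nd.sim_mean == pytest.approx(14.0, abs=1e-12)
        assert nd.sim_sd == pytest.approx(np.std(sims, ddof=1), abs=1e-12)
        assert nd.z == pytest.approx((14.0 - 10.0) / nd.sim_sd)
        # deviations >= |10-14|=4: sims 10 and 18 -> (1+2)/6
        assert nd.p_empirical == pytest.approx(3 / 6)

    def test_observed_at_mean_gives_z_zero(self):
        nd = NullDistribution(observed=14.0, sims=np.array([10.0, 14.0, 18.0]))
        assert nd.z == 0
        assert nd.p_normal == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValidationError, match="zero null variance"):
            NullDistribution(observed=1.0, sims=np.array([3.0, 3.0, 3.0]))

    def test_published_z_arithmetic(self):
        assert round(zscore(1004, 1382, 31), 1) == 12.2
        assert round(zscore(32361, 21652, 6050), 1) == -1.8


class TestShiftRangesNull:
    def test_preserves_column_sums(self, rng):
        a = fill_ranges((rng.random((12, 6)) < 0.4).astype(np.int8))
        sims1 = shift_ranges_null(a, 10, seed=4)
        sims2 = shift_ranges_null(a, 10, seed=4)
        np.testing.assert_array_equal(sims1, sims2)

    def test_nested_observed_below_shift_null(self):
        # anchored staircase: observed Rep=0, shifted ranges overlap partially
        a = np.zeros((12, 6), dtype=np.int8)
        for j, w in enumerate([12, 10, 8, 6, 4, 2]):
            a[:w, j] = 1
        sims = shift_ranges_null(a, 200, seed=9)
        assert count_replacements(a) == 0
        assert sims.mean() > 0


class TestBoundaryClumping:
    def test_even_boundaries(self):
        # two taxa span rows 0-1, two span rows 2-3: counts [2,2,2,2]
        a = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]])
        bc = boundary_clumping(a)
        assert bc.boundary_counts.tolist() == [2, 2, 2, 2]
        assert bc.morisita_I == pytest.approx(4 * 8 / 56)
        assert bc.df == 3

    def test_maximal_clumping(self):
        # four single-site ranges at the same site: all 8 boundaries coincide
        a = np.zeros((4, 4), dtype=np.int8)
        a[0, :] = 1
        bc = boundary_clumping(a)
        assert bc.morisita_I == pytest.approx(4.0)

    def test_intermediate_clumping(self):
        # counts [5,1,1,1]: two single-site taxa at row0, one range 0-1, one 2-3
        a = np.array([
            [1, 1, 1, 0],
            [0, 0, 1, 0],
            [0, 0, 0, 1],
            [0, 0, 0, 1]])
        bc = boundary_clumping(a)
        assert bc.boundary_counts.tolist() == [5, 1, 1, 1]
        assert bc.morisita_I == pytest.approx(4 * 20 / 56)
        assert bc.chi2 == pytest.approx((4 * 20 / 56) * 7 + 4 - 8)

    def test_single_taxon_errors(self):
        with pytest.raises(ValidationError):
            boundary_clumping(np.array([[1], [1]]))


def _nd(observed, sim_mean, sim_sd):
    rng = np.random.default_rng(0)
    nd = NullDistribution.__new__(NullDistribution)
    nd.observed = observed
    nd.sims = rng.normal(sim_mean, sim_sd, 10)
    nd.sim_mean = sim_mean
    nd.sim_sd = sim_sd
    nd.z = zscore(observed, sim_mean, sim_sd)
    from scipy import stats
    nd.p_normal = float(2 * stats.norm.sf(abs(nd.z)))
    nd.p_empirical = 0.5
    return nd


def _bc(I, p, df=65):
    return BoundaryClumpResult(np.zeros(df + 1, dtype=int), I, float("nan"), df, p)


class TestClassifyStructure:
    @pytest.mark.parametrize("coh,tur,bc,expected", [
        # printed component statistics of the six-lake study
        ((1004, 1382, 31), (59527, 24895, 6440), (2.5, 0.001), "Clementsian"),
        ((1317, 1561, 21), (32361, 21652, 6050), (2.4, 0.001), "Quasi-clementsian"),
        ((11336, 15589, 109), (1995007, 895529, 198657), (9.5, 0.001), "Clementsian"),
        # tree root: non-significant coherence is Random regardless of the rest
        ((100, 102, 5), (50, 10, 5), (2.5, 0.001), "Random"),
        # more absences than the null -> Checkerboard
        ((150, 100, 5), (50, 10, 5), (2.5, 0.001), "Checkerboard"),
        # fewer replacements than the null -> nested family, mode by Morisita
        ((50, 100, 5), (10, 50, 5), (2.5, 0.001), "Nested (clumped)"),
        ((50, 100, 5), (10, 50, 5), (0.5, 0.999), "Nested (hyperdispersed)"),
        ((50, 100, 5), (10, 50, 5), (1.0, 0.5), "Nested (stochastic)"),
        # gradient family with non-significant boundary test -> Gleasonian
        ((50, 100, 5), (90, 50, 5), (1.0, 0.5), "Gleasonian"),
        ((50, 100, 5), (90, 50, 5), (0.5, 0.999), "Evenly spaced"),
        # non-significant turnover -> quasi flag on the deviation-sign family
        ((50, 100, 5), (55, 50, 5), (1.0, 0.5), "Quasi-gleasonian"),
        ((50, 100, 5), (45, 50, 5), (1.0, 0.5), "Quasi-nested (stochastic)"),
    ])
    def test_decision_tree(self, coh, tur, bc, expected):
        label = classify_structure(_nd(*coh), _nd(*tur), _bc(*bc))
        assert str(label) == expected

    def test_total_over_component_grid(self):
        zs = [-30, -2.5, -1.0, 0.0, 1.0, 2.5, 30]
        for cz, tz in itertools.product(zs, zs):
            for I, p in [(0.3, 0.999), (1.0, 0.5), (3.0, 0.001)]:
                label = classify_structure(
                    _nd(100 - cz * 5, 100, 5), _nd(100 - tz * 5, 100, 5), _bc(I, p))
                assert isinstance(label, StructureLabel)

    def test_quasi_only_without_significant_turnover(self):
        label = classify_structure(_nd(50, 100, 5), _nd(90, 50, 5), _bc(2.5, 0.001))
        assert not label.quasi
        label = classify_structure(_nd(50, 100, 5), _nd(55, 50, 5), _bc(2.5, 0.001))
        assert label.quasi


class TestEndToEnd:
    def test_null_test_statistics_agree_with_analysis(self, rng):
        a = (rng.random((15, 10)) < 0.4).astype(np.int8)
        a[a.sum(1) == 0, 0] = 1
        a[0, a.sum(0) == 0] = 1
        m = make_incidence(a)
        cfg = NullModelConfig(seed=21, n_sims=30)
        res = ems_analysis(m, cfg)
        coh = null_test(m, "embedded_absences", cfg)
        assert res.coherence.observed == coh.observed
        np.testing.assert_allclose(res.coherence.sims, coh.sims)
        tur = null_test(m, "replacements", cfg)
        assert res.turnover.observed == tur.observed
        np.testing.assert_allclose(res.turnover.sims, tur.sims)

    def test_json_round_trip_fields(self, rng):
        import json

        a = (rng.random((15, 10)) < 0.4).astype(np.int8)
        a[a.sum(1) == 0, 0] = 1
        a[0, a.sum(0) == 0] = 1
        cfg = NullModelConfig(seed=2, n_sims=20)
        res = ems_analysis(make_incidence(a), cfg)
        d = json.loads(res.to_json(cfg))
        for key in ("abs", "rep", "coherence_z", "turnover_z", "morisita_index",
                    "df", "structure", "coherence_sims", "null_config"):
            assert key in d
        assert len(d["coherence_sims"]) == 20


class TestRangeStatisticProperties:
    """Hypothesis property checks against the brute-force oracles."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    matrices = arrays(np.int8, st.tuples(st.integers(2, 8), st.integers(2, 6)),
                      elements=st.integers(0, 1))

    @given(matrices)
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_embedded_absences_match_oracle(self, a):
        assert count_embedded_absences(a) == brute_embedded_absences(a)

    @given(matrices)
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_replacements_match_oracle_and_filling_removes_gaps(self, a):
        assert count_replacements(a) == brute_replacements(a)
        filled = fill_ranges(a)
        assert brute_embedded_absences(filled, both_axes=False) == 0
        assert np.all(filled >= a)
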