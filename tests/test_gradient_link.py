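import numpy as np
import pandas as pd
import pytest

from algalmeta.gradient_link import (cca, correlate_rank_axis, loadings_matrix,
                                     loadings_table, per_group_cca)
from algalmeta.matrix_io import EnvTable, GroupMap, ValidationError
from algalmeta.ordination import rank_site_scores, reciprocal_averaging
from algalmeta.reference import han_river_cca_loadings
from algalmeta.synthetic import (SyntheticScenario, make_abundances, make_env,
                                 make_structure)
from conftest import make_table


def gradient_dataset(seed=3, k_linked=1, k_noise=3, noise_sd=0.2):
    m, truth = make_structure(SyntheticScenario("gleasonian", n_sites=60,
                                                n_taxa=20, seed=seed))
    env = make_env(truth, k_linked=k_linked, k_noise=k_noise,
                   noise_sd=noise_sd, seed=seed, sample_ids=m.sample_ids)
    table = make_abundances(m, truth, seed=seed)
    return m, truth, table, env


class TestCCA:
    def test_env_equal_to_ca_axis_explains_itself(self, rng):
        m, truth, table, _ = gradient_dataset()
        from algalmeta.matrix_io import to_incidence

        ca = reciprocal_averaging(to_incidence(table))
        env = EnvTable(table.sample_ids, ["axis"], ca.site_scores[:, None])
        r = cca(table, env)
        assert abs(r.loadings[0]) >= 0.99

    def test_noise_environment_rarely_important(self):
        hits = 0
        for seed in range(50):
            m, truth, table, _ = gradient_dataset(seed=200 + seed)
            rng = np.random.default_rng(seed)
            env = EnvTable(table.sample_ids, ["a", "b", "c"],
                           rng.normal(size=(len(table.sample_ids), 3)))
            r = cca(table, env)
            if np.max(np.abs(r.loadings)) < 0.5:
                hits += 1
        assert hits >= 45  # >= 95% of replicates within tolerance of seed noise

    def test_constrained_eigenvalue_below_unconstrained(self, rng):
        from algalmeta.matrix_io import to_incidence

        for seed in range(5):
            m, truth, table, env = gradient_dataset(seed=37 + seed)
            r = cca(table, env)
            ca = reciprocal_averaging(to_incidence(table))
            assert r.eigenvalue_1 <= ca.eigenvalue_1 + 1e-12

    def test_matches_skbio_cca_eigenvalue(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        m, truth, table, env = gradient_dataset(seed=8)
        r = cca(table, env)
        ref = skbio_ord.cca(pd.DataFrame(table.counts, index=table.sample_ids),
                            pd.DataFrame(env.values, index=env.sample_ids))
        assert r.eigenvalue_1 == pytest.approx(float(ref.eigvals.iloc[0]), rel=1e-6)
        rho_lc = np.corrcoef(r.site_scores_lc,
                             ref.sample_constraints.iloc[:, 0].to_numpy())[0, 1]
        rho_wa = np.corrcoef(r.site_scores_wa,
                             ref.samples.iloc[:, 0].to_numpy())[0, 1]
        assert abs(abs(rho_lc) - 1) < 1e-6
        assert abs(abs(rho_wa) - 1) < 1e-6

    def test_affine_rescaling_invariance(self):
        m, truth, table, env = gradient_dataset(seed=5)
        r1 = cca(table, env)
        scaled = EnvTable(env.sample_ids, env.variables,
                          env.values * [3.7, -2.0, 0.01, 40.0] + [5, -1, 0, 100])
        r2 = cca(table, scaled)
        np.testing.assert_allclose(np.abs(r2.loadings), np.abs(r1.loadings),
                                   atol=1e-8)

    def test_zero_variance_variable_rejected(self):
        m, truth, table, env = gradient_dataset(seed=5)
        env.values[:, 1] = 2.5
        with pytest.raises(ValidationError, match="zero-variance"):
            cca(table, env)

    def test_collinear_environment_rejected(self):
        m, truth, table, env = gradient_dataset(seed=5)
        env.values[:, 1] = 2 * env.values[:, 0]
        with pytest.raises(ValidationError, match="collinear"):
            cca(table, env)

    def test_orientation_largest_loading_positive(self):
        m, truth, table, env = gradient_dataset(seed=9)
        r = cca(table, env)
        assert r.loadings[np.argmax(np.abs(r.loadings))] > 0


class TestLoadingsTable:
    def test_published_importance_flags(self):
        ref = han_river_cca_loadings()["ALL"]
        flagged = set(ref.index[ref.abs() > 0.5])
        assert flagged == {"conductivity", "COD", "BOD"}
        assert "temperature" not in flagged

    def test_threshold_one_flags_nothing(self):
        m, truth, table, env = gradient_dataset(seed=4)
        out = loadings_table(cca(table, env), threshold=1.0)
        assert not out["important"].any()

    def test_flags_invariant_to_variable_order(self):
        m, truth, table, env = gradient_dataset(seed=4)
        r1 = cca(table, env)
        perm = [2, 0, 3, 1]
        env2 = EnvTable(env.sample_ids, [env.variables[i] for i in perm],
                        env.values[:, perm])
        r2 = cca(table, env2)
        t1 = loadings_table(r1)
        t2 = loadings_table(r2)
        assert (set(t1.index[t1["important"]])
                == set(t2.index[t2["important"]]))


class TestCorrelateRankAxis:
    def test_perfect_and_reversed_correlation(self):
        m, truth, table, env = gradient_dataset(seed=6)
        r = cca(table, env)
        order = pd.Series(r.site_scores_wa, index=r.sample_ids).rank()
        rho, p, method = correlate_rank_axis(order, r)
        assert rho == pytest.approx(1.0)
        rho2, _, _ = correlate_rank_axis(order.max() + 1 - order, r)
        assert rho2 == pytest.approx(-1.0)

    def test_single_gradient_scenario_high_correlation(self):
        from algalmeta.matrix_io import to_incidence

        m, truth, table, env = gradient_dataset(seed=0)
        ca = reciprocal_averaging(to_incidence(table))
        ranks = rank_site_scores(ca, sample_ids=table.sample_ids)
        r = cca(table, env)
        rho, p, method = correlate_rank_axis(ranks["rank"], r)
        assert abs(rho) >= 0.8
        assert p < 0.001

    def test_too_few_samples_error(self):
        m, truth, table, env = gradient_dataset(seed=6)
        r = cca(table, env)
        with pytest.raises(ValidationError):
            correlate_rank_axis(np.array([1.0, 2.0, 3.0]), r)


class TestPerGroupCCA:
    def test_duplicate_labels_replicate_pooled(self):
        m, truth, table, env = gradient_dataset(seed=12)
        groups = GroupMap({s: "G" for s in table.sample_ids})
        results = per_group_cca(table, env, groups)
        assert [r.group for r in results] == ["ALL", "G"]
        np.testing.assert_allclose(results[0].loadings, results[1].loadings,
                                   atol=1e-10)

    def test_pooled_equals_direct_cca(self):
        m, truth, table, env = gradient_dataset(seed=12)
        groups = GroupMap({s: ("A" if i < 30 else "B")
                           for i, s in enumerate(table.sample_ids)})
        results = per_group_cca(table, env, groups)
        direct = cca(table, env)
        np.testing.assert_allclose(results[0].loadings, direct.loadings, atol=1e-12)

    def test_undersized_group_skipped_with_warning(self):
        m, truth, table, env = gradient_dataset(seed=12)
        labels = {s: "big" for s in table.sample_ids}
        for s in table.sample_ids[:3]:
            labels[s] = "tiny"
        with pytest.warns(UserWarning, match="too few samples"):
            results = per_group_cca(table, env, GroupMap(labels))
        assert {r.group for r in results} == {"ALL", "big"}

    def test_linked_variable_beats_noise_in_most_seeds(self):
        wins = 0
        for seed in range(20):
            m, truth, table, env = gradient_dataset(seed=400 + seed)
            r = cca(table, env)
            linked = truth.linked_variables[0]
            j = r.variables.index(linked)
            others = np.abs(np.delete(r.loadings, j))
            if abs(r.loadings[j]) > others.max():
                wins += 1
        assert wins >= 18

    def test_loadings_matrix_layout(self):
        m, truth, table, env = gradient_dataset(seed=12)
        groups = GroupMap({s: ("A" if i < 30 else "B")
                           for i, s in enumerate(table.sample_ids)})
        df = loadings_matrix(per_group_cca(table, env, groups))
        assert list(df.columns) == ["ALL", "A", "B"]
        assert list(df.index) == env.variables
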