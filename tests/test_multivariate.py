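"""Transforms, resemblance, ordination, SIMPROF clustering, screening, BEST."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phiec.multivariate import (
    ResemblanceMatrix,
    best_match,
    cluster_simprof,
    euclidean_resemblance,
    nmds,
    normalize_env,
    pca,
    simprof_test,
    spearman_screen,
    transform_env,
)


class TestTransformEnv:
    def test_sqrt_applied_to_listed_vars(self):
        df = pd.DataFrame({"NO3": [4.0, 9.0], "depth": [16.0, 25.0]})
        out = transform_env(df, ["NO3"])
        assert list(out["NO3"]) == [2.0, 3.0]
        assert list(out["depth"]) == [16.0, 25.0]  # untouched

    def test_default_set_covers_skewed_covariates(self):
        df = pd.DataFrame({
            "salinity": [4.0], "temperature": [9.0], "chla": [16.0],
            "NO3": [25.0], "PO4": [36.0], "Kd": [0.04],
        })
        out = transform_env(df)
        assert out.loc[0, ["salinity", "temperature", "chla", "NO3", "PO4"]].tolist() == [2, 3, 4, 5, 6]
        assert out.loc[0, "Kd"] == 0.04

    def test_empty_set_is_identity(self):
        df = pd.DataFrame({"NO3": [4.0]})
        pd.testing.assert_frame_equal(transform_env(df, []), df)

    def test_negative_value_raises(self):
        with pytest.raises(ValueError, match="negative"):
            transform_env(pd.DataFrame({"NO3": [-1.0]}), ["NO3"])


class TestNormalizeEnv:
    def test_hand_arithmetic_n_minus_1(self):
        out = normalize_env(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert out["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent_and_centred(self, rng):
        df = pd.DataFrame(rng.normal(3, 7, (50, 4)), columns=list("abcd"))
        once = normalize_env(df)
        twice = normalize_env(once)
        pd.testing.assert_frame_equal(once, twice, atol=1e-12)
        assert np.allclose(once.mean(), 0, atol=1e-12)
        assert np.allclose(once.std(ddof=1), 1, atol=1e-12)

    def test_constant_column_error_names_column(self):
        with pytest.raises(ValueError, match="'flat'"):
            normalize_env(pd.DataFrame({"flat": [2.0, 2.0, 2.0]}))


class TestEuclideanResemblance:
    def test_identical_rows_and_345(self):
        df = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]], columns=["a", "b"])
        r = euclidean_resemblance(df)
        assert r.values[0, 1] == 0.0
        assert r.values[0, 2] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 3)))
        df.columns = ["a", "b", "c"]
        r = euclidean_resemblance(df)
        for i in range(6):
            for j in range(6):
                oracle = np.sqrt(sum(
                    (df.iloc[i, k] - df.iloc[j, k]) ** 2 for k in range(3)
                ))
                assert r.values[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_metric_axioms_on_random_tables(self, rng):
        for _ in range(5):
            df = pd.DataFrame(rng.normal(size=(8, 4)))
            v = euclidean_resemblance(df).values
            assert np.allclose(v, v.T)
            assert np.allclose(np.diag(v), 0)
            for i, j, k in itertools.permutations(range(8), 3):
                assert v[i, k] <= v[i, j] + v[j, k] + 1e-9

    def test_incomplete_rows_dropped_with_warning(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        df.loc[2, "a"] = np.nan
        with pytest.warns(UserWarning, match="dropped 1"):
            r = euclidean_resemblance(df)
        assert r.n == 4

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            ResemblanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])


class TestPCA:
    def test_uncorrelated_standardized_pair_splits_variance(self, rng):
        df = normalize_env(pd.DataFrame(rng.normal(size=(2000, 2)), columns=["a", "b"]))
        _, fractions, _ = pca(df)
        assert fractions[0] == pytest.approx(0.5, abs=0.05)
        assert fractions.sum() == pytest.approx(1.0)

    def test_perfectly_correlated_pair_collapses_to_pc1(self, rng):
        x = rng.normal(size=100)
        df = normalize_env(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        _, fractions, _ = pca(df)
        assert fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal_and_sign_fixed(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 5)))
        loadings, _, _ = pca(df)
        L = loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(5), atol=1e-10)
        for j in range(5):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_degenerate_warns(self, rng):
        df = pd.DataFrame(rng.normal(size=(4, 6)))
        with pytest.warns(UserWarning, match="degenerate"):
            pca(df)


class TestNMDS:
    def test_planar_configuration_has_near_zero_stress(self, rng):
        pts = pd.DataFrame(rng.normal(size=(15, 2)), columns=["x", "y"])
        r = euclidean_resemblance(pts)
        _, stress = nmds(r, dims=2, n_restarts=4, seed=0)
        assert stress < 0.02

    def test_3d_stress_not_above_2d(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 6)))
        r = euclidean_resemblance(df)
        _, s2 = nmds(r, dims=2, n_restarts=6, seed=1)
        _, s3 = nmds(r, dims=3, n_restarts=6, seed=1)
        assert s3 <= s2 + 1e-6

    def test_seed_reproducible(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 3)))
        r = euclidean_resemblance(df)
        conf_a, sa = nmds(r, dims=2, n_restarts=3, seed=42)
        conf_b, sb = nmds(r, dims=2, n_restarts=3, seed=42)
        assert sa == sb
        pd.testing.assert_frame_equal(conf_a, conf_b)

    def test_dims_validated(self, rng):
        r = euclidean_resemblance(pd.DataFrame(rng.normal(size=(5, 2))))
        with pytest.raises(ValueError):
            nmds(r, dims=5)


class TestClusterSimprof:
    def test_identical_rows_single_group(self):
        df = pd.DataFrame(np.ones((10, 3)), columns=["a", "b", "c"])
        part = cluster_simprof(df, seed=0, n_perm_profile=99, n_perm_null=99)
        assert part.n_groups == 1

    def test_two_separated_groups_recovered(self, rng):
        a = rng.normal(0, 1, (20, 3))
        b = rng.normal(8, 1, (20, 3))
        df = pd.DataFrame(np.vstack([a, b]), columns=["x", "y", "z"])
        part = cluster_simprof(df, alpha=0.005, seed=11)
        assert part.n_groups == 2
        labels = part.groups.to_numpy()
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_small_nodes_untestable(self, rng):
        df = pd.DataFrame(rng.normal(size=(2, 3)))
        part = cluster_simprof(df, seed=0, n_perm_profile=29, n_perm_null=29)
        reasons = {t.reason for t in part.tests}
        assert "too_small" in reasons

    def test_simprof_rejects_structure(self, rng):
        a = rng.normal(0, 1, (15, 4))
        b = rng.normal(6, 1, (15, 4))
        _, p = simprof_test(np.vstack([a, b]), 199, 199, rng)
        assert p <= 0.01
        _, p_h = simprof_test(rng.normal(size=(30, 4)), 199, 199, rng)
        assert p_h > 0.05

    def test_newick_export_contains_all_labels(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 2)), index=[f"s{i}" for i in range(6)])
        df.columns = ["a", "b"]
        part = cluster_simprof(df, seed=0, n_perm_profile=29, n_perm_null=29)
        nwk = part.to_newick()
        assert nwk.endswith(";") and all(f"s{i}" in nwk for i in range(6))


class TestSpearmanScreen:
    def test_monotone_and_reversed(self):
        df = pd.DataFrame({
            "up": [1.0, 2, 3, 4, 5, 6], "down": [6.0, 5, 4, 3, 2, 1],
            "phi_ec": [2.0, 4, 5, 7, 8, 11],
        })
        out = screen = spearman_screen(df)
        rho = out.set_index("variable")["rho"]
        assert rho["up"] == pytest.approx(1.0)
        assert rho["down"] == pytest.approx(-1.0)

    def test_null_predictor_rarely_significant(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"x": rng.normal(size=100), "phi_ec": rng.normal(size=100)})
            row = spearman_screen(df).iloc[0]
            assert abs(row["rho"]) < 0.35
            hits += row["p_value"] <= 0.05
        assert hits <= 4  # ~5% type-I over 40 seeded replicates

    def test_tied_variable_reported_missing(self):
        df = pd.DataFrame({"flat": [1.0] * 6, "phi_ec": [1.0, 2, 3, 4, 5, 6]})
        out = spearman_screen(df)
        assert np.isnan(out.loc[out["variable"] == "flat", "rho"].iloc[0])

    def test_per_study_grouping(self, rng):
        df = pd.DataFrame({
            "study_id": ["a"] * 8 + ["b"] * 8,
            "x": rng.normal(size=16), "phi_ec": rng.normal(size=16),
        })
        out = spearman_screen(df, group="study_id")
        assert set(out["group"]) == {"global", "a", "b"}


def brute_force_best(env: pd.DataFrame, phi: np.ndarray):
    """Naive-loop oracle: all subsets, list-based distances, scipy Spearman."""
    n = len(env)
    names = list(env.columns)
    phi_d = [abs(phi[i] - phi[j]) for i in range(n) for j in range(i + 1, n)]
    best = (None, -np.inf)
    for r in range(1, len(names) + 1):
        for cols in itertools.combinations(names, r):
            d = []
            for i in range(n):
                for j in range(i + 1, n):
                    d.append(np.sqrt(sum((env[c].iloc[i] - env[c].iloc[j]) ** 2 for c in cols)))
            rho = stats.spearmanr(d, phi_d).statistic
            if rho > best[1]:
                best = (cols, rho)
    return best


class TestBestMatch:
    def test_constructed_signal_recovered(self, rng):
        env = pd.DataFrame(rng.normal(size=(25, 5)), columns=["T", "S", "N", "P", "K"])
        phi = 2.0 * env["T"] + 1.5 * env["S"] + rng.normal(0, 0.05, 25)
        res = best_match(env, phi, max_subset_size=3, n_perm=99, seed=0)
        assert res.best_subset == ("T", "S")
        assert res.p_value <= 0.01

    def test_matches_brute_force_oracle(self, rng):
        env = pd.DataFrame(rng.normal(size=(8, 3)), columns=["a", "b", "c"])
        phi = rng.normal(size=8)
        res = best_match(env, phi, max_subset_size=3, n_perm=19, seed=0)
        oracle_subset, oracle_rho = brute_force_best(env, phi)
        assert res.best_subset == oracle_subset
        assert res.rho == pytest.approx(oracle_rho, abs=1e-12)
        # full search table covers all 7 subsets
        assert len(res.table) == 7

    def test_row_order_invariance(self, rng):
        env = pd.DataFrame(rng.normal(size=(12, 3)), columns=["a", "b", "c"])
        phi = pd.Series(2 * env["a"] + rng.normal(0, 0.1, 12))
        res1 = best_match(env, phi, n_perm=19, seed=5)
        perm = rng.permutation(12)
        res2 = best_match(env.iloc[perm].reset_index(drop=True),
                          phi.iloc[perm].reset_index(drop=True), n_perm=19, seed=5)
        assert res1.best_subset == res2.best_subset
        assert res1.rho == pytest.approx(res2.rho, abs=1e-12)

    def test_null_phi_not_significant(self):
        insignif = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            env = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("wxyz"))
            phi = rng.normal(size=20)
            res = best_match(env, phi, max_subset_size=3, n_perm=99, seed=seed)
            insignif += res.p_value > 0.01
        assert insignif >= int(0.95 * n_rep)

    def test_subset_cap(self, rng):
        env = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="max_subset_size"):
            best_match(env, rng.normal(size=10), max_subset_size=4, subset_cap=5)
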