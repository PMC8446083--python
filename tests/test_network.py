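"""Adjacency, topological overlap, module detection, eigengenes, trait correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poleward import (
    NetworkConfig,
    detect_modules,
    module_eigengene,
    module_trait_correlation,
    node_geography,
    soft_adjacency,
    tom_matrix,
)
from poleward.errors import ConfigError, InputError


def tom_oracle(A: np.ndarray) -> np.ndarray:
    """Naive O(n^3) topological overlap."""
    n = A.shape[0]
    Aoff = A.copy()
    np.fill_diagonal(Aoff, 0.0)
    k = Aoff.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(Aoff[i, u] * Aoff[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l + Aoff[i, j]) / (min(k[i], k[j]) + 1 - Aoff[i, j])
    return T


class TestSoftAdjacency:
    def test_perfect_correlation_is_one(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        a = soft_adjacency(t, beta=7)
        assert a.loc["a", "b"] == pytest.approx(1.0)

    def test_negative_half_correlation_to_eleventh_power(self, rng):
        # Build two profiles with Pearson r exactly -0.5 by construction.
        x = np.array([1.0, -1.0, 0.5, -0.5, 0.0, 2.0, -2.0, 1.5])
        x = (x - x.mean()) / x.std()
        z = rng.normal(size=x.size)
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)  # orthogonal to x
        z /= z.std()
        y = -0.5 * x + np.sqrt(1 - 0.25) * z
        t = pd.DataFrame({"a": x, "b": y})
        a = soft_adjacency(t, beta=11)
        assert a.loc["a", "b"] == pytest.approx(0.5**11, rel=1e-9)

    def test_signed_variant_kills_anticorrelation(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [-1.0, -2, -3, -4]})
        unsigned = soft_adjacency(t, beta=6, adjacency_type="unsigned")
        signed = soft_adjacency(t, beta=6, adjacency_type="signed")
        assert unsigned.loc["a", "b"] == pytest.approx(1.0)
        assert signed.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_feature_named(self):
        t = pd.DataFrame({"a": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(InputError, match="flat"):
            soft_adjacency(t, beta=6)


class TestTom:
    def test_empty_graph_stays_empty(self):
        A = pd.DataFrame(np.eye(5))
        T = tom_matrix(A)
        off = T.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_complete_graph_is_all_ones(self):
        A = pd.DataFrame(np.ones((6, 6)))
        assert np.allclose(tom_matrix(A), 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 9))
            M = rng.uniform(0, 1, (n, n))
            A = (M + M.T) / 2
            np.fill_diagonal(A, 1.0)
            T = tom_matrix(pd.DataFrame(A))
            assert np.max(np.abs(T.to_numpy() - tom_oracle(A))) < 1e-12

    def test_out_of_range_adjacency_rejected(self):
        A = np.eye(4)
        A[0, 1] = A[1, 0] = 1.5
        with pytest.raises(InputError):
            tom_matrix(pd.DataFrame(A))


class TestDetectModules:
    def test_planted_anticorrelated_blocks_recovered(self, rng):
        n_st, m = 30, 12
        g = np.linspace(-1, 1, n_st)
        block1 = np.column_stack([g + rng.normal(0, 0.05, n_st) for _ in range(m)])
        block2 = np.column_stack([-g + rng.normal(0, 0.05, n_st) for _ in range(m)])
        t = pd.DataFrame(
            np.hstack([block1, block2]),
            columns=[f"a{i}" for i in range(m)] + [f"b{i}" for i in range(m)],
        )
        adj = soft_adjacency(t, beta=6, adjacency_type="signed")
        labels = detect_modules(tom_matrix(adj), NetworkConfig(min_module_size=4))
        a_lab = set(labels[[f"a{i}" for i in range(m)]])
        b_lab = set(labels[[f"b{i}" for i in range(m)]])
        assert len(a_lab) == 1 and len(b_lab) == 1 and a_lab != b_lab
        assert "grey" not in (a_lab | b_lab)

    def test_identity_tom_yields_all_grey(self):
        T = pd.DataFrame(np.eye(8), columns=[f"f{i}" for i in range(8)])
        labels = detect_modules(T, NetworkConfig(min_module_size=3, cut_height=0.5))
        assert set(labels) == {"grey"}

    def test_cut_height_one_is_single_module(self, rng):
        M = rng.uniform(0, 1, (9, 9))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 1.0)
        T = tom_matrix(pd.DataFrame(A, columns=[f"f{i}" for i in range(9)]))
        labels = detect_modules(T, NetworkConfig(cut_height=1.0, min_module_size=3))
        assert labels.nunique() == 1 and labels.iloc[0] == "turquoise"

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            NetworkConfig(cut_height=0.0)
        with pytest.raises(ConfigError):
            NetworkConfig(soft_power=0)


class TestEigengene:
    def test_identical_profiles_give_that_profile(self, rng):
        p = rng.normal(size=15)
        t = pd.DataFrame({"a": p, "b": p.copy()})
        labels = pd.Series({"a": "m", "b": "m"})
        e = module_eigengene(t, labels, "m")
        z = (p - p.mean()) / p.std(ddof=1)
        assert np.corrcoef(e, z)[0, 1] == pytest.approx(1.0)
        assert e.std(ddof=1) == pytest.approx(1.0)

    def test_mirror_members_have_unit_abs_correlation(self, rng):
        p = rng.normal(size=12)
        t = pd.DataFrame({"a": p, "b": -p})
        labels = pd.Series({"a": "m", "b": "m"})
        e = module_eigengene(t, labels, "m")
        assert abs(np.corrcoef(e, t["a"])[0, 1]) == pytest.approx(1.0)

    def test_matches_symmetric_eigendecomposition_oracle(self, rng):
        t = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        labels = pd.Series("m", index=t.columns)
        e = module_eigengene(t, labels, "m").to_numpy()
        Z = (t - t.mean()) / t.std(ddof=1)
        # Oracle: leading eigenvector of Z Z^T (no SVD call).
        w, V = np.linalg.eigh(Z.to_numpy() @ Z.to_numpy().T)
        lead = V[:, np.argmax(w)]
        r = np.corrcoef(e, lead)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_member_order(self, rng):
        t = pd.DataFrame(rng.normal(size=(18, 6)), columns=list("abcdef"))
        labels = pd.Series("m", index=t.columns)
        e1 = module_eigengene(t, labels, "m")
        shuffled = t[["d", "b", "f", "a", "c", "e"]]
        e2 = module_eigengene(shuffled, labels, "m")
        assert np.max(np.abs(e1 - e2)) < 1e-10

    def test_unknown_module_rejected(self, rng):
        t = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        with pytest.raises(InputError):
            module_eigengene(t, pd.Series({"a": "m", "b": "m"}), "nope")


class TestTraitCorrelation:
    def test_half_correlation_p_value(self, rng):
        # r = 0.5 at n = 20 gives t = 2.4495 and p ~ 0.0247; build the
        # eigengene/covariate pair to have that exact correlation.
        n = 20
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z = rng.normal(size=n)
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)
        z /= z.std()
        y = 0.5 * x + np.sqrt(0.75) * z
        idx = [f"s{i}" for i in range(n)]
        r, p = module_trait_correlation(
            pd.DataFrame({"m": x}, index=idx), pd.DataFrame({"T": y}, index=idx)
        )
        assert r.loc["m", "T"] == pytest.approx(0.5, abs=1e-9)
        t_stat = 0.5 * np.sqrt(18 / 0.75)
        assert p.loc["m", "T"] == pytest.approx(2 * stats.t.sf(t_stat, 18), rel=1e-9)
        assert p.loc["m", "T"] == pytest.approx(0.0247, abs=5e-4)

    def test_too_few_shared_stations_rejected(self, rng):
        e = pd.DataFrame({"m": rng.normal(size=3)}, index=["a", "b", "c"])
        env = pd.DataFrame({"T": [1.0, 2, 3]}, index=["a", "b", "c"])
        with pytest.raises(InputError):
            module_trait_correlation(e, env)


class TestNodeGeography:
    def test_single_station_holds_everything(self):
        t = pd.DataFrame({"a": [10.0, 0.0], "b": [5.0, 0.0]}, index=["s1", "s2"])
        labels = pd.Series({"a": "m", "b": "m"})
        pct = node_geography(t, labels, "m")
        assert pct["s1"] == pytest.approx(100.0) and pct["s2"] == 0.0

    def test_uniform_distribution(self):
        t = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0]})
        pct = node_geography(t, pd.Series({"a": "m"}), "m")
        assert np.allclose(pct, 25.0)

    def test_cold_module_mass_sits_in_cold_stations(self, transect):
        labels = pd.Series(transect.truth.module_membership)
        pct = node_geography(transect.table_pfam, labels, "cold")
        cold_stations = transect.env.index[transect.env["temperature"] < transect.truth.threshold_T]
        assert pct.loc[cold_stations].sum() > 95.0
        assert pct.sum() == pytest.approx(100.0)
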