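import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from sklearn.metrics import adjusted_rand_score

import emtdyn as e
from emtdyn.containers import ValidationError
from emtdyn.coexpression import UNASSIGNED


def ts(rows: dict, hours=None) -> e.TimeSeriesMatrix:
    df = pd.DataFrame(rows).T
    df.columns = hours if hours is not None else [float(i) for i in range(df.shape[1])]
    return e.TimeSeriesMatrix(df)


def hand_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


class TestCorrelationMatrix:
    def test_perfect_linear_and_antilinear(self, tiny_timeseries):
        C = e.correlation_matrix(tiny_timeseries)
        assert C.loc["g1", "g2"] == pytest.approx(1.0)
        assert C.loc["g1", "g3"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        X = ts({"a": [1, 2, 4], "b": [1, 3, 2]})
        C = e.correlation_matrix(X)
        assert C.loc["a", "b"] == pytest.approx(hand_pearson([1, 2, 4], [1, 3, 2]))

    def test_zero_variance_gene_rejected_by_name(self):
        X = ts({"flat": [2, 2, 2], "ok": [1, 2, 3]})
        with pytest.raises(ValidationError, match="flat"):
            e.correlation_matrix(X)

    def test_symmetric_unit_diagonal(self, study):
        C = e.correlation_matrix(study["Xa"])
        v = C.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert v.min() >= -1.0 and v.max() <= 1.0


class TestAdjacency:
    def test_anticorrelation_modes(self):
        C = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]], index=list("ab"),
                         columns=list("ab"))
        assert e.adjacency(C, 6, "unsigned").loc["a", "b"] == pytest.approx(1.0)
        assert e.adjacency(C, 6, "signed").loc["a", "b"] == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(hst.integers(0, 10_000), hst.integers(1, 8))
    def test_matches_elementwise_bruteforce(self, seed, beta):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(5, 7))
        C = pd.DataFrame(np.corrcoef(M), index=list("abcde"), columns=list("abcde"))
        for mode, fn in (("unsigned", lambda r: abs(r) ** beta),
                         ("signed", lambda r: ((1 + r) / 2) ** beta)):
            A = e.adjacency(C, beta, mode).to_numpy()
            for i in range(5):
                for j in range(5):
                    want = 0.0 if i == j else fn(C.iloc[i, j])
                    assert A[i, j] == pytest.approx(want, abs=1e-12)

    def test_invalid_beta_rejected(self):
        C = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValidationError):
            e.adjacency(C, 0)


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    n = len(a)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTOM:
    def test_complete_graph_closed_form(self):
        n = 6
        a = np.ones((n, n)) - np.eye(n)
        ids = [f"g{i}" for i in range(n)]
        tom = e.tom_similarity(pd.DataFrame(a, index=ids, columns=ids))
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_isolated_pair_is_zero(self):
        a = np.zeros((3, 3))
        ids = list("abc")
        tom = e.tom_similarity(pd.DataFrame(a, index=ids, columns=ids))
        off = tom.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, (6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        ids = [f"g{i}" for i in range(6)]
        tom = e.tom_similarity(pd.DataFrame(a, index=ids, columns=ids))
        assert np.allclose(tom.to_numpy(), brute_force_tom(a), atol=1e-12)


class TestSoftPower:
    def test_planted_power_law_connectivity_fits_well(self):
        """A connectivity sequence constructed on the exact quantiles of a
        power law scores R^2 >= 0.95 in the binned log-log fit."""
        from emtdyn.coexpression import _scale_free_fit
        u = (np.arange(4000) + 0.5) / 4000
        k = (1 - u) ** (-1 / 2.0)
        assert _scale_free_fit(k) >= 0.95

    def test_chosen_power_is_smallest_passing(self, study):
        C = e.correlation_matrix(study["Xa"])
        rep = e.pick_soft_power(C, powers=range(1, 13), target_fit=0.1,
                                mode="signed")
        passing = rep.table.loc[rep.table.fit_r2 > 0.1, "power"]
        assert rep.chosen_power == int(passing.iloc[0])
        assert not rep.fallback

    def test_constant_matrix_falls_back_with_warning(self):
        n = 20
        C = np.full((n, n), 0.5)
        np.fill_diagonal(C, 1.0)
        ids = [f"g{i}" for i in range(n)]
        with pytest.warns(UserWarning):
            rep = e.pick_soft_power(pd.DataFrame(C, index=ids, columns=ids),
                                    powers=[2, 4])
        assert rep.fallback
        assert rep.chosen_power in (2, 4)


def block_tom(sizes, within=0.9, between=0.0):
    n = sum(sizes)
    t = np.full((n, n), between)
    start = 0
    for s in sizes:
        t[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(t, 1.0)
    ids = [f"g{i:03d}" for i in range(n)]
    return pd.DataFrame(t, index=ids, columns=ids)


class TestDetectModules:
    def test_planted_blocks_recovered_exactly(self):
        tom = block_tom([40, 40, 40])
        part = e.detect_modules(tom, min_size=30)
        truth = np.repeat([0, 1, 2], 40)
        assert len(part.module_labels) == 3
        assert adjusted_rand_score(truth, part.assignment.values) == 1.0

    def test_small_block_unassigned(self):
        tom = block_tom([40, 29])   # second block below min_size
        part = e.detect_modules(tom, min_size=30)
        labels = part.assignment.values
        assert (labels[40:] == UNASSIGNED).all()

    def test_noise_genes_mostly_unassigned(self):
        rng = np.random.default_rng(0)
        X = e.TimeSeriesMatrix(pd.DataFrame(
            rng.normal(size=(400, 10)),
            index=[f"g{i:03d}" for i in range(400)],
            columns=[float(h) for h in range(10)],
        ))
        corr = e.correlation_matrix(X)
        tom = e.tom_similarity(e.adjacency(corr, 6, "signed"))
        part = e.detect_modules(tom, min_size=100, expr=X)
        assert (part.assignment == UNASSIGNED).mean() >= 0.9

    def test_fewer_genes_than_min_size_warns_all_unassigned(self):
        tom = block_tom([10])
        with pytest.warns(UserWarning):
            part = e.detect_modules(tom, min_size=50)
        assert (part.assignment == UNASSIGNED).all()

    def test_permutation_equivariance(self, study):
        X = study["Xa"]
        corr = e.correlation_matrix(X)
        tom = e.tom_similarity(e.adjacency(corr, 6, "signed"))
        part = e.detect_modules(tom, min_size=30, expr=X)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(X.gene_ids))
        Xp = e.TimeSeriesMatrix(X.values.iloc[perm])
        corr_p = e.correlation_matrix(Xp)
        tom_p = e.tom_similarity(e.adjacency(corr_p, 6, "signed"))
        part_p = e.detect_modules(tom_p, min_size=30, expr=Xp)
        aligned = part_p.assignment.loc[part.assignment.index]
        assert (aligned == part.assignment).all()

    def test_labels_ordered_by_decreasing_size(self, detected):
        part = detected["a"]["part"]
        sizes = [len(part.members(m)) for m in part.module_labels]
        assert sizes == sorted(sizes, reverse=True)


class TestEigengene:
    def test_identical_profiles_rank_one(self):
        prof = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        X = ts({f"g{i}": prof for i in range(6)})
        eig, ev, single = e.module_eigengene(X, X.gene_ids)
        assert not single
        assert ev == pytest.approx(1.0)
        assert abs(np.corrcoef(eig, prof)[0, 1]) == pytest.approx(1.0)

    def test_orientation_toward_mean_profile(self, study, detected):
        X, part = study["Xa"], detected["a"]["part"]
        eig = detected["a"]["eig"]
        for m in part.module_labels:
            block = X.restrict(part.members(m)).values.to_numpy()
            z = (block - block.mean(1, keepdims=True)) / block.std(1, keepdims=True)
            r = np.corrcoef(eig.profiles.loc[m], z.mean(0))[0, 1]
            assert r >= 0

    def test_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(7)
        M = rng.normal(size=(20, 8))
        X = ts({f"g{i:02d}": M[i] for i in range(20)})
        eig, ev, _ = e.module_eigengene(X, X.gene_ids)
        Z = (M - M.mean(1, keepdims=True)) / M.std(1, keepdims=True)
        _, s, vt = np.linalg.svd(Z)
        want = vt[0]
        assert min(np.abs(eig - want).max(), np.abs(eig + want).max()) < 1e-10
        assert ev == pytest.approx(s[0] ** 2 / (s**2).sum())
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_single_gene_module_flagged(self):
        X = ts({"g0": [1.0, 2.0, 4.0], "g1": [0.0, 1.0, 5.0]})
        with pytest.warns(UserWarning):
            eig, ev, single = e.module_eigengene(X, ["g0"])
        assert single and ev == 1.0
        assert np.linalg.norm(eig) == pytest.approx(1.0)
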