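import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import emtdyn as e
from emtdyn.containers import ValidationError
from emtdyn.coexpression import EigengeneSet


def ts(rows, hours):
    df = pd.DataFrame(rows).T
    df.columns = list(hours)
    return e.TimeSeriesMatrix(df)


@pytest.fixture()
def toy_eig():
    hours = [0.0, 2.0, 8.0, 24.0, 72.0]
    e1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    e2 = np.array([2.0, 1.0, 3.0, 1.0, 2.0])
    prof = pd.DataFrame([e1 / np.linalg.norm(e1), e2 / np.linalg.norm(e2)],
                        index=["M1", "M2"], columns=hours)
    return EigengeneSet(prof, pd.Series({"M1": 0.9, "M2": 0.8}))


class TestMembership:
    def test_rescaled_and_negated_eigengene(self, toy_eig):
        hours = toy_eig.profiles.columns
        X = ts({"up": [10, 20, 30, 40, 50], "down": [-1, -2, -3, -4, -5]}, hours)
        kme = e.module_membership(X, toy_eig)
        assert kme.loc["up", "M1"] == pytest.approx(1.0)
        assert kme.loc["down", "M1"] == pytest.approx(-1.0)

    def test_matches_pairwise_pearson_oracle(self, toy_eig):
        rng = np.random.default_rng(0)
        hours = toy_eig.profiles.columns
        X = ts({f"g{i}": rng.normal(size=5) for i in range(8)}, hours)
        kme = e.module_membership(X, toy_eig)
        for g in X.gene_ids:
            for m in toy_eig.modules:
                want = np.corrcoef(X.values.loc[g], toy_eig.profiles.loc[m])[0, 1]
                assert kme.loc[g, m] == pytest.approx(want, abs=1e-12)

    def test_stage_grid_mismatch_rejected(self, toy_eig):
        X = ts({"g": [1, 2, 3]}, [0.0, 1.0, 2.0])
        with pytest.raises(ValidationError):
            e.module_membership(X, toy_eig)


class TestFlagEMTModules:
    def test_seed_equal_to_eigengene_flags_module(self, toy_eig):
        hours = toy_eig.profiles.columns
        seeds = ts({"seed1": toy_eig.profiles.loc["M1"].values * 3.0}, hours)
        flags = e.flag_emt_modules(seeds, toy_eig)
        assert bool(flags.loc["M1", "flagged"])
        assert flags.loc["M1", "best_seed"] == "seed1"

    def test_uncorrelated_seed_does_not_flag(self, toy_eig):
        hours = toy_eig.profiles.columns
        seeds = ts({"seed1": [1.0, -1.0, 1.0, -1.0, 1.0]}, hours)
        flags = e.flag_emt_modules(seeds, toy_eig)
        assert not flags.loc["M1", "flagged"]

    def test_threshold_is_strict(self, toy_eig):
        """A module whose best seed correlation equals the threshold exactly
        must NOT be flagged."""
        hours = toy_eig.profiles.columns
        rng = np.random.default_rng(2)
        seeds = ts({"s": rng.normal(size=5)}, hours)
        flags = e.flag_emt_modules(seeds, toy_eig, r_threshold=0.0)
        best = float(flags["best_r"].max())
        at_threshold = e.flag_emt_modules(seeds, toy_eig, r_threshold=best)
        assert not at_threshold.loc[flags["best_r"].idxmax(), "flagged"]

    def test_monotone_in_threshold(self, study, detected):
        X, eig = study["Xa"], detected["a"]["eig"]
        seeds = X.restrict(study["truth"].seed_emt_genes)
        counts = [
            e.flag_emt_modules(seeds, eig, r_threshold=t)["flagged"].sum()
            for t in (0.5, 0.7, 0.9, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_seed_list_rejected(self, toy_eig):
        hours = toy_eig.profiles.columns
        X = ts({"g": [1, 2, 3, 4, 5]}, hours)
        empty = e.TimeSeriesMatrix(X.values.iloc[:0])
        with pytest.raises(ValidationError):
            e.flag_emt_modules(empty, toy_eig)


def flags_frame(modules, flagged):
    return pd.DataFrame(
        {"flagged": [m in flagged for m in modules],
         "best_seed": "s", "best_r": 0.95},
        index=modules,
    )


class TestTopMembership:
    def test_small_module_contributes_all_genes(self):
        mem = pd.DataFrame({"M1": [0.9, 0.8, 0.7]}, index=["a", "b", "c"])
        out = e.top_membership_genes(mem, flags_frame(["M1"], {"M1"}), k=50)
        assert sorted(out["gene"]) == ["a", "b", "c"]

    def test_tie_at_rank_k_broken_lexicographically(self):
        mem = pd.DataFrame({"M1": [0.9, 0.5, 0.5]}, index=["a", "z", "b"])
        out = e.top_membership_genes(mem, flags_frame(["M1"], {"M1"}), k=2)
        assert sorted(out["gene"]) == ["a", "b"]

    def test_matches_full_sort_oracle(self, study, detected):
        X, eig = study["Xa"], detected["a"]["eig"]
        mem = e.module_membership(X, eig)
        flags = flags_frame(eig.modules, {eig.modules[0]})
        out = e.top_membership_genes(mem, flags, k=50)
        m = eig.modules[0]
        want = mem[m].sort_values(ascending=False).index[:50]
        # oracle modulo ties: compare kME multisets
        assert np.allclose(
            sorted(out["kme"]), sorted(mem.loc[want, m]), atol=1e-12
        )

    def test_k_monotonicity(self, study, detected):
        X, eig = study["Xa"], detected["a"]["eig"]
        mem = e.module_membership(X, eig)
        flags = flags_frame(eig.modules, set(eig.modules))
        small = set(e.top_membership_genes(mem, flags, k=10)["gene"])
        large = set(e.top_membership_genes(mem, flags, k=60)["gene"])
        assert small <= large

    def test_no_flagged_modules_warns_empty(self):
        mem = pd.DataFrame({"M1": [0.9]}, index=["a"])
        with pytest.warns(UserWarning):
            out = e.top_membership_genes(mem, flags_frame(["M1"], set()), k=5)
        assert out.empty


def cand(genes, module="M1"):
    return pd.DataFrame(
        {"gene": list(genes), "module": module,
         "kme": np.linspace(0.99, 0.9, len(genes)),
         "rank": range(1, len(genes) + 1)}
    )


class TestIntersectSignature:
    def test_identical_sets(self):
        sig = e.intersect_signature(cand("abc"), cand("abc"))
        assert sig.genes == ["a", "b", "c"]

    def test_disjoint_sets_warn_empty(self):
        with pytest.warns(UserWarning):
            sig = e.intersect_signature(cand("ab"), cand("cd"))
        assert len(sig) == 0

    def test_symmetry(self):
        a, b = cand("abcf"), cand("bcde")
        assert (e.intersect_signature(a, b).genes
                == e.intersect_signature(b, a).genes)

    def test_sorted_by_gene_id(self):
        sig = e.intersect_signature(cand("zxy"), cand("yzx"))
        assert sig.genes == sorted(sig.genes)


class TestTemporalGroups:
    def test_planted_archetypes_recovered(self):
        hours = np.array([0, 1, 2, 4, 6, 8, 16, 24, 72, 168.0])
        rows, truth = {}, []
        for aid in (1, 2, 3, 4):
            prof = e.archetype_profile(aid, hours)
            for j in range(10):
                rows[f"a{aid}_g{j}"] = prof
                truth.append(aid)
        X = ts(rows, hours)
        out = e.temporal_groups(X, k=4, seed=0)
        assert adjusted_rand_score(truth, out["group"]) == 1.0

    def test_single_group(self, tiny_timeseries):
        out = e.temporal_groups(tiny_timeseries, k=1, seed=0)
        assert set(out["group"]) == {1}

    def test_deterministic_given_seed(self, study):
        X = study["Xa"].restrict(study["truth"].seed_emt_genes)
        a = e.temporal_groups(X, k=4, seed=3)
        b = e.temporal_groups(X, k=4, seed=3)
        assert a.equals(b)

    def test_k_larger_than_gene_count_rejected(self, tiny_timeseries):
        with pytest.raises(ValidationError):
            e.temporal_groups(tiny_timeseries, k=10, seed=0)


def hand_ks(x, y):
    """Max ECDF gap by direct enumeration."""
    pts = sorted(set(x) | set(y))
    gap = 0.0
    for p in pts:
        fx = sum(v <= p for v in x) / len(x)
        fy = sum(v <= p for v in y) / len(y)
        gap = max(gap, abs(fx - fy))
    return gap


class TestCorrelationContrast:
    def make_cohort(self, G, n, rng, signal_genes=0, covariate=None):
        M = rng.normal(size=(G, n))
        if signal_genes and covariate is not None:
            M[:signal_genes] = 0.8 * covariate + 0.6 * rng.normal(
                size=(signal_genes, n))
        fpkm = 2.0 ** (5 + M)
        return e.PatientMatrix(pd.DataFrame(
            fpkm, index=[f"g{i:03d}" for i in range(G)],
            columns=[f"s{j:03d}" for j in range(n)]))

    def test_null_t_statistic_centered_and_p_uniform(self):
        from scipy import stats
        rng = np.random.default_rng(0)
        tstats, pvals = [], []
        for _ in range(200):
            cov = rng.normal(size=40)
            cohort = self.make_cohort(30, 40, rng)
            rep = e.gene_set_correlation_contrast(
                cohort, cov, [f"g{i:03d}" for i in range(10)])
            tstats.append(rep.t_statistic)
            pvals.append(rep.t_pvalue)
        assert abs(np.mean(tstats)) < 0.2
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_signal_detected_with_power(self):
        rng = np.random.default_rng(1)
        wins = 0
        for _ in range(100):
            cov = rng.normal(size=200)
            cohort = self.make_cohort(80, 200, rng, signal_genes=20,
                                      covariate=cov)
            rep = e.gene_set_correlation_contrast(
                cohort, cov, [f"g{i:03d}" for i in range(20)])
            wins += rep.t_pvalue < 1e-4
        assert wins >= 95

    def test_ks_statistic_matches_hand_enumeration(self):
        from scipy import stats
        x = [0.1, 0.4, 0.35, 0.8, 0.2]
        y = [0.05, 0.5, 0.6, 0.9, 0.7]
        assert stats.ks_2samp(x, y).statistic == pytest.approx(hand_ks(x, y))

    def test_complement_empty_rejected(self):
        rng = np.random.default_rng(2)
        cohort = self.make_cohort(5, 10, rng)
        with pytest.raises(ValidationError):
            e.gene_set_correlation_contrast(
                cohort, rng.normal(size=10), list(cohort.gene_ids))
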