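"""Metabolite preprocessing, OPLS-DA internals, VIP, permutation test, DEM calls."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import adjusted_rand_score

from heatomics import (
    MetaboliteMatrix,
    OPLSDA,
    SimulationConfig,
    call_dems,
    metabolite_kmeans,
    permutation_test,
    preprocess,
    simulate_metabolites,
    vip_scores,
)


def make_metabolites(vals, genotypes=None, conditions=None, replicates=None):
    n_m, n_s = vals.shape
    ids = [f"m{i}" for i in range(n_m)]
    sids = [f"s{j}" for j in range(n_s)]
    genotypes = genotypes or ["tolerant"] * n_s
    conditions = conditions or (["CK"] * (n_s // 2) + ["HS"] * (n_s - n_s // 2))
    samples = pd.DataFrame(
        {
            "genotype": genotypes,
            "condition": conditions,
            "replicate": replicates or list(range(1, n_s + 1)),
        },
        index=pd.Index(sids, name="sample_id"),
    )
    return MetaboliteMatrix(
        intensities=pd.DataFrame(vals, index=ids, columns=sids), samples=samples
    )


class TestPreprocess:
    def test_constant_metabolite_centered_to_zero(self):
        mm = make_metabolites(np.full((1, 6), 128.0))
        out = preprocess(mm)
        assert out.to_numpy() == pytest.approx(0.0)

    def test_variable_means_zero(self):
        rng = np.random.default_rng(0)
        mm = make_metabolites(rng.lognormal(10, 1, size=(40, 6)))
        out = preprocess(mm)
        assert out.mean(axis=1).to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_uncentering_recovers_log_values(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(10, 1, size=(10, 4))
        mm = make_metabolites(vals)
        logx = np.log2(vals)
        out = preprocess(mm)
        restored = out.to_numpy() + logx.mean(axis=1, keepdims=True)
        assert restored == pytest.approx(logx)

    def test_all_zero_metabolite_dropped_with_warning(self):
        vals = np.vstack([np.zeros(4), np.full(4, 8.0)])
        with pytest.warns(UserWarning, match="all-zero"):
            out = preprocess(make_metabolites(vals))
        assert list(out.index) == ["m1"]


class TestOplsda:
    def test_separable_classes_high_r2y(self):
        rng = np.random.default_rng(2)
        n = 10
        X = rng.normal(size=(n, 20)) * 0.0
        y = np.array(["A"] * 5 + ["B"] * 5)
        X[:, 0] = np.where(y == "B", 1.0, -1.0)  # single perfectly separating variable
        res = OPLSDA(X, y, n_ortho=0).fit(seed=0)
        assert res.r2y >= 0.99

    def test_orthogonal_component_raises_r2x_not_r2y(self):
        rng = np.random.default_rng(3)
        n = 12
        y = np.array(["A"] * 6 + ["B"] * 6)
        signal = np.where(y == "B", 1.0, -1.0)
        ortho_factor = np.tile([1.0, -1.0], 6)  # structured, y-orthogonal
        X = np.outer(signal, np.r_[np.ones(5), np.zeros(5)])
        X += np.outer(ortho_factor, np.r_[np.zeros(5), np.ones(5)])
        X += rng.normal(scale=0.01, size=X.shape)
        res0 = OPLSDA(X, y, n_ortho=0).fit(seed=0)
        res1 = OPLSDA(X, y, n_ortho=1).fit(seed=0)
        assert res1.r2x > res0.r2x
        assert res1.r2y == pytest.approx(res0.r2y, abs=1e-6)

    def test_q2_not_exceeding_r2y(self, met_sim):
        _, mm, _ = met_sim
        for genotype in ("tolerant", "susceptible"):
            sub = mm.subset_samples(mm.samples["genotype"] == genotype)
            res = OPLSDA(preprocess(sub).T, sub.samples["condition"]).fit(seed=0)
            assert res.q2 <= res.r2y + 1e-6

    def test_matches_pls1_when_no_orthogonal_component(self):
        """With n_ortho=0 the predictive component is the first PLS1 component."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(14, 30))
        y = np.array(["A"] * 7 + ["B"] * 7)
        res = OPLSDA(X, y, n_ortho=0).fit(seed=0)
        pls = PLSRegression(n_components=1, scale=False).fit(
            X - X.mean(0), np.where(y == "B", 1.0, -1.0)
        )
        ours = res.scores.to_numpy()
        theirs = pls.x_scores_[:, 0]
        sign = np.sign(ours @ theirs)
        assert ours == pytest.approx(sign * theirs, rel=1e-8)

    def test_scores_invariant_under_variable_reordering(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 15))
        y = np.array(["A"] * 5 + ["B"] * 5)
        res1 = OPLSDA(X, y, n_ortho=1).fit(seed=0)
        perm = rng.permutation(15)
        res2 = OPLSDA(X[:, perm], y, n_ortho=1).fit(seed=0)
        assert res1.scores.to_numpy() == pytest.approx(res2.scores.to_numpy(), abs=1e-9)
        assert res1.vip.to_numpy()[perm] == pytest.approx(res2.vip.to_numpy(), abs=1e-9)

    def test_one_class_rejected(self):
        X = np.random.default_rng(6).normal(size=(6, 4))
        with pytest.raises(ValueError, match="two classes"):
            OPLSDA(X, ["A"] * 6)

    def test_excessive_n_ortho_rejected(self):
        X = np.random.default_rng(7).normal(size=(4, 10))
        with pytest.raises(ValueError, match="n_ortho"):
            OPLSDA(X, ["A", "A", "B", "B"], n_ortho=3)


class TestVip:
    def test_single_informative_variable_closed_form(self):
        """One nonzero weight gives VIP sqrt(p) for it and 0 elsewhere."""
        p = 25
        X = np.zeros((8, p))
        y = np.array(["A"] * 4 + ["B"] * 4)
        X[:, 3] = np.where(y == "B", 1.0, -1.0)
        res = OPLSDA(X, y, n_ortho=0).fit(seed=0)
        expected = np.zeros(p)
        expected[3] = np.sqrt(p)
        assert res.vip.to_numpy() == pytest.approx(expected, abs=1e-8)

    def test_equal_weights_all_unity(self):
        p = 16
        X = np.zeros((6, p))
        y = np.array(["A"] * 3 + ["B"] * 3)
        X[:] = np.where(y == "B", 1.0, -1.0)[:, None]  # all variables identical
        res = OPLSDA(X, y, n_ortho=0).fit(seed=0)
        assert res.vip.to_numpy() == pytest.approx(np.ones(p))

    def test_sum_squared_vip_equals_n_variables(self, met_sim):
        _, mm, _ = met_sim
        sub = mm.subset_samples(mm.samples["genotype"] == "susceptible")
        X = preprocess(sub).T
        res = OPLSDA(X, sub.samples["condition"]).fit(seed=0)
        assert float((res.vip**2).sum()) == pytest.approx(X.shape[1])
        assert (vip_scores(res) == res.vip).all()


class TestPermutation:
    def test_planted_effect_small_p(self, met_sim):
        _, mm, _ = met_sim
        sub = mm.subset_samples(mm.samples["genotype"] == "susceptible")
        model = OPLSDA(preprocess(sub).T, sub.samples["condition"])
        perm = permutation_test(model, n_perm=99, seed=0)
        assert perm.p_value <= 0.05
        assert perm.q2_observed > np.median(perm.q2_null)

    def test_refit_with_identical_labels_reproduces_statistic(self, met_sim):
        _, mm, _ = met_sim
        sub = mm.subset_samples(mm.samples["genotype"] == "tolerant")
        model = OPLSDA(preprocess(sub).T, sub.samples["condition"])
        a = model.fit(seed=0)
        b = OPLSDA(preprocess(sub).T, sub.samples["condition"]).fit(seed=0)
        assert a.q2 == pytest.approx(b.q2)
        assert a.r2y == pytest.approx(b.r2y)

    def test_noise_data_p_not_small(self):
        """On pure noise the permutation p should rarely be small."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(8, 30))
            y = np.array(["A"] * 4 + ["B"] * 4)
            perm = permutation_test(OPLSDA(X, y), n_perm=39, seed=seed)
            hits += perm.p_value < 0.05
        assert hits <= 1

    def test_tiny_n_perm_warns(self, met_sim):
        _, mm, _ = met_sim
        sub = mm.subset_samples(mm.samples["genotype"] == "tolerant")
        model = OPLSDA(preprocess(sub).T, sub.samples["condition"])
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test(model, n_perm=5, seed=0)


class TestCallDems:
    def test_inclusive_boundaries(self):
        vals = np.ones((2, 6))
        vals[0, 3:] = 2.0  # exactly log2fc = 1
        mm = make_metabolites(vals)
        vip = pd.Series([1.0, 2.0], index=["m0", "m1"])
        out = call_dems(mm, vip)
        assert out.loc["m0", "call"] == "up"  # vip == 1 and log2fc == 1 both count
        assert out.loc["m1", "call"] == "ns"  # log2fc = 0

    def test_high_vip_low_fc_not_called(self):
        vals = np.ones((1, 6))
        vals[0, 3:] = 2**0.5
        mm = make_metabolites(vals)
        out = call_dems(mm, pd.Series([2.0], index=["m0"]))
        assert out.loc["m0", "call"] == "ns"

    def test_missing_condition_errors(self):
        mm = make_metabolites(np.ones((1, 4)), conditions=["CK"] * 4)
        with pytest.raises(ValueError, match="missing"):
            call_dems(mm, pd.Series([1.0], index=["m0"]))

    def test_planted_dem_recovery(self, met_sim):
        """Planted differential metabolites recovered with sensitivity >= 0.8."""
        _, mm, truth = met_sim
        for genotype in ("tolerant", "susceptible"):
            sub = mm.subset_samples(mm.samples["genotype"] == genotype)
            res = OPLSDA(preprocess(sub).T, sub.samples["condition"]).fit(seed=0)
            dems = call_dems(sub, res.vip)
            planted = {
                m: d[genotype] for m, d in truth.met_status.items() if d[genotype] != "ns"
            }
            if not planted:
                continue
            hits = sum(dems.loc[m, "call"] == direction for m, direction in planted.items())
            assert hits / len(planted) >= 0.8

    def test_zero_planted_dems_zero_true_positives(self):
        config = SimulationConfig(n_metabolites=100, met_planted={}, rng_seed=31)
        mm, truth = simulate_metabolites(config)
        assert all(
            d["tolerant"] == "ns" and d["susceptible"] == "ns"
            for d in truth.met_status.values()
        )


class TestMetaboliteKmeans:
    def test_planted_archetypes_recovered(self):
        rng = np.random.default_rng(8)
        patterns = {
            "A": [0, 2, 0, 2],  # up under heat in both genotypes
            "B": [2, 0, 2, 0],  # down under heat
            "C": [0, 0, 0, 2],  # up in susceptible only
        }
        rows, labels = [], []
        base = 14.0
        for name, pat in patterns.items():
            for _ in range(20):
                log2_groups = base + np.array(pat, float)
                reps = np.repeat(log2_groups, 3) + rng.normal(0, 0.05, 12)
                rows.append(2.0**reps)
                labels.append(name)
        genotypes = ["tolerant"] * 6 + ["susceptible"] * 6
        conditions = (["CK"] * 3 + ["HS"] * 3) * 2
        mm = make_metabolites(
            np.array(rows), genotypes=genotypes, conditions=conditions,
            replicates=[1, 2, 3] * 4,
        )
        res = metabolite_kmeans(mm, list(mm.metabolite_ids), k=3, seed=0)
        assert adjusted_rand_score(labels, res.assignments) == 1.0

    def test_constant_metabolite_excluded_with_warning(self):
        vals = np.vstack([np.full(12, 64.0), 2 ** np.linspace(10, 12, 12)])
        genotypes = ["tolerant"] * 6 + ["susceptible"] * 6
        conditions = (["CK"] * 3 + ["HS"] * 3) * 2
        mm = make_metabolites(vals, genotypes=genotypes, conditions=conditions,
                              replicates=[1, 2, 3] * 4)
        with pytest.warns(UserWarning, match="constant"):
            res = metabolite_kmeans(mm, ["m0", "m1"], k=1, seed=0)
        assert list(res.assignments.index) == ["m1"]

    def test_same_seed_same_partition(self, met_sim):
        _, mm, _ = met_sim
        ids = list(mm.metabolite_ids[:60])
        a = metabolite_kmeans(mm, ids, k=5, seed=3).assignments
        b = metabolite_kmeans(mm, ids, k=5, seed=3).assignments
        assert (a == b).all()
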