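"""Ensemble construction, averaging identities and dropout optimization."""

import numpy as np
import pytest

from conftest import FixedPredictor, brute_force_best_subset, make_linear_dataset
from envgp.ensembles import (
    EnsembleModel,
    ensemble_predict,
    holdout_split,
    optimize_ensemble,
    train_bagged_ensemble,
    train_ensemble,
    train_singular,
)
from envgp.models import fit_ols


def ols_fitter(X, y, seed):
    return fit_ols(X, y)


class TestAveraging:
    def test_prediction_is_exact_submodel_mean(self):
        subs = [FixedPredictor([1.0, 4.0]), FixedPredictor([3.0, 0.0])]
        ens = EnsembleModel(subs, [["A"], ["B"]], "ensemble")
        assert np.array_equal(ensemble_predict(ens, np.zeros((2, 1))),
                              [2.0, 2.0])

    def test_single_submodel_equals_base(self):
        sub = FixedPredictor([5.0, -1.0])
        ens = EnsembleModel([sub], [["A"]], "singular")
        assert np.array_equal(ens.predict(None), sub.predict(None))

    def test_permutation_invariant(self):
        preds = [FixedPredictor(p) for p in ([0.0, 1], [2.0, 3], [4.0, 5])]
        a = EnsembleModel(preds, [["A"], ["B"], ["C"]], "ensemble")
        b = EnsembleModel(preds[::-1], [["C"], ["B"], ["A"]], "ensemble")
        assert np.allclose(a.predict(None), b.predict(None))


class TestSingular:
    def test_duplicated_blocks_leave_ols_unchanged(self):
        ds = make_linear_dataset(n_locations=3, identical_blocks=True, seed=2)
        single = fit_ols(ds.blocks["L01"].X, ds.blocks["L01"].y)
        pooled = train_singular(ds, ols_fitter, "L03")  # trains on L01+L02 copies
        Xt = ds.blocks["L03"].X
        assert np.allclose(pooled.predict(Xt), single.predict(Xt), atol=1e-8)

    def test_test_location_never_in_membership(self):
        ds = make_linear_dataset()
        m = train_singular(ds, ols_fitter, "L02")
        assert "L02" not in m.membership[0]

    def test_prediction_length_matches_test_block(self):
        ds = make_linear_dataset()
        m = train_singular(ds, ols_fitter, "L01")
        assert len(m.predict(ds.blocks["L01"].X)) == len(ds.blocks["L01"].y)


class TestEnsembleTraining:
    def test_one_submodel_per_training_location(self):
        ds = make_linear_dataset(n_locations=5)
        m = train_ensemble(ds, ols_fitter, "L05")
        assert len(m.submodels) == 4
        assert m.membership == [["L01"], ["L02"], ["L03"], ["L04"]]

    def test_identical_blocks_collapse_to_singular(self):
        ds = make_linear_dataset(n_locations=4, identical_blocks=True, seed=9)
        Xt = ds.blocks["L04"].X
        ens = train_ensemble(ds, ols_fitter, "L04")
        sing = train_singular(ds, ols_fitter, "L04")
        assert np.allclose(ens.predict(Xt), sing.predict(Xt), atol=1e-8)


class TestBagging:
    def test_single_location_degenerate_bags(self):
        ds = make_linear_dataset(n_locations=2)
        m = train_bagged_ensemble(ds, ols_fitter, 3, seed=1, test_location="L02")
        assert all(bag == ["L01"] for bag in m.membership)

    def test_reproducible_but_varied_bags(self):
        ds = make_linear_dataset(n_locations=5)
        a = train_bagged_ensemble(ds, ols_fitter, 6, seed=4, test_location="L05")
        b = train_bagged_ensemble(ds, ols_fitter, 6, seed=4, test_location="L05")
        assert a.membership == b.membership
        assert len({tuple(bag) for bag in a.membership}) > 1

    def test_bootstrap_exclusion_fraction(self):
        ds = make_linear_dataset(n_locations=6, n_per_block=6, n_features=2)
        m = train_bagged_ensemble(ds, ols_fitter, 400, seed=2,
                                  test_location="L06")
        L = 5
        absent = np.mean([(L - len(set(bag))) / L for bag in m.membership])
        assert absent == pytest.approx((1 - 1 / L) ** L, abs=0.05)


class TestOptimization:
    def _adversarial_case(self, case):
        rng = np.random.default_rng(100 + case)
        n_val = 80
        y = rng.normal(size=n_val)
        k = int(rng.integers(3, 9))
        noise = rng.normal(scale=0.5, size=(k - 1, n_val))
        noise -= noise.mean(axis=0)  # good-model errors cancel in the mean
        preds = [y + noise[i] for i in range(k - 1)]
        adv = int(rng.integers(0, k))
        preds.insert(adv, -y + 0.5 * rng.normal(size=n_val))
        ens = EnsembleModel([FixedPredictor(p) for p in preds],
                            [[f"L{i}"] for i in range(k)], "ensemble")
        return ens, preds, y, adv

    def test_adversary_excluded_and_greedy_optimal(self):
        for case in range(20):
            ens, preds, y, adv = self._adversarial_case(case)
            opt = optimize_ensemble(ens, np.zeros((len(y), 1)), y)
            kept = {int(mb[0][1:]) for mb in opt.membership}
            best, _ = brute_force_best_subset(preds, y)
            assert adv not in kept, f"case {case}"
            assert kept == best, f"case {case}"

    def test_identical_submodels_all_retained(self):
        y = np.random.default_rng(1).normal(size=30)
        preds = [FixedPredictor(y + 0.1) for _ in range(4)]
        ens = EnsembleModel(preds, [[f"L{i}"] for i in range(4)], "ensemble")
        opt = optimize_ensemble(ens, np.zeros((30, 1)), y)
        assert len(opt.submodels) == 4  # strict inequality: ties keep data

    def test_submodels_never_refit_by_dropout(self):
        ens, _, y, _ = self._adversarial_case(0)
        ids_before = [id(s) for s in ens.submodels]
        opt = optimize_ensemble(ens, np.zeros((len(y), 1)), y)
        assert all(id(s) in ids_before for s in opt.submodels)

    def test_constant_truth_rejected(self):
        preds = [FixedPredictor(np.arange(5.0)) for _ in range(2)]
        ens = EnsembleModel(preds, [["A"], ["B"]], "ensemble")
        with pytest.raises(ValueError, match="validation"):
            optimize_ensemble(ens, np.zeros((5, 1)), np.ones(5))

    def test_optimized_validation_accuracy_never_below_full(self):
        from envgp.metrics import accuracy
        for case in range(10):
            ens, preds, y, _ = self._adversarial_case(case)
            opt = optimize_ensemble(ens, np.zeros((len(y), 1)), y)
            if len(opt.submodels) < len(ens.submodels):
                full_acc = accuracy(y, ens.predict(np.zeros((len(y), 1))))
                opt_acc = accuracy(y, opt.predict(np.zeros((len(y), 1))))
                assert opt_acc >= full_acc - 1e-12


class TestVarianceReduction:
    def test_ensemble_prediction_variance_bounded_by_submodel_mean(self):
        # independent location noise: var of the averaged prediction across
        # seeds cannot exceed the average submodel prediction variance
        rng = np.random.default_rng(20)
        beta = rng.normal(size=3)
        X_test = rng.normal(size=(1, 3))
        ens_preds, sub_preds = [], []
        for seed in range(60):
            r = np.random.default_rng(seed)
            subs = []
            for _ in range(4):
                X = r.normal(size=(15, 3))
                y = X @ beta + 0.8 * r.normal(size=15)
                subs.append(fit_ols(X, y))
            sub_preds.append([m.predict(X_test)[0] for m in subs])
            ens_preds.append(np.mean(sub_preds[-1]))
        var_ens = np.var(ens_preds)
        var_subs = np.mean(np.var(np.array(sub_preds), axis=0))
        assert var_ens <= var_subs + 1e-12


class TestHoldoutSplit:
    def test_no_genotype_straddles_split(self):
        ds = make_linear_dataset(n_locations=4, identical_blocks=True)
        reduced, Xv, yv = holdout_split(ds, "L04", seed=3)
        held_rows = sum(len(ds.blocks[l].y) - len(reduced.blocks[l].y)
                        for l in reduced.blocks if l != "L04")
        assert held_rows == len(yv)
        train_gids = {g for l, b in reduced.blocks.items() if l != "L04"
                      for g in b.genotype_ids}
        all_gids = {g for l in ("L01", "L02", "L03")
                    for g in ds.blocks[l].genotype_ids}
        held_gids = all_gids - train_gids
        assert held_gids and train_gids.isdisjoint(held_gids)

    def test_test_block_untouched(self):
        ds = make_linear_dataset()
        reduced, _, _ = holdout_split(ds, "L02", seed=1)
        assert reduced.blocks["L02"] is ds.blocks["L02"]
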