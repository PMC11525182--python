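"""Impairment module: gradient correctness against finite differences,
set invariances, head linearity, loss semantics and checkpointing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import setrvat as sv
from setrvat.model import (
    ImpairmentModule,
    PhenotypeHead,
    TrainingConfig,
    forward_predict,
    multitask_loss,
)


def _random_sets(rng, n_sets=6, d=5, max_size=4):
    sizes = rng.integers(1, max_size + 1, size=n_sets)
    S = sizes.max()
    A = rng.normal(size=(n_sets, S, d))
    mask = np.arange(S)[None, :] < sizes[:, None]
    A[~mask] = 0.0
    return A, mask


class TestForwardInvariances:
    def test_permutation_invariance(self, rng):
        mod = ImpairmentModule(5, rng_seed=3)
        x = rng.normal(size=(7, 5))
        s1 = mod.score_gene(x)
        s2 = mod.score_gene(x[rng.permutation(7)])
        assert s1 == s2

    def test_duplication_invariance(self, rng):
        mod = ImpairmentModule(4, rng_seed=1)
        x = rng.normal(size=(3, 4))
        dup = np.vstack([x, x[1:2], x[1:2]])
        assert mod.score_gene(x) == pytest.approx(mod.score_gene(dup), abs=0.0)

    def test_padding_never_changes_scores(self, rng):
        mod = ImpairmentModule(5, rng_seed=2)
        A, mask = _random_sets(rng)
        psi1, _ = mod.forward_sets(A, mask)
        # add three more columns of pure padding with arbitrary content
        pad = rng.normal(size=(A.shape[0], 3, 5)) * 100
        A2 = np.concatenate([A, pad], axis=1)
        mask2 = np.concatenate([mask, np.zeros((A.shape[0], 3), bool)], axis=1)
        psi2, _ = mod.forward_sets(A2, mask2)
        assert np.array_equal(psi1, psi2)

    def test_scores_strictly_inside_unit_interval(self, rng):
        mod = ImpairmentModule(5, rng_seed=4)
        for _ in range(20):
            s = mod.score_gene(rng.normal(size=(rng.integers(1, 6), 5)))
            assert 0.0 < s < 1.0

    def test_empty_set_scores_exactly_zero(self):
        mod = ImpairmentModule(5)
        assert mod.score_gene(np.empty((0, 5))) == 0.0

    def test_dominated_member_is_ignored(self, rng):
        # a member whose phi-embedding is element-wise dominated cannot
        # change the max; construct it through an identity-ish phi
        mod = ImpairmentModule(3, rng_seed=0)
        big = np.full((1, 3), 5.0)
        small = np.full((1, 3), -5.0)
        # ensure domination holds at the embedding level for this draw
        _, cache = mod.forward_sets(
            np.stack([np.vstack([big, small])]), np.ones((1, 2), bool))
        h2 = cache[5]
        if np.all(h2[0, 0] >= h2[0, 1]):
            assert mod.score_gene(big) == mod.score_gene(np.vstack([big, small]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariance_over_many_parameter_draws(self, seed):
        rng = np.random.default_rng(seed)
        mod = ImpairmentModule(4, rng_seed=seed)
        x = rng.normal(size=(rng.integers(1, 6), 4))
        perm = x[rng.permutation(x.shape[0])]
        dup = np.vstack([x, x[:1]])
        s = mod.score_gene(x)
        assert s == mod.score_gene(perm)
        # duplication changes the batch shape, which may flip the last bit
        # of the BLAS reduction; equality is demanded to machine precision
        assert mod.score_gene(dup) == pytest.approx(s, abs=1e-14)

    def test_dimension_mismatch_raises(self):
        mod = ImpairmentModule(5)
        with pytest.raises(sv.DataError):
            mod.score_gene(np.ones((2, 4)))


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        mod = ImpairmentModule(4, rng_seed=7)
        A, mask = _random_sets(rng, n_sets=5, d=4)
        target = rng.normal(size=5)

        def loss_fn():
            psi, _ = mod.forward_sets(A, mask)
            return 0.5 * np.sum((psi - target) ** 2)

        psi, cache = mod.forward_sets(A, mask)
        grads = {k: np.zeros_like(v) for k, v in mod.params.items()}
        mod.backward_sets(psi - target, cache, grads)
        eps = 1e-6
        for name in mod.params:
            flat = mod.params[name].ravel()
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_fn()
                flat[idx] = orig - eps
                down = loss_fn()
                flat[idx] = orig
                num = (up - down) / (2 * eps)
                assert grads[name].ravel()[idx] == pytest.approx(num, abs=1e-5), name

    def test_linear_ablation_gradient(self, rng):
        mod = ImpairmentModule(3, rng_seed=9, linear=True)
        A, mask = _random_sets(rng, n_sets=4, d=3)
        psi, cache = mod.forward_sets(A, mask)
        grads = {k: np.zeros_like(v) for k, v in mod.params.items()}
        mod.backward_sets(np.ones(4), cache, grads)
        eps = 1e-6
        name = "phi1_W"
        flat = mod.params[name].ravel()
        orig = flat[0]
        flat[0] = orig + eps
        up = mod.forward_sets(A, mask)[0].sum()
        flat[0] = orig - eps
        down = mod.forward_sets(A, mask)[0].sum()
        flat[0] = orig
        assert grads[name].ravel()[0] == pytest.approx((up - down) / (2 * eps), abs=1e-5)


class TestForwardPredict:
    def _head(self):
        return PhenotypeHead(trait="t", alpha=np.array([0.5, -1.0]),
                             genes=["g1", "g2"], w=np.array([2.0, 0.0]))

    def test_zero_weights_reduce_to_covariates(self, rng):
        mod = ImpairmentModule(3, rng_seed=0)
        head = self._head()
        head.w = np.zeros(2)
        x = np.array([1.0, 2.0])
        sets = {"g1": rng.normal(size=(2, 3))}
        assert forward_predict(mod, head, x, sets) == pytest.approx(x @ head.alpha)

    def test_empty_gene_contributes_nothing(self, rng):
        mod = ImpairmentModule(3, rng_seed=0)
        head = self._head()
        x = np.array([1.0, 2.0])
        sets = {"g1": rng.normal(size=(2, 3))}
        with_empty = dict(sets, g2=np.empty((0, 3)))
        assert forward_predict(mod, head, x, sets) == forward_predict(
            mod, head, x, with_empty)

    def test_linear_in_gene_weight(self, rng):
        mod = ImpairmentModule(3, rng_seed=0)
        head = self._head()
        x = np.array([0.0, 0.0])
        sets = {"g1": rng.normal(size=(2, 3))}
        y1 = forward_predict(mod, head, x, sets)
        head2 = PhenotypeHead("t", head.alpha, head.genes,
                              np.array([4.0, 0.0]))
        y2 = forward_predict(mod, head2, x, sets)
        assert y2 - y1 == pytest.approx(2.0 * mod.score_gene(sets["g1"]))


class TestMultitaskLoss:
    def test_zero_for_perfect_predictions(self):
        assert multitask_loss({"a": np.array([1.0, 2.0])},
                              {"a": np.array([1.0, 2.0])}) == 0.0

    def test_single_trait_is_plain_mse(self, rng):
        p = rng.normal(size=10)
        y = rng.normal(size=10)
        assert multitask_loss({"a": p}, {"a": y}) == pytest.approx(
            np.mean((p - y) ** 2))

    def test_mean_across_traits(self):
        loss = multitask_loss(
            {"a": np.array([1.0, 1.0]), "b": np.array([2.0, 2.0])},
            {"a": np.array([1.2, 0.8]), "b": np.array([1.8, 2.2])})
        # per-trait MSEs are 0.04 and 0.04
        assert loss == pytest.approx(0.04)

    def test_missing_pairs_excluded(self):
        loss = multitask_loss({"a": np.array([1.0, 5.0])},
                              {"a": np.array([1.0, np.nan])})
        assert loss == 0.0

    def test_all_missing_raises(self):
        with pytest.raises(sv.DataError):
            multitask_loss({"a": np.array([1.0])}, {"a": np.array([np.nan])})


@pytest.fixture(scope="module")
def trained(small_cohort):
    _, dataset, truth = small_cohort
    seeds = {"quant": sorted(truth.seed_genes["quant"])}
    cfg = TrainingConfig(min_epochs=5, max_epochs=30, patience=5,
                         batch_size=256, rng_seed=0)
    mod, heads, log = sv.train_impairment_module(
        dataset, seeds, truth.assignment, cfg)
    return dataset, truth, mod, heads, log, cfg


class TestTraining:
    def test_loss_improves_over_initialization(self, trained):
        _, _, _, _, log, _ = trained
        assert log["train_loss"].iloc[-1] <= log.attrs["initial_train_loss"]

    def test_seeded_reproducibility(self, small_cohort):
        _, dataset, truth = small_cohort
        seeds = {"quant": sorted(truth.seed_genes["quant"])}
        cfg = TrainingConfig(min_epochs=3, max_epochs=3, patience=3,
                             batch_size=256, rng_seed=11)
        m1, h1, _ = sv.train_impairment_module(dataset, seeds, truth.assignment, cfg)
        m2, h2, _ = sv.train_impairment_module(dataset, seeds, truth.assignment, cfg)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])
        assert np.array_equal(h1["quant"].w, h2["quant"].w)

    def test_no_seed_genes_raises(self, small_cohort):
        _, dataset, truth = small_cohort
        with pytest.raises(sv.DataError):
            sv.train_impairment_module(dataset, {"quant": []}, truth.assignment,
                                       TrainingConfig())

    def test_checkpoint_round_trip(self, trained, tmp_path):
        dataset, truth, mod, _, _, _ = trained
        mod.save(str(tmp_path / "ckpt"), extra={"maf_cutoff": 0.01})
        back = ImpairmentModule.load(str(tmp_path / "ckpt"))
        for k in mod.params:
            assert np.array_equal(mod.params[k], back.params[k])
        x = np.random.default_rng(0).normal(size=(3, mod.d))
        assert mod.score_gene(x) == back.score_gene(x)

    def test_schema_mismatch_rejected(self, trained):
        dataset, truth, mod, _, _, _ = trained
        with pytest.raises(sv.DataError, match="schema"):
            mod.check_schema(dataset.annotation_cols[:-1] + ["bogus"])

    def test_score_matrix_zero_for_noncarriers(self, trained):
        dataset, truth, mod, _, _, _ = trained
        S = sv.score_matrix(mod, dataset, truth.assignment, maf_cutoff=0.01)
        gene = dataset.gene_ids[0]
        rows = truth.assignment.loc[truth.assignment["gene_id"] == gene,
                                    "variant_row"].to_numpy()
        qual = sv.filter_qualifying_variants(dataset.variants, 0.01)
        rows = np.intersect1d(rows, qual)
        carriers = np.asarray(
            (dataset.genotypes.matrix.tocsc()[:, rows] != 0).sum(axis=1)).ravel() > 0
        vals = S[gene].to_numpy()
        assert np.all(vals[~carriers] == 0.0)
        assert np.all(vals[carriers] > 0.0)

    def test_validation_config_rejected(self):
        with pytest.raises(sv.DataError):
            TrainingConfig(val_fraction=1.5)
        with pytest.raises(sv.DataError):
            TrainingConfig(min_epochs=10, max_epochs=5)
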