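"""Composite loss, step semantics, CV selection and LOSO plumbing."""

import numpy as np
import pytest

from deepjdd import (EpochSet, FeatureBatch, KernelConfig, LossWeights,
                     NetworkSpec, TrainConfig, build_dcjnn,
                     cross_validate_gammas, evaluate, forward_features,
                     forward_predict, jdd_sq_bruteforce, leave_one_subject_out,
                     mmd_sq, total_loss, train_supervised, train_transfer)
from deepjdd.trainer import GAMMA_GRID, AdamOptimizer, train_step


def tiny_epochs(rng, n=12, ch=4, T=32, subject=0, labeled=True):
    labels = np.tile([0, 1], n // 2) if labeled else None
    return EpochSet(data=rng.standard_normal((n, ch, T)),
                    labels=labels,
                    subject_ids=np.full(n, subject),
                    srate_hz=100.0,
                    channel_names=[f"c{i}" for i in range(ch)],
                    class_names=["left", "right"])


TINY_NET = NetworkSpec(n_classes=2)


def tiny_config(**over):
    base = dict(batch_size=4, max_epochs=2, seed=0, network=TINY_NET)
    base.update(over)
    return TrainConfig(**base)


class TestLossWeights:
    def test_nonnegative(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 0.0)

    def test_adapting_flag(self):
        assert not LossWeights(0.0, 0.0).adapting
        assert LossWeights(0.0, 0.5).adapting


class TestTotalLoss:
    def test_zero_gammas_reduce_to_cross_entropy(self, rng):
        src = tiny_epochs(rng)
        tgt = tiny_epochs(rng, labeled=False, subject=1)
        model = build_dcjnn(4, 32, TINY_NET, seed=1)
        scalar, comps = total_loss(src, tgt, model, LossWeights(0.0, 0.0))
        assert scalar == pytest.approx(comps["ce"])
        # oracle CE from the eval-mode probabilities
        probs = forward_predict(model, src.data)
        want = -np.mean(np.log(probs[np.arange(src.n_trials),
                                     src.labels] + 1e-30))
        assert comps["ce"] == pytest.approx(want, abs=1e-9)

    def test_identical_batches_zero_regularizers(self, rng):
        src = tiny_epochs(rng)
        tgt = EpochSet(data=src.data.copy(), labels=None,
                       subject_ids=np.full(src.n_trials, 1),
                       srate_hz=100.0, channel_names=src.channel_names,
                       class_names=src.class_names)
        model = build_dcjnn(4, 32, TINY_NET, seed=1)
        _, comps = total_loss(src, tgt, model, LossWeights(1.0, 1.0))
        assert comps["mmd_sq"] == pytest.approx(0.0, abs=1e-8)
        assert comps["jdd_sq"] == pytest.approx(0.0, abs=1e-8)

    def test_component_composition_matches_oracles(self, rng):
        """scalar = CE + gJ*JDD + gM*MMD with oracle discrepancy values."""
        src = tiny_epochs(rng)
        tgt = tiny_epochs(rng, labeled=False, subject=1)
        model = build_dcjnn(4, 32, TINY_NET, seed=2)
        weights = LossWeights(2.0, 0.5)
        scalar, comps = total_loss(src, tgt, model, weights)
        fs = forward_features(model, src.data)
        ft = forward_features(model, tgt.data)
        ps = forward_predict(model, src.data)
        pt = forward_predict(model, tgt.data)
        from deepjdd.trainer import _median_sigma
        from scipy.spatial.distance import cdist
        Zf = np.vstack([fs, ft])
        Zp = np.vstack([ps, pt])
        sx = _median_sigma(cdist(Zf, Zf, "sqeuclidean"))
        sy = _median_sigma(cdist(Zp, Zp, "sqeuclidean"), floor=0.1)
        bs = FeatureBatch(fs, ps)
        bt = FeatureBatch(ft, pt)
        mmd_oracle = mmd_sq(bs, bt, KernelConfig(bandwidth=sx))
        jdd_oracle = jdd_sq_bruteforce(bs, bt, KernelConfig(bandwidth=sx),
                                       KernelConfig(bandwidth=sy))
        assert comps["mmd_sq"] == pytest.approx(mmd_oracle, abs=1e-7)
        assert comps["jdd_sq"] == pytest.approx(jdd_oracle, abs=1e-7)
        assert scalar == pytest.approx(
            comps["ce"] + 2.0 * jdd_oracle + 0.5 * mmd_oracle, abs=1e-7)

    def test_target_order_invariance(self, rng):
        """Both discrepancies are set statistics of the target batch."""
        src = tiny_epochs(rng)
        tgt = tiny_epochs(rng, labeled=False, subject=1)
        model = build_dcjnn(4, 32, TINY_NET, seed=3)
        s1, _ = total_loss(src, tgt, model, LossWeights(1.0, 1.0))
        perm = np.random.default_rng(0).permutation(tgt.n_trials)
        s2, _ = total_loss(src, tgt.select(perm), model, LossWeights(1.0, 1.0))
        assert s1 == pytest.approx(s2, abs=1e-8)

    def test_unlabeled_source_rejected(self, rng):
        src = tiny_epochs(rng, labeled=False)
        model = build_dcjnn(4, 32, TINY_NET, seed=0)
        with pytest.raises(ValueError, match="labeled"):
            total_loss(src, None, model, LossWeights(0, 0))


class TestTrainStep:
    def test_loss_decreases_on_fixed_problem(self, rng):
        """Composite loss trends down over 50 steps on a small fixed task."""
        src = tiny_epochs(rng, n=16)
        tgt = tiny_epochs(rng, n=16, labeled=False, subject=1)
        # separable signal: class shifts the mean of channel 0
        src.data[src.labels == 1, 0, :] += 3.0
        model = build_dcjnn(4, 32, TINY_NET, seed=4)
        opt = AdamOptimizer(model.parameters(), lr=3e-3)
        rng_s, rng_t = (np.random.default_rng(k) for k in (10, 11))
        losses = []
        for _ in range(80):
            comps = train_step(model, src, tgt, LossWeights(0.1, 0.1), opt,
                               rng_s=rng_s, rng_t=rng_t)
            losses.append(comps["total"])
        smooth = np.convolve(losses, np.ones(10) / 10, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_non_finite_loss_aborts_with_components(self, rng):
        src = tiny_epochs(rng)
        model = build_dcjnn(4, 32, TINY_NET, seed=0)
        model.w6.data[:] = np.nan  # corrupted state must abort, not update
        opt = AdamOptimizer(model.parameters())
        with pytest.raises(FloatingPointError, match="ce"):
            train_step(model, src, None, LossWeights(0, 0), opt,
                       rng_s=np.random.default_rng(0))


class TestSupervisedReduction:
    def test_zero_gamma_transfer_is_bitwise_supervised(self, rng):
        """gamma_J = gamma_M = 0 reproduces the plain supervised run exactly."""
        src = tiny_epochs(rng, n=16)
        tgt = tiny_epochs(rng, n=8, labeled=False, subject=1)
        cfg = tiny_config(max_epochs=3, seed=5)
        m_sup, _ = train_supervised(src, cfg)
        m_tr, _ = train_transfer(src, tgt, LossWeights(0.0, 0.0), cfg)
        for pa, pb in zip(m_sup.parameters(), m_tr.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_seeded_determinism_of_transfer(self, rng):
        src = tiny_epochs(rng, n=16)
        tgt = tiny_epochs(rng, n=8, labeled=False, subject=1)
        cfg = tiny_config(seed=6)
        m1, t1 = train_transfer(src, tgt, LossWeights(1.0, 1.0), cfg)
        m2, t2 = train_transfer(src, tgt, LossWeights(1.0, 1.0), cfg)
        for pa, pb in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(pa.data, pb.data)
        assert t1.jdd_sq == t2.jdd_sq


class TestLeakageGuards:
    def test_labeled_target_refused(self, rng):
        src = tiny_epochs(rng)
        tgt = tiny_epochs(rng, subject=1)  # still labeled
        with pytest.raises(ValueError, match="label-free"):
            train_transfer(src, tgt, LossWeights(1, 1), tiny_config())

    def test_overlapping_subjects_refused(self, rng):
        src = tiny_epochs(rng, subject=0)
        tgt = tiny_epochs(rng, subject=0, labeled=False)
        with pytest.raises(ValueError, match="overlap"):
            train_transfer(src, tgt, LossWeights(1, 1), tiny_config())


class TestEvaluate:
    def test_perfect_and_chance_predictors(self, rng):
        src = tiny_epochs(rng, n=8)
        model = build_dcjnn(4, 32, TINY_NET, seed=0)
        acc, conf = evaluate(model, src)
        assert conf.sum() == 8
        assert 0.0 <= acc <= 1.0

    def test_accuracy_equals_mean_recall_when_balanced(self, rng):
        src = tiny_epochs(rng, n=20)
        model = build_dcjnn(4, 32, TINY_NET, seed=1)
        acc, conf = evaluate(model, src)
        recalls = np.diag(conf) / conf.sum(axis=1)
        assert acc == pytest.approx(recalls.mean())

    def test_unlabeled_rejected(self, rng):
        model = build_dcjnn(4, 32, TINY_NET, seed=0)
        with pytest.raises(ValueError):
            evaluate(model, tiny_epochs(rng, labeled=False))


class TestCrossValidation:
    def test_single_pair_grid_returned(self, rng):
        src = tiny_epochs(rng, n=20)
        cfg = tiny_config(max_epochs=1, gamma_grid=(0.5,), cv_folds=2)
        w = cross_validate_gammas(src, cfg)
        assert (w.gamma_J, w.gamma_M) == (0.5, 0.5)

    def test_selection_is_deterministic_and_on_grid(self, rng):
        src = tiny_epochs(rng, n=20)
        cfg = tiny_config(max_epochs=1, gamma_grid=(0.1, 1.0), cv_folds=2,
                          seed=9)
        w1 = cross_validate_gammas(src, cfg)
        w2 = cross_validate_gammas(src, cfg)
        assert (w1.gamma_J, w1.gamma_M) == (w2.gamma_J, w2.gamma_M)
        assert w1.gamma_J in cfg.gamma_grid
        assert w1.gamma_M in cfg.gamma_grid

    def test_default_grid_matches_protocol(self):
        assert GAMMA_GRID == (0.01, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0)

    def test_too_few_trials_per_class_rejected(self, rng):
        src = tiny_epochs(rng, n=4)
        with pytest.raises(ValueError, match="cv_folds"):
            cross_validate_gammas(src, tiny_config(cv_folds=5))


class TestLeaveOneSubjectOut:
    def test_one_row_per_subject_and_aggregates(self, rng):
        parts = [tiny_epochs(rng, n=12, subject=s) for s in range(3)]
        ds = EpochSet(data=np.concatenate([p.data for p in parts]),
                      labels=np.concatenate([p.labels for p in parts]),
                      subject_ids=np.concatenate([p.subject_ids
                                                  for p in parts]),
                      srate_hz=100.0, channel_names=parts[0].channel_names,
                      class_names=parts[0].class_names)
        table = leave_one_subject_out(ds, tiny_config(max_epochs=1),
                                      weights=LossWeights(0.1, 0.1))
        assert len(table) == 3
        assert set(table["subject"]) == {0, 1, 2}
        assert table.attrs["mean_accuracy"] == pytest.approx(
            table["accuracy"].mean())
        assert table.attrs["var_accuracy"] == pytest.approx(
            table["accuracy"].var(ddof=0))
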