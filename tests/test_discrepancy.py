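"""Kernel gram, W1, and the MMD/JDD estimators against explicit-sum oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepjdd import (FeatureBatch, KernelConfig, jdd_sq, jdd_sq_bruteforce,
                     median_bandwidth, mmd_sq, rbf_gram, weight_matrix_W1)
from deepjdd.discrepancy import DegenerateInputError, DiscrepancyResult

from conftest import random_batch_pair


class TestRbfGram:
    def test_single_point_self_similarity(self):
        g = rbf_gram([[2.0, 3.0]], [[2.0, 3.0]], KernelConfig(bandwidth=1.5))
        assert g.shape == (1, 1)
        assert g[0, 0] == pytest.approx(1.0)

    def test_closed_form_unit_bandwidth(self):
        g = rbf_gram([[0.0]], [[1.0]], KernelConfig(bandwidth=1.0))
        assert g[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_gram_is_psd_symmetric_unit_diag(self, rng):
        X = rng.standard_normal((5, 3))
        g = rbf_gram(X, X, KernelConfig(bandwidth=1.0))
        assert np.allclose(g, g.T)
        assert np.allclose(np.diag(g), 1.0)
        assert np.linalg.eigvalsh(g).min() >= -1e-10
        assert np.all((g > 0) & (g <= 1))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            rbf_gram(np.zeros((2, 3)), np.zeros((2, 4)), KernelConfig())

    def test_identical_points_degenerate_median(self):
        X = np.ones((4, 2))
        with pytest.raises(DegenerateInputError):
            rbf_gram(X, X, KernelConfig(bandwidth="median"))

    def test_median_heuristic_matches_pdist(self, rng):
        from scipy.spatial.distance import pdist
        X = rng.standard_normal((9, 4))
        assert median_bandwidth(X) == pytest.approx(np.median(pdist(X)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KernelConfig(kind="linear")
        with pytest.raises(ValueError):
            KernelConfig(bandwidth=0.0)
        with pytest.raises(ValueError):
            KernelConfig(bandwidth="mean")


class TestW1:
    @pytest.mark.parametrize("ns,nt", [(2, 2), (1, 5), (7, 3), (16, 16)])
    def test_block_structure_and_zero_sums(self, ns, nt):
        W = weight_matrix_W1(ns, nt)
        assert np.allclose(W[:ns, :ns], 1.0 / ns**2)
        assert np.allclose(W[ns:, ns:], 1.0 / nt**2)
        assert np.allclose(W[:ns, ns:], -1.0 / (ns * nt))
        assert np.allclose(W.sum(), 0.0)
        assert np.allclose(W.sum(axis=1), 0.0)
        assert np.linalg.matrix_rank(W) == 1

    def test_two_by_two_values(self):
        W = weight_matrix_W1(2, 2)
        assert np.allclose(W[:2, :2], 0.25)
        assert np.allclose(W[2:, 2:], 0.25)
        assert np.allclose(W[:2, 2:], -0.25)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            weight_matrix_W1(0, 3)


def mmd_sq_doublesum(src, tgt, sigma):
    """Literal three-term expansion of the squared MMD (oracle)."""
    def k(u, v):
        return np.exp(-np.sum((u - v) ** 2) / (2 * sigma**2))

    xs, xt = src.features, tgt.features
    ns, nt = len(xs), len(xt)
    ss = sum(k(xs[i], xs[j]) for i in range(ns) for j in range(ns))
    tt = sum(k(xt[i], xt[j]) for i in range(nt) for j in range(nt))
    st = sum(k(xs[i], xt[j]) for i in range(ns) for j in range(nt))
    return ss / ns**2 + tt / nt**2 - 2 * st / (ns * nt)


class TestMmd:
    def test_identical_batches_zero(self, rng):
        b = FeatureBatch(features=rng.standard_normal((6, 3)))
        assert abs(mmd_sq(b, b, KernelConfig(bandwidth=1.0))) < 1e-10

    def test_matches_doublesum_oracle(self, rng):
        for _ in range(50):
            ns, nt = rng.integers(2, 17, size=2)
            src, tgt = random_batch_pair(rng, ns, nt, d=3)
            sigma = float(rng.uniform(0.5, 3.0))
            got = mmd_sq(src, tgt, KernelConfig(bandwidth=sigma))
            want = mmd_sq_doublesum(src, tgt, sigma)
            assert got == pytest.approx(want, abs=1e-10)
            assert got >= -1e-10

    def test_symmetry(self, rng):
        src, tgt = random_batch_pair(rng, 5, 9)
        cfg = KernelConfig()
        assert mmd_sq(src, tgt, cfg) == pytest.approx(
            mmd_sq(tgt, src, cfg), abs=1e-10)

    def test_mean_shift_monotonicity(self):
        """E[MMD^2] grows with the separation of two 1-D Gaussians."""
        means = []
        for delta in (0.0, 1.0, 2.0):
            vals = []
            for seed in range(20):
                r = np.random.default_rng(1000 + seed)
                a = FeatureBatch(features=r.normal(0, 1, (200, 1)))
                b = FeatureBatch(features=r.normal(delta, 1, (200, 1)))
                vals.append(mmd_sq(a, b, KernelConfig(bandwidth=1.0)))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestJdd:
    def test_identical_joint_batches_zero(self, rng):
        src, _ = random_batch_pair(rng, 6, 6)
        assert abs(jdd_sq(src, src)) < 1e-10

    def test_matches_bruteforce_on_sweep(self, rng):
        for _ in range(50):
            ns, nt = rng.integers(2, 17, size=2)
            src, tgt = random_batch_pair(rng, ns, nt, d=2)
            kx = KernelConfig(bandwidth=float(rng.uniform(0.5, 2.0)))
            ky = KernelConfig(bandwidth=float(rng.uniform(0.5, 2.0)))
            got = jdd_sq(src, tgt, kx, ky)
            want = jdd_sq_bruteforce(src, tgt, kx, ky)
            assert got == pytest.approx(want, abs=1e-10)
            assert got >= -1e-10

    def test_constant_label_kernel_collapses_to_mmd(self, rng):
        src, tgt = random_batch_pair(rng, 8, 8)
        kx = KernelConfig(bandwidth=1.0)
        ky = KernelConfig(bandwidth=1e9)  # K_y -> all-ones
        assert jdd_sq(src, tgt, kx, ky) == pytest.approx(
            mmd_sq(src, tgt, kx), abs=1e-8)

    def test_symmetry(self, rng):
        src, tgt = random_batch_pair(rng, 4, 7)
        assert jdd_sq(src, tgt) == pytest.approx(jdd_sq(tgt, src), abs=1e-10)

    def test_label_permutation_increases_jdd(self):
        """Mismatched class-conditional structure raises the joint distance."""
        matched, permuted = [], []
        for seed in range(20):
            r = np.random.default_rng(2000 + seed)
            n = 40
            y = np.repeat([0, 1], n // 2)
            x = np.where(y[:, None] == 0, -2.0, 2.0) + r.normal(0, .5, (n, 1))
            onehot = np.eye(2)[y]
            src = FeatureBatch(features=x, soft_labels=onehot)
            tgt = FeatureBatch(features=x.copy(), soft_labels=onehot.copy())
            tgt_perm = FeatureBatch(features=x.copy(),
                                    soft_labels=onehot[:, ::-1].copy())
            kx, ky = KernelConfig(bandwidth=1.0), KernelConfig(bandwidth=0.5)
            matched.append(jdd_sq(src, tgt, kx, ky))
            permuted.append(jdd_sq(src, tgt_perm, kx, ky))
        assert np.mean(permuted) > np.mean(matched)

    def test_single_point_each_identical(self):
        b = FeatureBatch(features=[[1.0, 2.0]], soft_labels=[[0.3, 0.7]])
        assert abs(jdd_sq_bruteforce(b, b, KernelConfig(bandwidth=1.0),
                                     KernelConfig(bandwidth=1.0))) < 1e-12

    def test_unbiased_variant_drops_diagonal(self, rng):
        src, tgt = random_batch_pair(rng, 5, 5)
        kx = KernelConfig(bandwidth=1.0)
        ky = KernelConfig(bandwidth=1.0)
        v_stat = jdd_sq(src, tgt, kx, ky)
        u_stat = jdd_sq(src, tgt, kx, ky, unbiased=True)
        assert v_stat != pytest.approx(u_stat)  # diagonal terms differ

    def test_missing_labels_rejected(self, rng):
        a = FeatureBatch(features=rng.standard_normal((3, 2)))
        with pytest.raises(ValueError, match="soft labels"):
            jdd_sq(a, a)


class TestFeatureBatchValidation:
    def test_row_sum_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FeatureBatch(features=[[0.0]], soft_labels=[[0.6, 0.6]])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            FeatureBatch(features=[[np.nan]])

    def test_onehot_constructor(self):
        b = FeatureBatch.from_hard_labels(np.zeros((3, 2)), [0, 1, 1], 2)
        assert np.allclose(b.soft_labels, [[1, 0], [0, 1], [0, 1]])

    def test_result_invariant(self):
        with pytest.raises(ValueError):
            DiscrepancyResult(mmd_sq=-1.0, jdd_sq=0.0, ns=1, nt=1)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(ns=st.integers(1, 10), nt=st.integers(1, 10),
       seed=st.integers(0, 1000))
def test_nonnegativity_property(ns, nt, seed):
    """Both squared statistics are nonnegative on arbitrary batches."""
    r = np.random.default_rng(seed)
    src, tgt = random_batch_pair(r, ns, nt, d=2)
    cfg = KernelConfig(bandwidth=1.0)
    assert mmd_sq(src, tgt, cfg) >= -1e-10
    assert jdd_sq(src, tgt, cfg, cfg) >= -1e-10
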