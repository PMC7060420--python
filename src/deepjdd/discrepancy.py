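"""Kernel two-sample machinery: RBF grams, squared MMD and squared JDD.

The maximum mean discrepancy (MMD) compares the *marginal* feature
distributions of a source and a target sample through the distance between
their kernel mean embeddings.  The joint distribution discrepancy (JDD)
extends this to the *joint* distribution of (feature, predicted label) pairs
by embedding each sample with a tensor-product feature map ``phi(x) (x)
psi(y)`` and taking the Hilbert-Schmidt distance between the two joint
embeddings.  Both statistics reduce to quadratic forms in the kernel gram
matrices of the stacked source+target batch:

    MMD^2 = 1^T (K_x  o W1) 1
    JDD^2 = 1^T (K_x o K_y o W1) 1

where ``o`` is the Hadamard product and ``W1 = v v^T`` with
``v = [1/ns, ..., 1/ns, -1/nt, ..., -1/nt]``.

All kernels are Gaussian RBF, ``k(u, v) = exp(-||u - v||^2 / (2 sigma^2))``,
with the median pairwise-distance heuristic as the default bandwidth rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "KernelConfig",
    "FeatureBatch",
    "DiscrepancyResult",
    "rbf_gram",
    "median_bandwidth",
    "weight_matrix_W1",
    "mmd_sq",
    "jdd_sq",
    "jdd_sq_bruteforce",
    "discrepancy",
]


class DegenerateInputError(ValueError):
    """Raised when a sample set cannot support a positive kernel bandwidth."""


@dataclass(frozen=True)
class KernelConfig:
    """Specification of an RBF kernel.

    Parameters
    ----------
    kind:
        Kernel family; only ``"rbf"`` is supported.
    bandwidth:
        A positive number sigma, or the sentinel string ``"median"`` meaning
        the median of the pairwise Euclidean distances of whatever sample set
        the kernel is eventually evaluated on.
    """

    kind: str = "rbf"
    bandwidth: float | str = "median"

    def __post_init__(self) -> None:
        if self.kind != "rbf":
            raise ValueError(f"unsupported kernel kind {self.kind!r}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "median":
                raise ValueError(f"unknown bandwidth rule {self.bandwidth!r}")
        elif not (float(self.bandwidth) > 0):
            raise ValueError("numeric bandwidth must be > 0")

    def resolve(self, samples: np.ndarray) -> float:
        """Concrete sigma for ``samples`` (n x d)."""
        if not isinstance(self.bandwidth, str):
            return float(self.bandwidth)
        return median_bandwidth(samples)


def median_bandwidth(samples: np.ndarray) -> float:
    """Median pairwise Euclidean distance of ``samples`` (n x d).

    Raises
    ------
    DegenerateInputError
        If the median distance is zero (all points identical) so no positive
        bandwidth can be resolved.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be a 2-D array")
    if samples.shape[0] < 2:
        # a single point has no pairwise distance; fall back to unit scale
        return 1.0
    d = pdist(samples)
    med = float(np.median(d))
    if med <= 0.0:
        # duplicate-heavy samples: take the median of the positive distances
        pos = d[d > 0]
        if pos.size == 0:
            raise DegenerateInputError(
                "all points identical; cannot resolve RBF bandwidth")
        med = float(np.median(pos))
    return med


@dataclass
class FeatureBatch:
    """A batch of network outputs entering the discrepancy estimators.

    ``features`` are the flatten-layer activations (n x d) and
    ``soft_labels`` the softmax outputs (n x N, rows on the simplex).
    """

    features: np.ndarray
    soft_labels: np.ndarray | None = None
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be n x d")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite entries")
        self.n = self.features.shape[0]
        if self.n < 1:
            raise ValueError("empty batch")
        if self.soft_labels is not None:
            self.soft_labels = np.asarray(self.soft_labels, dtype=float)
            if self.soft_labels.shape[0] != self.n:
                raise ValueError("soft_labels row count != features row count")
            if not np.all(np.isfinite(self.soft_labels)):
                raise ValueError("soft_labels contain non-finite entries")
            if np.any(self.soft_labels < -1e-9):
                raise ValueError("soft_labels must be nonnegative")
            rowsum = self.soft_labels.sum(axis=1)
            if np.any(np.abs(rowsum - 1.0) > 1e-6):
                raise ValueError("soft_labels rows must sum to 1 (within 1e-6)")

    @staticmethod
    def from_hard_labels(features: np.ndarray, labels: np.ndarray,
                         n_classes: int) -> "FeatureBatch":
        """One-hot encode integer ``labels`` as soft labels (source ablation)."""
        labels = np.asarray(labels, dtype=int)
        onehot = np.zeros((labels.shape[0], n_classes))
        onehot[np.arange(labels.shape[0]), labels] = 1.0
        return FeatureBatch(features=features, soft_labels=onehot)


@dataclass(frozen=True)
class DiscrepancyResult:
    """Squared MMD and squared JDD for one source/target batch pair."""

    mmd_sq: float
    jdd_sq: float
    ns: int
    nt: int

    def __post_init__(self) -> None:
        if self.mmd_sq < -1e-10 or self.jdd_sq < -1e-10:
            raise ValueError("squared discrepancies must be nonnegative")


def rbf_gram(X: np.ndarray, Y: np.ndarray, config: KernelConfig) -> np.ndarray:
    """RBF gram matrix k(x_i, y_j) between two point sets.

    A ``"median"`` bandwidth is resolved on the stacked rows of X and Y.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"dimension mismatch: X has d={X.shape[1]}, Y has d={Y.shape[1]}"
        )
    sigma = config.resolve(np.vstack([X, Y]))
    d2 = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma * sigma))


def weight_matrix_W1(ns: int, nt: int) -> np.ndarray:
    """Rank-1 signed weight matrix ``v v^T`` used by both quadratic forms.

    ``v`` holds 1/ns for the ns source rows and -1/nt for the nt target rows,
    so every row of W1 sums to zero and the total sum is zero.
    """
    if ns < 1 or nt < 1:
        raise ValueError("ns and nt must be positive")
    v = np.concatenate([np.full(ns, 1.0 / ns), np.full(nt, -1.0 / nt)])
    return np.outer(v, v)


def _stacked_gram(source: np.ndarray, target: np.ndarray,
                  config: KernelConfig) -> np.ndarray:
    Z = np.vstack([source, target])
    sigma = config.resolve(Z)
    d2 = cdist(Z, Z, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma * sigma))


def _quadratic_form(K: np.ndarray, ns: int, nt: int, unbiased: bool) -> float:
    W1 = weight_matrix_W1(ns, nt)
    M = K * W1
    if unbiased:
        # U-statistic variant: drop the i=j terms of the two within-domain
        # sums and renormalise them to 1/(n(n-1)).
        ss = (M[:ns, :ns].sum() - np.trace(M[:ns, :ns])) * ns / max(ns - 1, 1)
        tt = (M[ns:, ns:].sum() - np.trace(M[ns:, ns:])) * nt / max(nt - 1, 1)
        cross = M[:ns, ns:].sum() + M[ns:, :ns].sum()
        return float(ss + tt + cross)
    return float(M.sum())


def mmd_sq(source: FeatureBatch, target: FeatureBatch,
           config: KernelConfig | None = None, *,
           unbiased: bool = False) -> float:
    """Squared empirical MMD between the two feature batches.

    Computed as ``1^T (K_x o W1) 1`` on the stacked gram; identical batches
    give exactly zero up to float error.
    """
    config = config or KernelConfig()
    if source.features.shape[1] != target.features.shape[1]:
        raise ValueError("feature dimension mismatch between batches")
    K = _stacked_gram(source.features, target.features, config)
    return _quadratic_form(K, source.n, target.n, unbiased)


def jdd_sq(source: FeatureBatch, target: FeatureBatch,
           kx: KernelConfig | None = None, ky: KernelConfig | None = None, *,
           unbiased: bool = False) -> float:
    """Squared empirical JDD between the two (feature, soft-label) batches.

    Computed as ``1^T (K_x o K_y o W1) 1``; with a constant label kernel it
    collapses to ``mmd_sq`` on the same features.
    """
    kx = kx or KernelConfig()
    ky = ky or KernelConfig()
    if source.soft_labels is None or target.soft_labels is None:
        raise ValueError("jdd_sq requires soft labels on both batches")
    if source.features.shape[1] != target.features.shape[1]:
        raise ValueError("feature dimension mismatch between batches")
    if source.soft_labels.shape[1] != target.soft_labels.shape[1]:
        raise ValueError("label dimension mismatch between batches")
    Kx = _stacked_gram(source.features, target.features, kx)
    Ky = _stacked_gram(source.soft_labels, target.soft_labels, ky)
    return _quadratic_form(Kx * Ky, source.n, target.n, unbiased)


def jdd_sq_bruteforce(source: FeatureBatch, target: FeatureBatch,
                      kx: KernelConfig | None = None,
                      ky: KernelConfig | None = None) -> float:
    """Literal three-term double-sum JDD^2 estimator (independent oracle).

    O((ns+nt)^2) explicit Python loops with no Hadamard/matrix shortcut;
    kept deliberately naive so it can cross-check :func:`jdd_sq`.
    """
    kx = kx or KernelConfig()
    ky = ky or KernelConfig()
    if source.soft_labels is None or target.soft_labels is None:
        raise ValueError("jdd_sq_bruteforce requires soft labels")
    xs, ys = source.features, source.soft_labels
    xt, yt = target.features, target.soft_labels
    sx = kx.resolve(np.vstack([xs, xt]))
    sy = ky.resolve(np.vstack([ys, yt]))

    def k1(u, v):
        return float(np.exp(-np.sum((u - v) ** 2) / (2.0 * sx * sx)))

    def k2(u, v):
        return float(np.exp(-np.sum((u - v) ** 2) / (2.0 * sy * sy)))

    ns, nt = source.n, target.n
    ss = sum(k1(xs[i], xs[j]) * k2(ys[i], ys[j])
             for i in range(ns) for j in range(ns))
    tt = sum(k1(xt[i], xt[j]) * k2(yt[i], yt[j])
             for i in range(nt) for j in range(nt))
    st = sum(k1(xs[i], xt[j]) * k2(ys[i], yt[j])
             for i in range(ns) for j in range(nt))
    return ss / ns**2 + tt / nt**2 - 2.0 * st / (ns * nt)


def discrepancy(source: FeatureBatch, target: FeatureBatch,
                kx: KernelConfig | None = None,
                ky: KernelConfig | None = None) -> DiscrepancyResult:
    """Both statistics for one source/target batch pair."""
    m = mmd_sq(source, target, kx)
    j = jdd_sq(source, target, kx, ky)
    return DiscrepancyResult(mmd_sq=m, jdd_sq=j, ns=source.n, nt=target.n)
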