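"""Training with joint distribution matching.

The objective is the composite loss

    L = CE(source) + gamma_J * JDD^2(source, target) + gamma_M * MMD^2(source, target)

where both discrepancies are computed between the flatten-layer features
(and, for JDD, the softmax outputs) of a labeled source batch and an
*unlabeled* target batch flowing through the current network.  Each step
performs one source forward, one target forward with the same weights (no
update in between), and a single Adam update from the composite gradient.

Target labels never enter training: :func:`train_transfer` refuses a labeled
target set, and accuracy monitoring uses a separate argument that only feeds
the per-epoch trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._autodiff import Tensor, concat
from .dcjnn import DCJNN, NetworkSpec, build_dcjnn, forward_predict
from .discrepancy import weight_matrix_W1
from .preprocess import EpochSet, remove_epoch_mean

__all__ = [
    "LossWeights",
    "TrainConfig",
    "TrainTrace",
    "total_loss",
    "train_step",
    "train_supervised",
    "train_transfer",
    "cross_validate_gammas",
    "evaluate",
    "leave_one_subject_out",
    "AdamOptimizer",
]

GAMMA_GRID = (0.01, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class LossWeights:
    """Trade-off weights for the JDD and MMD regularisers."""

    gamma_J: float = 1.0
    gamma_M: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_J < 0 or self.gamma_M < 0:
            raise ValueError("gamma weights must be nonnegative")

    @property
    def adapting(self) -> bool:
        return self.gamma_J > 0 or self.gamma_M > 0


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 200
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    cv_folds: int = 5
    seed: int = 0
    gamma_grid: tuple[float, ...] = GAMMA_GRID
    network: NetworkSpec | None = None
    dtype: str = "float64"  # "float32" roughly halves training time
    # The adaptation terms engage only after the source cross-entropy first
    # drops below ce_gate (the classifier has escaped its initial plateau),
    # then ramp linearly to their nominal weights over gamma_warmup_frac of
    # max_epochs.  Aligning domains before any class structure exists lets
    # the discrepancy terms collapse the features to a trivial common
    # embedding; gating prevents that at short training budgets.  ce_gate
    # >= ln(n_classes) disables the gate, gamma_warmup_frac = 0 the ramp.
    ce_gate: float = 0.6
    gamma_warmup_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class TrainTrace:
    """Per-epoch loss components and (optionally) monitored target accuracy."""

    epoch: list[int] = field(default_factory=list)
    source_ce_loss: list[float] = field(default_factory=list)
    mmd_sq: list[float] = field(default_factory=list)
    jdd_sq: list[float] = field(default_factory=list)
    target_accuracy: list[float] = field(default_factory=list)

    def append(self, epoch: int, ce: float, mmd: float, jdd: float,
               acc: float = float("nan")) -> None:
        if not all(math.isfinite(v) for v in (ce, mmd, jdd)):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: ce={ce} mmd={mmd} jdd={jdd}")
        self.epoch.append(epoch)
        self.source_ce_loss.append(ce)
        self.mmd_sq.append(mmd)
        self.jdd_sq.append(jdd)
        self.target_accuracy.append(acc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epoch, "ce": self.source_ce_loss,
            "mmd_sq": self.mmd_sq, "jdd_sq": self.jdd_sq,
            "target_acc": self.target_accuracy,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class AdamOptimizer:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# differentiable discrepancy terms


def _median_sigma(D: np.ndarray, floor: float = 1e-3) -> float:
    """Median pairwise distance from a squared-distance matrix (detached).

    The floor guards against near-coincident batches (e.g. softmax outputs
    early in training) whose median distance would otherwise drive the
    kernel exponent to numerically meaningless magnitudes.
    """
    iu = np.triu_indices(D.shape[0], k=1)
    med = float(np.median(np.sqrt(np.maximum(D[iu], 0.0))))
    return max(med, floor)


def _sq_dists(Z: Tensor) -> Tensor:
    r = (Z * Z).sum(axis=1, keepdims=True)
    # clamp at 0: float cancellation may leave tiny negatives that would
    # blow up once divided by a small bandwidth
    return (r + r.T - 2.0 * (Z @ Z.T)).relu()


def _gram(Z: Tensor, floor: float = 1e-3) -> Tensor:
    D = _sq_dists(Z)
    sigma = _median_sigma(D.data, floor)
    return (D * (-1.0 / (2.0 * sigma * sigma))).exp()


def _discrepancy_terms(feats_s: Tensor, feats_t: Tensor, probs_s: Tensor,
                       probs_t: Tensor) -> tuple[Tensor, Tensor]:
    """(mmd_sq, jdd_sq) as differentiable quadratic forms 1ᵀ(K∘W1)1."""
    ns, nt = feats_s.shape[0], feats_t.shape[0]
    W1 = Tensor(weight_matrix_W1(ns, nt))
    Kx = _gram(concat([feats_s, feats_t], axis=0))
    # label vectors live on the probability simplex (diameter sqrt(2)); a
    # higher floor keeps the label kernel informative near-uniform outputs
    Ky = _gram(concat([probs_s, probs_t], axis=0), floor=0.1)
    mmd = (Kx * W1).sum()
    jdd = (Kx * Ky * W1).sum()
    return mmd, jdd


def _cross_entropy(probs: Tensor, labels: np.ndarray, n_classes: int) -> Tensor:
    onehot = np.zeros((labels.shape[0], n_classes))
    onehot[np.arange(labels.shape[0]), labels] = 1.0
    # tiny floor keeps 0 * log(0) out of the off-class terms
    return -(Tensor(onehot) * (probs + 1e-30).log()).sum(axis=1).mean()


# ---------------------------------------------------------------------------
# loss and steps


def _composite_loss(model: DCJNN, xs: np.ndarray, ys: np.ndarray,
                    xt: np.ndarray | None, weights: LossWeights, *,
                    train: bool,
                    rng_s: np.random.Generator | None = None,
                    rng_t: np.random.Generator | None = None,
                    ) -> tuple[Tensor, dict[str, float]]:
    feats_s, probs_s = model.forward(xs, train=train, rng=rng_s,
                                     update_bn=True)
    ce = _cross_entropy(probs_s, ys, model.spec.n_classes)
    if xt is None:
        comps = {"ce": float(ce.data), "mmd_sq": 0.0, "jdd_sq": 0.0}
        return ce, comps
    feats_t, probs_t = model.forward(xt, train=train, rng=rng_t,
                                     update_bn=False)
    mmd, jdd = _discrepancy_terms(feats_s, feats_t, probs_s, probs_t)
    loss = ce
    if weights.gamma_J > 0:
        loss = loss + weights.gamma_J * jdd
    if weights.gamma_M > 0:
        loss = loss + weights.gamma_M * mmd
    comps = {"ce": float(ce.data), "mmd_sq": float(mmd.data),
             "jdd_sq": float(jdd.data)}
    return loss, comps


def total_loss(source_batch: EpochSet, target_batch: EpochSet | None,
               model: DCJNN, weights: LossWeights,
               ) -> tuple[float, dict[str, float]]:
    """Composite loss for inspection (deterministic eval-mode forwards).

    Returns ``(scalar, components)`` with components keyed ``ce``,
    ``mmd_sq``, ``jdd_sq``.  Both discrepancies are set statistics of the
    two batches, so they are invariant to trial order.
    """
    if source_batch.labels is None:
        raise ValueError("source batch must be labeled")
    if source_batch.n_trials == 0 or (
            target_batch is not None and target_batch.n_trials == 0):
        raise ValueError("empty batch")
    xt = None if target_batch is None else target_batch.data
    loss, comps = _composite_loss(model, source_batch.data,
                                  source_batch.labels, xt, weights,
                                  train=False)
    scalar = (comps["ce"] + weights.gamma_J * comps["jdd_sq"]
              + weights.gamma_M * comps["mmd_sq"])
    return scalar, comps


def train_step(model: DCJNN, source_batch: EpochSet, target_batch: EpochSet | None,
               weights: LossWeights, optimizer: AdamOptimizer, *,
               rng_s: np.random.Generator | None = None,
               rng_t: np.random.Generator | None = None,
               ) -> dict[str, float]:
    """One composite-loss parameter update.

    The source and target forwards share the same (frozen) weights; the
    single Adam update happens only after both passes, from the gradient of
    the full composite loss through both branches.
    """
    if source_batch.labels is None:
        raise ValueError("source batch must be labeled")
    xt = None if target_batch is None else target_batch.data
    loss, comps = _composite_loss(model, source_batch.data,
                                  source_batch.labels, xt, weights,
                                  train=True, rng_s=rng_s, rng_t=rng_t)
    if not np.isfinite(loss.data):
        raise FloatingPointError(f"non-finite composite loss: {comps}")
    model.zero_grad()
    loss.backward()
    optimizer.step()
    comps["total"] = float(loss.data)
    return comps


# ---------------------------------------------------------------------------
# full training loops


def _prep(epochs: EpochSet) -> EpochSet:
    # per-trial channel mean removal, as applied before spatial filtering
    return remove_epoch_mean(epochs)


def _train_loop(source: EpochSet, target: EpochSet | None,
                weights: LossWeights, config: TrainConfig, *,
                monitor_labels: np.ndarray | None = None,
                ) -> tuple[DCJNN, TrainTrace]:
    source = _prep(source)
    use_target = target is not None and weights.adapting
    if use_target:
        target = _prep(target)
    ch, T = source.n_channels, source.n_times
    spec = config.network or NetworkSpec(
        n_classes=len(source.class_names) or int(source.labels.max()) + 1)
    model = build_dcjnn(ch, T, spec, seed=config.seed,
                        dtype=np.dtype(config.dtype))
    optimizer = AdamOptimizer(model.parameters(), lr=config.learning_rate)
    rng_train = np.random.default_rng(config.seed + 1)
    rng_target = np.random.default_rng(config.seed + 2)
    ns = source.n_trials
    ba = config.batch_size
    steps = math.ceil(ns / ba)
    trace = TrainTrace()
    warmup = int(round(config.gamma_warmup_frac * config.max_epochs))
    gate_epoch: int | None = None
    for epoch in range(config.max_epochs):
        if gate_epoch is None:
            ramp = 0.0
        elif warmup <= 0:
            ramp = 1.0
        else:
            ramp = min(1.0, (epoch - gate_epoch + 1) / warmup)
        eff = LossWeights(weights.gamma_J * ramp, weights.gamma_M * ramp)
        perm = rng_train.permutation(ns)
        ce_sum = mmd_sum = jdd_sum = 0.0
        for s in range(steps):
            idx = perm[s * ba:(s + 1) * ba]
            if idx.size < 2:
                continue  # BN needs at least two samples
            sb = source.select(idx)
            tb = None
            if use_target:
                tidx = rng_target.choice(target.n_trials,
                                         size=min(ba, target.n_trials),
                                         replace=False)
                tb = target.select(tidx)
            comps = train_step(model, sb, tb, eff, optimizer,
                               rng_s=rng_train, rng_t=rng_target)
            ce_sum += comps["ce"]
            mmd_sum += comps["mmd_sq"]
            jdd_sum += comps["jdd_sq"]
        if gate_epoch is None and ce_sum / steps < config.ce_gate:
            gate_epoch = epoch + 1  # regularisers engage next epoch
        acc = float("nan")
        if monitor_labels is not None and target is not None:
            acc, _ = evaluate(model, EpochSet(
                data=target.data, labels=monitor_labels,
                subject_ids=target.subject_ids, srate_hz=target.srate_hz,
                channel_names=target.channel_names,
                class_names=source.class_names))
        trace.append(epoch, ce_sum / steps, mmd_sum / steps,
                     jdd_sum / steps, acc)
    return model, trace


def train_supervised(source: EpochSet, config: TrainConfig,
                     ) -> tuple[DCJNN, TrainTrace]:
    """Plain supervised training on the labeled source set alone."""
    if source.labels is None:
        raise ValueError("source must be labeled")
    return _train_loop(source, None, LossWeights(0.0, 0.0), config)


def train_transfer(source: EpochSet, target: EpochSet,
                   weights: LossWeights, config: TrainConfig, *,
                   monitor_labels: np.ndarray | None = None,
                   ) -> tuple[DCJNN, TrainTrace]:
    """Adaptation training: labeled source, unlabeled target.

    ``target`` must carry no labels (pass ``EpochSet.without_labels()``);
    ``monitor_labels`` may supply held-back target labels purely for the
    per-epoch accuracy trace — they never influence any update.
    Subjects of the two sets must be disjoint.
    """
    if source.labels is None:
        raise ValueError("source must be labeled")
    if target.labels is not None:
        raise ValueError(
            "target must enter training label-free; use without_labels()")
    overlap = set(np.unique(source.subject_ids)) & \
        set(np.unique(target.subject_ids))
    if overlap:
        raise ValueError(f"source/target subjects overlap (leakage): {overlap}")
    return _train_loop(source, target, weights, config,
                       monitor_labels=monitor_labels)


def evaluate(model: DCJNN, labeled: EpochSet,
             chunk: int = 64) -> tuple[float, np.ndarray]:
    """Eval-mode accuracy and per-class confusion counts.

    Returns ``(accuracy, confusion)`` where ``confusion[i, j]`` counts
    trials of true class i predicted as class j.
    """
    if labeled.labels is None:
        raise ValueError("evaluation requires labels")
    data = remove_epoch_mean(labeled).data
    n = data.shape[0]
    preds = np.empty(n, dtype=int)
    for a in range(0, n, chunk):
        preds[a:a + chunk] = forward_predict(
            model, data[a:a + chunk]).argmax(axis=1)
    N = model.spec.n_classes
    conf = np.zeros((N, N), dtype=int)
    for t, p in zip(labeled.labels, preds):
        conf[t, p] += 1
    return float((preds == labeled.labels).mean()), conf


def cross_validate_gammas(source: EpochSet, config: TrainConfig, *,
                          search: str = "joint",
                          ) -> LossWeights:
    """Pick (gamma_J, gamma_M) from the grid by 5-fold source CV.

    Each fold plays the target role: the network trains on the remaining
    folds with the held-out fold entering label-free through the adaptation
    losses, and the held-out *source* accuracy is the selection metric
    (target labels being unavailable by construction).  Ties break toward
    the earliest grid pair.  ``search="coordinate"`` first scans gamma_J
    with gamma_M=0, then gamma_M at the chosen gamma_J.
    """
    if source.labels is None:
        raise ValueError("CV requires a labeled source")
    grid = tuple(config.gamma_grid)
    if not grid:
        raise ValueError("empty gamma grid")
    counts = np.bincount(source.labels)
    if counts.min() < config.cv_folds:
        raise ValueError("need >= cv_folds trials per class")

    def score(weights: LossWeights) -> float:
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                              random_state=config.seed)
        accs = []
        for tr_idx, va_idx in skf.split(source.data, source.labels):
            tr, va = source.select(tr_idx), source.select(va_idx)
            model, _ = _train_loop(tr, va.without_labels(), weights, config)
            acc, _ = evaluate(model, va)
            accs.append(acc)
        return float(np.mean(accs))

    if search == "coordinate":
        best_j = max(grid, key=lambda gj: (score(LossWeights(gj, 0.0)),
                                           -grid.index(gj)))
        best_m = max(grid, key=lambda gm: (score(LossWeights(best_j, gm)),
                                           -grid.index(gm)))
        return LossWeights(best_j, best_m)
    if search != "joint":
        raise ValueError("search must be 'joint' or 'coordinate'")
    pairs = list(product(grid, grid))
    scores = [score(LossWeights(gj, gm)) for gj, gm in pairs]
    best = int(np.argmax(scores))  # argmax takes the first maximum
    return LossWeights(*pairs[best])


def leave_one_subject_out(dataset: EpochSet, config: TrainConfig, *,
                          weights: LossWeights | None = None,
                          select_gammas: bool = False,
                          ) -> pd.DataFrame:
    """Hold out each subject in turn as the unlabeled target.

    The held-out subject's labels are used only for the final accuracy; with
    ``select_gammas=True`` the trade-off weights are re-chosen per split by
    source-only cross-validation.
    """
    if dataset.labels is None:
        raise ValueError("dataset must be labeled")
    rows = []
    for subj in np.unique(dataset.subject_ids):
        t_mask = dataset.subject_ids == subj
        target = dataset.select(t_mask)
        source = dataset.select(~t_mask)
        w = weights or LossWeights()
        if select_gammas:
            w = cross_validate_gammas(source, config)
        model, _ = train_transfer(source, target.without_labels(), w, config)
        acc, conf = evaluate(model, target)
        rows.append({"subject": subj, "accuracy": acc,
                     "n_trials": int(t_mask.sum()),
                     "gamma_J": w.gamma_J, "gamma_M": w.gamma_M})
    frame = pd.DataFrame(rows)
    frame.attrs["mean_accuracy"] = float(frame["accuracy"].mean())
    frame.attrs["var_accuracy"] = float(frame["accuracy"].var(ddof=0))
    return frame
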