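"""The deep CSP-like joint-adaptation network (DCJNN).

Six-layer architecture for epoched EEG (trials x channels x time):

1. bank of 32 temporal convolutions (length 16, same padding) applied to
   every channel -> 32 x ch x T; batch-norm, activation, dropout(0.2);
2. depthwise spatial convolution: one ch-length filter per temporal map
   (the learned analogue of a CSP spatial filter) -> 32 x 1 x T;
   batch-norm, activation, transpose to 1 x 32 x T, dropout(0.2);
3. 16 x Conv2D (2 x 16), batch-norm, activation, maxpool (2, 4);
4. 4 x Conv2D (2 x 16), batch-norm, activation, maxpool (2, 8);
5. flatten (the feature tap for the MMD/JDD losses and all diagnostics);
6. dense softmax head over N classes.

The default activation is the softplus ln(1 + e^x); a conventional ReLU is
available via ``NetworkSpec(activation="relu")``.  All randomness
(initialisation, dropout) is driven by explicit numpy generators so builds
and eval-mode forwards are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, batchnorm, conv2d, maxpool2d

__all__ = [
    "NetworkSpec",
    "LayerShapePlan",
    "shape_plan",
    "build_dcjnn",
    "forward_features",
    "forward_predict",
    "activation",
    "spatial_filter_weights",
    "DCJNN",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters (counts, kernel/pool sizes, dropout)."""

    n_temporal: int = 32
    temporal_len: int = 16
    n_spatial: int = 32
    conv3_maps: int = 16
    conv3_kernel: tuple[int, int] = (2, 16)
    pool3: tuple[int, int] = (2, 4)
    conv4_maps: int = 4
    conv4_kernel: tuple[int, int] = (2, 16)
    pool4: tuple[int, int] = (2, 8)
    dropout_p: float = 0.2
    n_classes: int = 2
    activation: str = "softplus_as_printed"
    spatial_depthwise: bool = True

    def __post_init__(self) -> None:
        counts = (self.n_temporal, self.temporal_len, self.n_spatial,
                  self.conv3_maps, self.conv4_maps, self.n_classes)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.activation not in ("softplus_as_printed", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.spatial_depthwise and self.n_spatial != self.n_temporal:
            raise ValueError("depthwise spatial layer requires "
                             "n_spatial == n_temporal")


@dataclass(frozen=True)
class LayerShapePlan:
    """Ordered (layer name, output shape) pairs, excluding the batch axis."""

    layers: tuple[tuple[str, tuple[int, ...]], ...]

    def shape_of(self, name: str) -> tuple[int, ...]:
        for n, s in self.layers:
            if n == name:
                return s
        raise KeyError(name)

    @property
    def flatten_width(self) -> int:
        return self.shape_of("flatten")[0]


def shape_plan(ch: int, T: int, spec: NetworkSpec | None = None) -> LayerShapePlan:
    """Deduce every layer's output shape for a ch x T input.

    Pooling is non-overlapping with floor division, so for T divisible by 32
    the time widths follow T, T/4, T/32 and the flatten width is
    4*8*(T/32) with the default spec.
    """
    spec = spec or NetworkSpec()
    if ch < 1:
        raise ValueError("ch must be >= 1")
    if T < spec.temporal_len:
        raise ValueError(f"T={T} shorter than temporal kernel "
                         f"{spec.temporal_len}")
    h3 = spec.n_spatial // spec.pool3[0]
    w3 = T // spec.pool3[1]
    if h3 < 1 or w3 < 1:
        raise ValueError("input too short for stage-3 pooling")
    h4 = h3 // spec.pool4[0]
    w4 = w3 // spec.pool4[1]
    if h4 < 1 or w4 < 1:
        raise ValueError("input too short for stage-4 pooling")
    flat = spec.conv4_maps * h4 * w4
    layers = (
        ("temporal_conv", (spec.n_temporal, ch, T)),
        ("spatial_conv", (spec.n_temporal, 1, T)),
        ("transpose", (1, spec.n_spatial, T)),
        ("conv3", (spec.conv3_maps, spec.n_spatial, T)),
        ("pool3", (spec.conv3_maps, h3, w3)),
        ("conv4", (spec.conv4_maps, h3, w3)),
        ("pool4", (spec.conv4_maps, h4, w4)),
        ("flatten", (flat,)),
        ("softmax", (spec.n_classes,)),
    )
    return LayerShapePlan(layers=layers)


def activation(x, mode: str = "softplus_as_printed"):
    """Scalar/array activation: ln(1+e^x) (as printed) or max(0, x)."""
    arr = np.asarray(x, dtype=float)
    if mode == "softplus_as_printed":
        out = np.maximum(arr, 0.0) + np.log1p(np.exp(-np.abs(arr)))
    elif mode == "relu":
        out = np.maximum(arr, 0.0)
    else:
        raise ValueError(f"unknown activation mode {mode!r}")
    return out if out.ndim else float(out)


class _BatchNorm:
    """Per-map batch normalisation with source-only running statistics."""

    def __init__(self, n_maps: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float64):
        self.gamma = Tensor(np.ones(n_maps, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(n_maps, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(n_maps, dtype=dtype)
        self.running_var = np.ones(n_maps, dtype=dtype)
        self.eps = eps
        self.momentum = momentum

    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, train: bool, update_running: bool) -> Tensor:
        # x: (batch, maps, H, W); normalise over (batch, H, W)
        axes = (0, 2, 3)
        if train:
            out, mu, var = batchnorm(x, self.gamma, self.beta, axes,
                                     eps=self.eps)
            if update_running:
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean
                                     + m * mu).astype(self.running_mean.dtype)
                self.running_var = ((1 - m) * self.running_var
                                    + m * var).astype(self.running_var.dtype)
            return out
        rm = self.running_mean[None, :, None, None]
        rv = self.running_var[None, :, None, None]
        xhat = (x - rm) * (1.0 / np.sqrt(rv + self.eps)).astype(rv.dtype)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class DCJNN:
    """Parameterised model handle; see module docstring for the layer plan.

    ``dtype`` selects the arithmetic precision of parameters and
    activations; float64 is the default, float32 roughly halves training
    time and memory at benchmark scale.
    """

    def __init__(self, ch: int, T: int, spec: NetworkSpec, seed: int,
                 dtype=np.float64):
        self.ch = ch
        self.T = T
        self.spec = spec
        self.dtype = np.dtype(dtype)
        self.plan = shape_plan(ch, T, spec)
        rng = np.random.default_rng(seed)

        def init(shape, fan_in):
            lim = np.sqrt(1.0 / fan_in)
            return Tensor(rng.uniform(-lim, lim,
                                      size=shape).astype(self.dtype),
                          requires_grad=True)

        s = spec
        # layer 1: temporal conv bank, kernel (1, temporal_len), 1 input map
        self.w1 = init((s.n_temporal, 1, 1, s.temporal_len), s.temporal_len)
        self.b1 = Tensor(np.zeros(s.n_temporal, dtype=self.dtype),
                         requires_grad=True)
        self.bn1 = _BatchNorm(s.n_temporal, dtype=self.dtype)
        # layer 2: spatial filters over channels
        if s.spatial_depthwise:
            self.w2 = init((s.n_temporal, ch), ch)  # one ch-vector per map
        else:
            self.w2 = init((s.n_spatial, s.n_temporal, ch), s.n_temporal * ch)
        self.b2 = Tensor(np.zeros(s.n_spatial, dtype=self.dtype),
                         requires_grad=True)
        self.bn2 = _BatchNorm(s.n_spatial, dtype=self.dtype)
        # layers 3/4: 2-D conv stages
        k3h, k3w = s.conv3_kernel
        self.w3 = init((s.conv3_maps, 1, k3h, k3w), k3h * k3w)
        self.b3 = Tensor(np.zeros(s.conv3_maps, dtype=self.dtype),
                         requires_grad=True)
        self.bn3 = _BatchNorm(s.conv3_maps, dtype=self.dtype)
        k4h, k4w = s.conv4_kernel
        self.w4 = init((s.conv4_maps, s.conv3_maps, k4h, k4w),
                       s.conv3_maps * k4h * k4w)
        self.b4 = Tensor(np.zeros(s.conv4_maps, dtype=self.dtype),
                         requires_grad=True)
        # batch-norm ahead of the stage-4 activation: without it every map
        # whose kernel sums negative is dead for all-nonnegative pool-3
        # inputs, and all four maps die together with probability 1/16
        self.bn4 = _BatchNorm(s.conv4_maps, dtype=self.dtype)
        # layer 6: softmax regression head
        flat = self.plan.flatten_width
        self.w6 = init((flat, s.n_classes), flat)
        self.b6 = Tensor(np.zeros(s.n_classes, dtype=self.dtype),
                         requires_grad=True)

    # ------------------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        ps = [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3,
              self.w4, self.b4, self.w6, self.b6]
        for bn in (self.bn1, self.bn2, self.bn3, self.bn4):
            ps.extend(bn.params())
        return ps

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def _act(self, x: Tensor) -> Tensor:
        if self.spec.activation == "relu":
            return x.relu()
        return x.softplus()

    def _dropout(self, x: Tensor, train: bool,
                 rng: np.random.Generator | None) -> Tensor:
        p = self.spec.dropout_p
        if not train or p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode forward requires an rng")
        u = rng.random(x.shape, dtype=np.float32) if \
            x.data.dtype == np.float32 else rng.random(x.shape)
        mask = (u >= p).astype(x.data.dtype) * (1.0 / (1.0 - p))
        return x * mask

    def forward(self, batch: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None,
                update_bn: bool = True) -> tuple[Tensor, Tensor]:
        """Run the network; returns (flatten features, softmax probabilities).

        ``train`` enables dropout and batch statistics; ``update_bn=False``
        performs a training-mode pass without touching the running
        statistics (the target-branch convention).
        """
        batch = np.asarray(batch, dtype=self.dtype)
        if batch.ndim != 3 or batch.shape[1:] != (self.ch, self.T):
            raise ValueError(
                f"batch shape {batch.shape} does not match (n, {self.ch}, "
                f"{self.T})")
        nb = batch.shape[0]
        x = Tensor(batch[:, None, :, :])  # (nb, 1, ch, T)
        # layer 1
        h = conv2d(x, self.w1, self.b1)  # (nb, 32, ch, T)
        h = self.bn1(h, train, update_bn)
        h = self._act(h)
        h = self._dropout(h, train, rng)
        # layer 2: collapse the channel axis with per-map spatial filters
        if self.spec.spatial_depthwise:
            # (nb, m, ch, T) x (m, ch) -> (nb, m, 1, T)
            w = self.w2.reshape(1, self.spec.n_temporal, self.ch, 1)
            h = (h * w).sum(axis=2, keepdims=True)
        else:
            # full connectivity across temporal maps and channels
            hm = h.transpose((0, 3, 1, 2)).reshape(nb * self.T,
                                                   self.spec.n_temporal * self.ch)
            wm = self.w2.reshape(self.spec.n_spatial,
                                 self.spec.n_temporal * self.ch)
            h = (hm @ wm.T).reshape(nb, self.T, self.spec.n_spatial, 1)
            h = h.transpose((0, 2, 3, 1))
        h = h + self.b2.reshape(1, -1, 1, 1)
        h = self.bn2(h, train, update_bn)
        h = self._act(h)
        h = h.transpose((0, 2, 1, 3))  # (nb, 1, 32, T)
        h = self._dropout(h, train, rng)
        # layer 3
        h = conv2d(h, self.w3, self.b3)
        h = self.bn3(h, train, update_bn)
        h = self._act(h)
        h = maxpool2d(h, self.spec.pool3)
        # layer 4
        h = conv2d(h, self.w4, self.b4)
        h = self.bn4(h, train, update_bn)
        h = self._act(h)
        h = maxpool2d(h, self.spec.pool4)
        # layer 5: flatten
        feats = h.reshape(nb, self.plan.flatten_width)
        # layer 6: softmax regression
        logits = feats @ self.w6 + self.b6.reshape(1, -1)
        zmax = logits.data.max(axis=1, keepdims=True)  # detached for stability
        e = (logits - zmax).exp()
        probs = e / e.sum(axis=1, keepdims=True)
        return feats, probs

    # ------------------------------------------------------------------

    def spatial_filter_weights(self) -> np.ndarray:
        """|weights| of the layer-2 spatial filters, (n_spatial, ch).

        In depthwise mode each row is one filter's channel profile (the
        object visualised as a scalp topography); in full mode the channel
        profile is aggregated over the incoming temporal maps.
        """
        if self.spec.spatial_depthwise:
            return np.abs(self.w2.data.copy())
        return np.abs(self.w2.data).sum(axis=1)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "ch": self.ch, "T": self.T, "dtype": self.dtype.name,
            "spec": asdict(self.spec),
            "plan": [[n, list(s)] for n, s in self.plan.layers],
            "params": {f"p{i}": p.data.tolist()
                       for i, p in enumerate(self.parameters())},
            "bn_running": {
                f"bn{i}": {"mean": bn.running_mean.tolist(),
                           "var": bn.running_var.tolist()}
                for i, bn in enumerate((self.bn1, self.bn2, self.bn3,
                                        self.bn4))},
        }
        path.write_text(json.dumps(payload))

    @staticmethod
    def load(path: str | Path) -> "DCJNN":
        payload = json.loads(Path(path).read_text())
        spec_d = payload["spec"]
        for key in ("conv3_kernel", "pool3", "conv4_kernel", "pool4"):
            spec_d[key] = tuple(spec_d[key])
        spec = NetworkSpec(**spec_d)
        dtype = np.dtype(payload.get("dtype", "float64"))
        model = DCJNN(payload["ch"], payload["T"], spec, seed=0, dtype=dtype)
        for i, p in enumerate(model.parameters()):
            p.data = np.asarray(payload["params"][f"p{i}"], dtype=dtype)
        for i, bn in enumerate((model.bn1, model.bn2, model.bn3,
                                model.bn4)):
            bn.running_mean = np.asarray(payload["bn_running"][f"bn{i}"]["mean"],
                                         dtype=dtype)
            bn.running_var = np.asarray(payload["bn_running"][f"bn{i}"]["var"],
                                        dtype=dtype)
        return model


def build_dcjnn(ch: int, T: int, spec: NetworkSpec | None = None,
                seed: int = 0, dtype=np.float64) -> DCJNN:
    """Construct a DCJNN with deterministic fan-in-scaled initialisation."""
    return DCJNN(ch, T, spec or NetworkSpec(), seed, dtype=dtype)


def forward_features(model: DCJNN, batch: np.ndarray) -> np.ndarray:
    """Eval-mode flatten-layer (layer 5) features, (trials x flatten_width)."""
    feats, _ = model.forward(batch, train=False)
    return feats.data.copy()


def forward_predict(model: DCJNN, batch: np.ndarray) -> np.ndarray:
    """Eval-mode class probabilities, rows summing to 1."""
    _, probs = model.forward(batch, train=False)
    return probs.data.copy()


def spatial_filter_weights(model: DCJNN) -> np.ndarray:
    """Module-level alias for :meth:`DCJNN.spatial_filter_weights`."""
    return model.spatial_filter_weights()
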