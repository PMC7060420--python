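"""Evidence diagnostics: embeddings, discriminative lines, trace analysis.

Three views of what joint-distribution matching does to the learned feature
space:

* a 2-D kernel-PCA embedding of flatten-layer features with one Fisher
  discriminant line per domain — when source and target are aligned the two
  lines nearly coincide;
* the angle between those lines plus the cross-domain MMD of the embedded
  coordinates, compared between an adapted and an unadapted model;
* the Spearman rank correlation between the epoch-wise JDD and the monitored
  target accuracy of a training trace (expected negative: accuracy rises as
  the joint discrepancy falls).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.decomposition import KernelPCA

from .discrepancy import FeatureBatch, KernelConfig, mmd_sq, rbf_gram
from .trainer import TrainTrace

__all__ = [
    "Embedding2D",
    "LdaLine",
    "kpca_embed_2d",
    "lda_line",
    "alignment_report",
    "trace_correlation",
]

LDA_RIDGE = 1e-6  # within-class scatter regulariser for singular fallback


@dataclass
class Embedding2D:
    """2-D coordinates plus per-point class labels and domain tags."""

    coords: np.ndarray
    labels: np.ndarray
    domains: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels)
        self.domains = np.asarray(self.domains)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be n x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        n = self.coords.shape[0]
        if self.labels.shape[0] != n or self.domains.shape[0] != n:
            raise ValueError("labels/domains length mismatch")


@dataclass(frozen=True)
class LdaLine:
    """Locus w . x = offset of equal Fisher discriminant score."""

    normal: tuple[float, float]
    offset: float

    def __post_init__(self) -> None:
        if np.hypot(*self.normal) == 0:
            raise ValueError("normal must be nonzero")

    def angle_to(self, other: "LdaLine") -> float:
        """Acute angle between the two lines, degrees in [0, 90]."""
        a = np.asarray(self.normal) / np.hypot(*self.normal)
        b = np.asarray(other.normal) / np.hypot(*other.normal)
        c = abs(float(a @ b))
        return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def kpca_embed_2d(features: np.ndarray, kernel: KernelConfig | None = None, *,
                  labels: np.ndarray | None = None,
                  domains: np.ndarray | None = None) -> Embedding2D:
    """Project features on the top-2 kernel principal components.

    Components are ordered by descending eigenvalue of the doubly-centered
    gram; each component's sign is fixed so its largest-magnitude coordinate
    is positive.
    """
    kernel = kernel or KernelConfig()
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    K = rbf_gram(features, features, kernel)
    kpca = KernelPCA(n_components=2, kernel="precomputed")
    try:
        coords = kpca.fit_transform(K)
    except ValueError as exc:  # pragma: no cover - sklearn message passthrough
        raise ValueError(f"degenerate input for KPCA: {exc}") from exc
    if kpca.eigenvalues_.shape[0] < 2 or kpca.eigenvalues_[1] <= 1e-12:
        raise ValueError("centered gram has rank < 2; degenerate input")
    for j in range(2):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return Embedding2D(
        coords=coords,
        labels=np.zeros(n, dtype=int) if labels is None else labels,
        domains=np.zeros(n, dtype=int) if domains is None else domains,
    )


def lda_line(embedding: Embedding2D, domain_tag) -> LdaLine:
    """Fisher discriminant line for one domain's points.

    Direction w solves ``S_w w = m1 - m0`` (within-class scatter, ridge
    fallback when singular); the line passes through the class-mean midpoint.
    """
    mask = embedding.domains == domain_tag
    pts = embedding.coords[mask]
    labs = embedding.labels[mask]
    classes = np.unique(labs)
    if classes.shape[0] != 2:
        raise ValueError("LDA line requires exactly two classes in domain")
    groups = [pts[labs == c] for c in classes]
    if any(g.shape[0] < 2 for g in groups):
        raise ValueError("need >= 2 points per class in domain")
    m0, m1 = (g.mean(axis=0) for g in groups)
    Sw = sum(np.cov(g.T, bias=True) * g.shape[0] for g in groups)
    try:
        w = np.linalg.solve(Sw, m1 - m0)
    except np.linalg.LinAlgError:
        w = np.linalg.solve(Sw + LDA_RIDGE * np.eye(2), m1 - m0)
    if np.hypot(*w) == 0:
        raise ValueError("degenerate class means (identical)")
    offset = float(w @ (m0 + m1) / 2.0)
    return LdaLine(normal=(float(w[0]), float(w[1])), offset=offset)


def _embed_pair(source_feats: np.ndarray, target_feats: np.ndarray,
                source_labels: np.ndarray, target_labels: np.ndarray,
                kernel: KernelConfig) -> Embedding2D:
    feats = np.vstack([source_feats, target_feats])
    labels = np.concatenate([source_labels, target_labels])
    domains = np.concatenate([np.zeros(len(source_labels), dtype=int),
                              np.ones(len(target_labels), dtype=int)])
    return kpca_embed_2d(feats, kernel, labels=labels, domains=domains)


def alignment_report(source_feats: dict[str, np.ndarray],
                     target_feats: dict[str, np.ndarray],
                     source_labels: np.ndarray, target_labels: np.ndarray,
                     kernel: KernelConfig | None = None) -> dict:
    """Compare feature-space alignment for two models.

    ``source_feats``/``target_feats`` map a model name (e.g. ``"with_jdd"``,
    ``"without_jdd"``) to that model's flatten-layer features for the same
    source/target trials.  For each model the report holds the 2-D
    embedding, per-domain LDA lines, the source-target line angle and the
    cross-domain squared MMD of the coordinates; ``smaller_angle`` names the
    model whose discriminative lines agree best.  Target labels enter only
    this diagnostic, never training.
    """
    if set(source_feats) != set(target_feats):
        raise ValueError("model name sets differ between domains")
    kernel = kernel or KernelConfig()
    report: dict = {"models": {}}
    for name in source_feats:
        emb = _embed_pair(source_feats[name], target_feats[name],
                          source_labels, target_labels, kernel)
        line_s = lda_line(emb, 0)
        line_t = lda_line(emb, 1)
        src_mask = emb.domains == 0
        coords_mmd = mmd_sq(FeatureBatch(emb.coords[src_mask]),
                            FeatureBatch(emb.coords[~src_mask]))
        report["models"][name] = {
            "embedding": emb.coords.tolist(),
            "labels": emb.labels.tolist(),
            "domains": emb.domains.tolist(),
            "source_line": {"normal": list(line_s.normal),
                            "offset": line_s.offset},
            "target_line": {"normal": list(line_t.normal),
                            "offset": line_t.offset},
            "angle_deg": line_s.angle_to(line_t),
            "coords_mmd_sq": coords_mmd,
        }
    names = sorted(report["models"],
                   key=lambda n: report["models"][n]["angle_deg"])
    report["smaller_angle"] = names[0]
    return report


def trace_correlation(trace: TrainTrace) -> float:
    """Spearman rank correlation of epoch-wise JDD vs target accuracy.

    Returns NaN when fewer than 5 epochs carry both quantities or when
    either series is constant (correlation undefined).
    """
    jdd = np.asarray(trace.jdd_sq, dtype=float)
    acc = np.asarray(trace.target_accuracy, dtype=float)
    ok = np.isfinite(jdd) & np.isfinite(acc)
    if ok.sum() < 5:
        raise ValueError("need >= 5 epochs with both jdd_sq and accuracy")
    jdd, acc = jdd[ok], acc[ok]
    if np.ptp(jdd) == 0 or np.ptp(acc) == 0:
        return float("nan")
    rho = spearmanr(jdd, acc).statistic
    return float(rho)


def report_to_json(report: dict, path) -> None:
    """Serialize an alignment report; round-trips through json."""
    with open(path, "w") as fh:
        json.dump(report, fh)
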