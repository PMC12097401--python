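"""Classification and image-quality metrics.

Sensitivity/specificity/accuracy/F1 from confusion counts, ROC/AUC, SSIM,
PSNR, and an embedder-qualified Fréchet distance between feature sets. The
Fréchet distance is only comparable across runs that used the same embedder,
so the caller is expected to log the embedder identity alongside the value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from skimage.metrics import peak_signal_noise_ratio as _sk_psnr
from skimage.metrics import structural_similarity as _sk_ssim
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ConfusionCounts", "EvalReport", "confusion_metrics", "roc_auc",
           "ssim", "psnr", "frechet_distance", "SmallConvEmbedder"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    sen: float | None
    spe: float | None
    acc: float | None
    f1: float | None
    n: int
    counts: ConfusionCounts | None = None
    roc: tuple | None = None       # (fpr, tpr, thresholds)
    auc: float | None = None


def confusion_metrics(counts: ConfusionCounts) -> EvalReport:
    """SEN = TP/(TP+FN), SPE = TN/(TN+FP), ACC, F1 = 2TP/(2TP+FP+FN).

    A metric whose denominator is zero is reported as None (missing), never
    silently as 0."""
    if counts.total <= 0:
        raise ValueError("confusion counts are all zero")

    def _ratio(num, den):
        return num / den if den > 0 else None

    return EvalReport(
        sen=_ratio(counts.tp, counts.tp + counts.fn),
        spe=_ratio(counts.tn, counts.tn + counts.fp),
        acc=(counts.tp + counts.tn) / counts.total,
        f1=_ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
        n=counts.total,
        counts=counts,
    )


def roc_auc(labels, scores):
    """ROC curve and AUC (rank/trapezoid; ties handled by the curve)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return (fpr, tpr, thr), float(_sk_auc(fpr, tpr))


def ssim(a: np.ndarray, b: np.ndarray, *, data_range: float = 1.0,
         win_size: int | None = None) -> float:
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(_sk_ssim(a.astype(np.float64), b.astype(np.float64),
                          data_range=data_range, win_size=win_size))


def psnr(a: np.ndarray, b: np.ndarray, *, data_range: float = 1.0) -> float:
    """PSNR in dB; identical images give +inf."""
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if np.array_equal(a, b):
        return float("inf")
    return float(_sk_psnr(a.astype(np.float64), b.astype(np.float64),
                          data_range=data_range))


def frechet_distance(features_a: np.ndarray, features_b: np.ndarray,
                     eps: float = 1e-6) -> float:
    """Fréchet distance between Gaussian fits to two feature sets:
    ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2}).

    The matrix square root is regularized with ``eps * I`` when it comes out
    non-finite (near-singular covariances at small n)."""
    a = np.asarray(features_a, dtype=np.float64)
    b = np.asarray(features_b, dtype=np.float64)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite features")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 feature rows per set")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    sa = np.cov(a, rowvar=False)
    sb = np.cov(b, rowvar=False)
    sa = np.atleast_2d(sa)
    sb = np.atleast_2d(sb)
    def _sqrtm(x):
        out = scipy.linalg.sqrtm(x)
        return out[0] if isinstance(out, tuple) else out

    covmean = _sqrtm(sa @ sb)
    if not np.isfinite(covmean).all():
        off = eps * np.eye(sa.shape[0])
        covmean = _sqrtm((sa + off) @ (sb + off))
    covmean = np.real(covmean)
    d2 = float(np.sum((mu_a - mu_b) ** 2)
               + np.trace(sa) + np.trace(sb) - 2.0 * np.trace(covmean))
    return max(d2, 0.0)


class SmallConvEmbedder:
    """Seeded fixed conv embedder for desk-scale Fréchet distances.

    Two random conv+ReLU stages with mean pooling; the final map is spatially
    averaged into a feature vector. Identified by its seed in logs."""

    def __init__(self, seed: int = 0):
        from ._nn import RandomFeatureNet
        self.seed = seed
        self.net = RandomFeatureNet(seed=seed)

    @property
    def name(self) -> str:
        return f"small-conv(seed={self.seed})"

    def embed(self, images) -> np.ndarray:
        x = np.stack([np.asarray(i, dtype=np.float32) for i in images])[:, None]
        feats = self.net.features(x)[-1]
        return feats.mean(axis=(2, 3))
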