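"""Per-feature phone discriminability, feature selection and LDA reduction.

Each stacked feature column (one channel at one temporal offset) is scored
by the mean Kullback-Leibler divergence between the per-phone univariate
Gaussians fitted on that column; averaging over all ordered pairs
symmetrizes the divergence.  Columns are ranked by their normalized score
and kept up to the last steep decline of the sorted sequence; the kept
columns are then projected to at most (n_classes - 1) dimensions with
linear discriminant analysis.

Two KL variants are available.  ``eq1_verbatim`` evaluates the closed form
with a base-2 logarithm on the determinant ratio while the trace and
Mahalanobis terms stay on the natural scale; this mixed-base expression is
not guaranteed non-negative.  ``natural`` uses the standard all-natural-log
closed form, which is a true divergence (>= 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .io_session import PipelineConfig, ValidationError
from .phones import SILENCE
from .preprocess import FrameLabels, StackedFeatures

log = logging.getLogger(__name__)


@dataclass
class GaussianStats:
    """Diagonal Gaussian: mean vector and per-dimension variances."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.var = np.atleast_1d(np.asarray(self.var, dtype=float))
        if self.mean.shape != self.var.shape:
            raise ValidationError("mean and variance dimensions differ")
        if np.any(self.var <= 0):
            raise ValidationError("variances must be positive")

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass
class KLMap:
    """Per-feature discriminability scores and the shift-null chance level."""

    feature_index_map: list[tuple[str, int]]
    d_k: np.ndarray                 # mean pairwise KL per feature, bits
    d_hat: np.ndarray               # normalized scores
    null_scores: np.ndarray | None  # n_shifts x n_features
    null_p99: float | None          # pooled 99th percentile of the null


@dataclass
class LdaProjection:
    """Linear map to the discriminant subspace (d_in x d_out)."""

    matrix: np.ndarray
    classes: list[str]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return X @ self.matrix


# ---------------------------------------------------------------------------
# KL divergence
# ---------------------------------------------------------------------------


def kl_divergence(g0: GaussianStats, g1: GaussianStats, mode: str = "eq1_verbatim") -> float:
    """Closed-form KL divergence D(N0 || N1) for diagonal Gaussians, in bits.

    ``natural`` is the standard divergence (non-negative); ``eq1_verbatim``
    replaces the log-determinant term's base by 2, which can go negative
    when the variance ratios stray far from 1.
    """
    if g0.dim != g1.dim:
        raise ValidationError(f"dimension mismatch: {g0.dim} vs {g1.dim}")
    trace = float(np.sum(g0.var / g1.var))
    maha = float(np.sum((g1.mean - g0.mean) ** 2 / g1.var))
    log_det_ratio = float(np.sum(np.log(g0.var) - np.log(g1.var)))
    d = g0.dim
    if mode == "eq1_verbatim":
        det_term = log_det_ratio / np.log(2.0)
    elif mode == "natural":
        det_term = log_det_ratio
    else:
        raise ValueError(f"unknown KL mode {mode!r}")
    return 0.5 * (trace + maha - d - det_term)


def _class_stats(
    X: np.ndarray,
    labels: np.ndarray,
    variance_floor: float,
    min_frames: int = 2,
    include_silence: bool = False,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-class mean and MLE variance for every column at once."""
    classes = sorted(set(labels.tolist()))
    if not include_silence:
        classes = [c for c in classes if c != SILENCE]
    kept, means, variances = [], [], []
    for c in classes:
        rows = X[labels == c]
        if rows.shape[0] < min_frames:
            log.warning("phone %r has %d frame(s); excluded from KL pairs", c, rows.shape[0])
            continue
        kept.append(c)
        means.append(rows.mean(axis=0))
        variances.append(np.maximum(rows.var(axis=0), variance_floor))
    if len(kept) < 2:
        raise ValidationError("need at least 2 phone classes with >= 2 frames")
    return kept, np.asarray(means), np.asarray(variances)


def mean_pairwise_kl(
    X: np.ndarray,
    labels: np.ndarray,
    mode: str = "eq1_verbatim",
    variance_floor: float = 1e-6,
    include_silence: bool = False,
) -> np.ndarray:
    """Mean KL divergence over all ordered class pairs, per feature column.

    Fits a univariate Gaussian per phone class on each column and averages
    D(j || j') over the ordered pairs j != j', which equals the mean of the
    symmetrized divergences.  Classes with fewer than 2 frames are excluded
    (with a warning).  Returns one score per column (bits).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels, dtype=object)
    _, mu, var = _class_stats(X, labels, variance_floor, include_silence=include_silence)
    n_classes = mu.shape[0]
    # ordered pairs (j, j'): broadcast classes x classes x features
    trace = var[:, None, :] / var[None, :, :]
    maha = (mu[None, :, :] - mu[:, None, :]) ** 2 / var[None, :, :]
    ldr = np.log(var[:, None, :]) - np.log(var[None, :, :])
    if mode == "eq1_verbatim":
        ldr = ldr / np.log(2.0)
    D = 0.5 * (trace + maha - 1.0 - ldr)
    off = ~np.eye(n_classes, dtype=bool)
    return D[off].reshape(n_classes * (n_classes - 1), -1).mean(axis=0)


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------


def normalize_scores(d_k: np.ndarray, normalization: str = "mean") -> np.ndarray:
    if normalization == "mean":
        return d_k / np.mean(d_k)
    if normalization == "sum":
        return d_k / np.sum(d_k)
    raise ValueError(f"unknown normalization {normalization!r}")


def select_features(
    d_hat: np.ndarray,
    threshold: float = -0.05,
    fallback_frac: float = 0.05,
) -> np.ndarray:
    """Keep the top-ranked features up to the last steep decline.

    Sort the normalized scores descending and find the largest rank l such
    that the drop from position l to l+1 is steeper than the threshold
    (d_(l+1) - d_(l) < t, t = -0.05); features 1..l are selected.  If no
    drop is that steep the configured fallback (top 5%, at least one
    feature) is returned with a warning.  The returned indices are a prefix
    of the descending score ranking.
    """
    d_hat = np.asarray(d_hat, dtype=float)
    if d_hat.size == 0:
        raise ValidationError("need at least one feature")
    order = np.argsort(-d_hat, kind="stable")
    if d_hat.size == 1:
        return order
    s = d_hat[order]
    drops = np.diff(s)  # s[l+1] - s[l], <= 0
    steep = np.nonzero(drops < threshold)[0]
    if steep.size == 0:
        k = max(1, int(np.ceil(fallback_frac * d_hat.size)))
        log.warning(
            "no decline steeper than %g in the sorted KL scores; "
            "falling back to the top %d feature(s)",
            abs(threshold),
            k,
        )
        return order[:k]
    l_star = steep[-1] + 1  # number of features kept
    return order[:l_star]


# ---------------------------------------------------------------------------
# Shift-null chance level
# ---------------------------------------------------------------------------


def shift_null_klmap(
    X: np.ndarray,
    labels: np.ndarray,
    n_shifts: int = 1,
    mode: str = "eq1_verbatim",
    variance_floor: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Null discriminability from label-preserving circular feature shifts.

    The feature rows are rotated circularly — by half the sequence length
    for the first shift, and by the other evenly spaced offsets when
    ``n_shifts > 1`` — while the labels stay in place, destroying the
    feature/label correspondence but preserving all marginal statistics.
    Returns (null score matrix [n_shifts x n_features], pooled 99th
    percentile across all features and shifts).
    """
    n = X.shape[0]
    if n < 4:
        raise ValidationError("need at least 4 frames for a shift null")
    if n_shifts == 1:
        offsets = [n // 2]
    else:
        offsets = [int(round((j + 1) * n / (n_shifts + 1))) for j in range(n_shifts)]
    rows = []
    for off in offsets:
        Xs = np.roll(X, off, axis=0)
        rows.append(mean_pairwise_kl(Xs, labels, mode=mode, variance_floor=variance_floor))
    null = np.asarray(rows)
    return null, float(np.percentile(null, 99))


def compute_klmap(
    features: StackedFeatures,
    frame_labels: FrameLabels,
    cfg: PipelineConfig | None = None,
    with_null: bool = True,
) -> KLMap:
    """Score every stacked column, normalize, and attach the shift-null level."""
    cfg = cfg or PipelineConfig()
    labels = frame_labels.as_array()
    d_k = mean_pairwise_kl(
        features.F, labels, mode=cfg.kl_mode, variance_floor=cfg.variance_floor
    )
    d_hat = normalize_scores(d_k, cfg.kl_normalization)
    null_scores, null_p99 = (None, None)
    if with_null:
        null_scores, null_p99 = shift_null_klmap(
            features.F,
            labels,
            n_shifts=cfg.n_shifts,
            mode=cfg.kl_mode,
            variance_floor=cfg.variance_floor,
        )
    return KLMap(features.feature_index_map, d_k, d_hat, null_scores, null_p99)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------


def fit_lda(
    X: np.ndarray,
    labels: np.ndarray,
    shrinkage: str | float | None = None,
) -> LdaProjection:
    """Fit an LDA projection to at most (n_classes - 1) dimensions.

    Scalar (Ledoit-Wolf) shrinkage of the within-class covariance is turned
    on automatically when the frame count is under three times the input
    dimension, where the plain scatter estimate is unreliable.
    """
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValidationError("LDA needs at least 2 classes")
    n, d = X.shape
    if shrinkage is None and n < 3 * d:
        shrinkage = "auto"
    n_components = min(len(classes) - 1, d)
    lda = LinearDiscriminantAnalysis(
        solver="eigen", shrinkage=shrinkage, n_components=n_components
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            lda.fit(X, labels.astype(str))
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                "singular within-class scatter; enable shrinkage (pass shrinkage='auto')"
            ) from exc
    W = np.asarray(lda.scalings_)[:, :n_components]
    if not np.isfinite(W).all():
        raise ValidationError(
            "LDA produced non-finite directions; enable shrinkage (pass shrinkage='auto')"
        )
    return LdaProjection(W, [str(c) for c in lda.classes_])
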