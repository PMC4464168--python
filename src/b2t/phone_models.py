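"""Per-phone diagonal Gaussian emission models and the speech-activity screen.

Each grouped phone j (plus the silence unit) is modelled in the reduced
feature space by a single multivariate Gaussian with diagonal covariance,
N(mu_j, Sigma_j), fitted by the sample mean and per-dimension sample
variance of its training frames.  A variance floor keeps the densities
proper when a dimension degenerates.

The speech-activity screen is a session-level sanity gate: if two such
Gaussians (speech vs non-speech) cannot classify held-out frames better
than a label-preserving shift null, the session carries no usable
speech-related signal and is rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.stats

from .discriminability import LdaProjection
from .io_session import ValidationError
from .phones import SILENCE
from .preprocess import FrameLabels

log = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PhoneModel:
    phone: str
    mean: np.ndarray
    var: np.ndarray  # diagonal variances
    n_train_frames: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.mean.shape != self.var.shape or self.mean.ndim != 1:
            raise ValidationError("phone model mean/variance must be matching vectors")
        if np.any(self.var <= 0):
            raise ValidationError("phone model variances must be positive")

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass
class ModelSet:
    """One Gaussian per trainable phone plus silence, with the feature maps used."""

    models: dict[str, PhoneModel]
    selected_features: np.ndarray | None = None
    lda: LdaProjection | None = None
    dropped_phones: list[str] = field(default_factory=list)

    @property
    def phones(self) -> list[str]:
        return sorted(self.models)

    @property
    def dim(self) -> int:
        return next(iter(self.models.values())).dim

    def reduce(self, F: np.ndarray) -> np.ndarray:
        """Apply the stored feature selection and LDA projection."""
        X = F
        if self.selected_features is not None:
            X = X[:, self.selected_features]
        if self.lda is not None:
            X = self.lda.transform(X)
        return X

    def to_json(self) -> str:
        payload = {
            "selected_features": None
            if self.selected_features is None
            else np.asarray(self.selected_features).tolist(),
            "lda": None
            if self.lda is None
            else {"matrix": self.lda.matrix.tolist(), "classes": self.lda.classes},
            "dropped_phones": self.dropped_phones,
            "models": {
                p: {
                    "mean": m.mean.tolist(),
                    "var": m.var.tolist(),
                    "n_train_frames": m.n_train_frames,
                }
                for p, m in self.models.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelSet":
        data = json.loads(text)
        models = {
            p: PhoneModel(p, np.asarray(m["mean"]), np.asarray(m["var"]), m["n_train_frames"])
            for p, m in data["models"].items()
        }
        sel = data.get("selected_features")
        lda = data.get("lda")
        return cls(
            models,
            None if sel is None else np.asarray(sel, dtype=int),
            None if lda is None else LdaProjection(np.asarray(lda["matrix"]), lda["classes"]),
            data.get("dropped_phones", []),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelSet":
        return cls.from_json(Path(path).read_text())


def fit_phone_models(
    X: np.ndarray,
    frame_labels: FrameLabels | np.ndarray,
    variance_floor: float = 1e-6,
    min_frames: int = 5,
) -> ModelSet:
    """Fit mu_j / diagonal Sigma_j per phone from its training frames.

    Phones with fewer than ``min_frames`` frames are dropped with a warning
    (words containing them become undecodable).  A silence model is
    mandatory: the decoder needs it.
    """
    labels = (
        frame_labels.as_array() if isinstance(frame_labels, FrameLabels) else np.asarray(frame_labels, dtype=object)
    )
    X = np.asarray(X, dtype=float)
    models: dict[str, PhoneModel] = {}
    dropped: list[str] = []
    for phone in sorted(set(labels.tolist())):
        rows = X[labels == phone]
        if rows.shape[0] < max(min_frames, 2):
            dropped.append(phone)
            log.warning(
                "phone %r has only %d frame(s) (< %d); model dropped",
                phone,
                rows.shape[0],
                min_frames,
            )
            continue
        mu = rows.mean(axis=0)
        var = np.maximum(rows.var(axis=0), variance_floor)
        models[phone] = PhoneModel(phone, mu, var, rows.shape[0])
    if SILENCE not in models:
        raise ValidationError("no silence frames in training data; a 'sil' model is required")
    return ModelSet(models, dropped_phones=dropped)


def log_likelihood_matrix(ms: ModelSet, X: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Diagonal-Gaussian log densities, frames x phones (columns in ms.phones order)."""
    X = np.asarray(X, dtype=float)
    phones = ms.phones
    d = ms.dim
    if X.shape[1] != d:
        raise ValidationError(f"feature dimension {X.shape[1]} != model dimension {d}")
    out = np.empty((X.shape[0], len(phones)))
    for j, p in enumerate(phones):
        m = ms.models[p]
        z = (X - m.mean) ** 2 / m.var
        out[:, j] = -0.5 * (d * LOG_2PI + np.sum(np.log(m.var)) + z.sum(axis=1))
    return out, phones


# ---------------------------------------------------------------------------
# Speech-activity pre-selection screen
# ---------------------------------------------------------------------------


def _two_class_accuracy(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, yte: np.ndarray, floor: float
) -> float:
    """Train speech/non-speech diagonal Gaussians, classify by higher likelihood."""
    scores = []
    for cls in (False, True):
        rows = Xtr[ytr == cls]
        mu = rows.mean(axis=0)
        var = np.maximum(rows.var(axis=0), floor)
        z = (Xte - mu) ** 2 / var
        scores.append(-0.5 * (np.sum(np.log(var)) + z.sum(axis=1)))
    pred = scores[1] > scores[0]
    return float(np.mean(pred == yte))


def speech_activity_screen(
    F: np.ndarray,
    frame_labels: FrameLabels,
    variance_floor: float = 1e-6,
) -> dict:
    """Leave-one-phrase-out speech/non-speech classification vs the shift null.

    Frames between phrases are attached to the preceding phrase so every
    fold contains both classes.  The same classifier is run on features
    circularly rotated by half the training length (labels fixed); a
    two-sided paired t-test across phrases compares real and null
    accuracies.  The session passes iff p <= 0.05 (and the effect favours
    the real features).
    """
    y_speech = np.asarray([p != SILENCE for p in frame_labels.phone])
    pid = list(frame_labels.phrase_id)
    # attach inter-phrase silence to the most recent phrase
    last = None
    filled: list[int | None] = []
    for p in pid:
        if p is not None:
            last = p
        filled.append(last)
    first = next((p for p in filled if p is not None), None)
    if first is None:
        raise ValidationError("no phrases in session")
    filled = [first if p is None else p for p in filled]
    fold_ids = np.asarray(filled)
    phrases = np.unique(fold_ids)
    if phrases.size < 2:
        raise ValidationError("speech-activity screen needs at least 2 phrases")

    acc_real, acc_null = [], []
    for ph in phrases:
        te = fold_ids == ph
        tr = ~te
        ytr, yte = y_speech[tr], y_speech[te]
        if ytr.all() or (~ytr).all() or yte.size == 0:
            log.warning("phrase %s fold lacks a class; skipped in screen", ph)
            continue
        Xtr, Xte = F[tr], F[te]
        acc_real.append(_two_class_accuracy(Xtr, ytr, Xte, yte, variance_floor))
        Xtr_null = np.roll(Xtr, Xtr.shape[0] // 2, axis=0)
        acc_null.append(_two_class_accuracy(Xtr_null, ytr, Xte, yte, variance_floor))

    acc_real_arr, acc_null_arr = np.asarray(acc_real), np.asarray(acc_null)
    diff = acc_real_arr - acc_null_arr
    if np.allclose(diff, 0.0):
        p_value = 1.0
    else:
        p_value = float(scipy.stats.ttest_rel(acc_real_arr, acc_null_arr).pvalue)
    return {
        "accuracy": float(acc_real_arr.mean()),
        "null_accuracy_mean": float(acc_null_arr.mean()),
        "p_value": p_value,
        "pass": bool(p_value <= 0.05 and acc_real_arr.mean() > acc_null_arr.mean()),
        "n_folds": int(acc_real_arr.size),
    }
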