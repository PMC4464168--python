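"""Leave-one-phrase-out evaluation against a label-preserving shift baseline.

Each phrase of a session is decoded by models trained on all other
phrases: feature selection, LDA, phone models and the language model are
all re-fitted per fold so the held-out phrase stays unseen.  Chance level
comes from retraining every fold on features circularly rotated by half
the training length with the labels fixed — the rotated data keep every
marginal property of broadband-gamma features but no longer correspond
to the labels, and the label priors are untouched.

Metrics: word error rate (WER = (S+D+I)/N from a minimum edit alignment),
single-frame phone accuracy, phone confusion matrices, and WER as a
function of dictionary size (per-phrase dictionaries of the spoken words
plus random distractors, identical in the real and randomized arms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .decoder import DecodeError, DecodeResult, decode_phrase, estimate_bigram_lm
from .discriminability import fit_lda, mean_pairwise_kl, normalize_scores, select_features
from .io_session import PipelineConfig, PronunciationDict, ValidationError
from .phone_models import ModelSet, fit_phone_models
from .phones import SILENCE
from .preprocess import FrameLabels, StackedFeatures

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def word_error_rate(ref: list[str], hyp: list[str]) -> tuple[float, int, int, int]:
    """(WER, S, D, I) from a unit-cost minimum edit alignment.

    WER = (S + D + I) / len(ref) and may exceed 1.  On equal cost the
    backtrace prefers match/substitution over deletion over insertion.
    """
    if not ref:
        raise ValidationError("empty reference")
    n, m = len(ref), len(hyp)
    cost = np.zeros((n + 1, m + 1), dtype=int)
    cost[:, 0] = np.arange(n + 1)
    cost[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = cost[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1])
            cost[i, j] = min(sub, cost[i - 1, j] + 1, cost[i, j - 1] + 1)
    S = D = I = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and cost[i, j] == cost[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1]):
            S += ref[i - 1] != hyp[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and cost[i, j] == cost[i - 1, j] + 1:
            D += 1
            i -= 1
        else:
            I += 1
            j -= 1
    return (S + D + I) / n, S, D, I


def frame_accuracy(ref: list[str], hyp: list[str]) -> float:
    """Fraction of frames with identical grouped label (silence counts)."""
    if len(ref) != len(hyp):
        raise ValidationError(f"length mismatch: {len(ref)} vs {len(hyp)}")
    if not ref:
        raise ValidationError("empty frame sequences")
    return float(np.mean([r == h for r, h in zip(ref, hyp)]))


def confusion_matrix(
    fold_results: list["FoldResult"],
) -> tuple[np.ndarray, list[str]]:
    """Reference-phone x decoded-phone frame counts over all folds."""
    if not fold_results:
        raise ValidationError("no folds")
    labels = sorted(
        {l for f in fold_results for l in f.reference_frames}
        | {l for f in fold_results for l in f.decoded_frames}
    )
    idx = {l: i for i, l in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)), dtype=int)
    for f in fold_results:
        for r, h in zip(f.reference_frames, f.decoded_frames):
            M[idx[r], idx[h]] += 1
    return M, labels


def phone_true_positive_rate(
    fold_results: list["FoldResult"], include_silence: bool = False
) -> float:
    """Mean per-phone recall over phones with reference frames (sil excluded)."""
    M, labels = confusion_matrix(fold_results)
    rates = []
    for i, lab in enumerate(labels):
        if lab == SILENCE and not include_silence:
            continue
        total = M[i].sum()
        if total:
            rates.append(M[i, i] / total)
    return float(np.mean(rates)) if rates else float("nan")


# ---------------------------------------------------------------------------
# Fold containers
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    phrase_id: int
    reference_words: list[str]
    decoded_words: list[str]
    reference_frames: list[str]
    decoded_frames: list[str]
    wer: float
    S: int
    D: int
    I: int
    N: int
    frame_acc: float
    score: float

    @classmethod
    def from_decode(
        cls,
        phrase_id: int,
        ref_words: list[str],
        ref_frames: list[str],
        result: DecodeResult,
    ) -> "FoldResult":
        wer, S, D, I = word_error_rate(ref_words, result.words)
        acc = frame_accuracy(ref_frames, result.frame_path)
        return cls(
            phrase_id,
            ref_words,
            result.words,
            ref_frames,
            result.frame_path,
            wer,
            S,
            D,
            I,
            len(ref_words),
            acc,
            result.score,
        )


@dataclass
class TrainedFold:
    """Models fitted with one phrase held out (real and shift-randomized arms)."""

    phrase_id: int
    real: ModelSet
    random: ModelSet | None
    mean_frames: dict[str, float]
    shift: int


@dataclass
class EvalReport:
    folds_real: list[FoldResult]
    folds_random: list[FoldResult]
    mean_wer: float
    mean_wer_random: float
    mean_frame_acc: float
    mean_frame_acc_random: float
    frame_acc_p_value: float
    wer_p_value: float
    confusion: np.ndarray = field(repr=False)
    confusion_labels: list[str] = field(default_factory=list)
    by_size: dict[int, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_wer": self.mean_wer,
            "mean_wer_random": self.mean_wer_random,
            "mean_frame_accuracy": self.mean_frame_acc,
            "mean_frame_accuracy_random": self.mean_frame_acc_random,
            "frame_accuracy_p_value": self.frame_acc_p_value,
            "wer_p_value": self.wer_p_value,
            "n_folds": len(self.folds_real),
            "confusion_labels": self.confusion_labels,
            "confusion": self.confusion.tolist(),
            "by_size": self.by_size,
            "folds": [
                {
                    "phrase_id": f.phrase_id,
                    "reference": f.reference_words,
                    "decoded": f.decoded_words,
                    "wer": f.wer,
                    "frame_accuracy": f.frame_acc,
                }
                for f in self.folds_real
            ],
        }


# ---------------------------------------------------------------------------
# Training per fold
# ---------------------------------------------------------------------------


def mean_run_lengths(labels: np.ndarray) -> dict[str, float]:
    """Mean contiguous-run length (frames) per label — expected phone durations."""
    runs: dict[str, list[int]] = {}
    prev, count = None, 0
    for lab in list(labels) + [None]:
        if lab == prev:
            count += 1
        else:
            if prev is not None:
                runs.setdefault(prev, []).append(count)
            prev, count = lab, 1
    return {k: float(np.mean(v)) for k, v in runs.items()}


def train_models(
    F: np.ndarray,
    labels: np.ndarray,
    cfg: PipelineConfig,
    rotate: int = 0,
) -> ModelSet:
    """Feature selection -> LDA -> phone models, on the given rows only.

    ``rotate`` circularly shifts the feature rows (labels fixed) before
    every training step — the randomization baseline.
    """
    X = np.roll(F, rotate, axis=0) if rotate else F
    d_k = mean_pairwise_kl(X, labels, mode=cfg.kl_mode, variance_floor=cfg.variance_floor)
    d_hat = normalize_scores(d_k, cfg.kl_normalization)
    sel = select_features(d_hat, cfg.selection_threshold, cfg.selection_fallback_frac)
    lda = fit_lda(X[:, sel], labels)
    X_red = lda.transform(X[:, sel])
    ms = fit_phone_models(X_red, labels, cfg.variance_floor, cfg.min_frames_per_phone)
    ms.selected_features = sel
    ms.lda = lda
    return ms


def train_fold(
    F: np.ndarray,
    labels: np.ndarray,
    train_mask: np.ndarray,
    phrase_id: int,
    cfg: PipelineConfig,
    with_random: bool = True,
) -> TrainedFold:
    Xtr, ytr = F[train_mask], labels[train_mask]
    shift = Xtr.shape[0] // 2
    real = train_models(Xtr, ytr, cfg)
    random_ms = train_models(Xtr, ytr, cfg, rotate=shift) if with_random else None
    return TrainedFold(phrase_id, real, random_ms, mean_run_lengths(ytr), shift)


# ---------------------------------------------------------------------------
# Session-level evaluation
# ---------------------------------------------------------------------------


def _phrase_masks(frame_labels: FrameLabels, n_phrases: int) -> list[np.ndarray]:
    pid = np.array([-1 if p is None else p for p in frame_labels.phrase_id])
    return [pid == i for i in range(n_phrases)]


def _fold_dictionary(
    spoken: list[str],
    pool: list[str],
    size: int,
    rng: np.random.Generator,
) -> list[str]:
    """Spoken words plus uniformly sampled distractors, without replacement."""
    vocab = sorted(set(spoken))
    candidates = sorted(set(pool) - set(vocab))
    n_extra = size - len(vocab)
    if n_extra < 0:
        raise ValidationError(
            f"dictionary size {size} smaller than the {len(vocab)} spoken words"
        )
    if n_extra > len(candidates):
        raise ValidationError(
            f"word pool too small: need {n_extra} distractors, have {len(candidates)}"
        )
    distractors = sorted(rng.choice(candidates, size=n_extra, replace=False).tolist())
    return sorted(vocab + distractors)


def _decodable_lexicon(lexicon: PronunciationDict, ms: ModelSet) -> PronunciationDict:
    """Drop words containing phones without a trained model."""
    modeled = set(ms.phones)
    sub = PronunciationDict()
    for w in lexicon.words:
        for pron in lexicon[w]:
            if set(pron) <= modeled:
                sub.add(w, pron)
            else:
                log.warning("word %r undecodable in this fold (unmodeled phone)", w)
    if len(sub) == 0:
        raise ValidationError("no decodable words left in this fold")
    return sub


def _decode_fold(
    ms: ModelSet,
    F_test: np.ndarray,
    lexicon: PronunciationDict,
    lm,
    cfg: PipelineConfig,
    mean_frames: dict[str, float],
) -> DecodeResult:
    X_red = ms.reduce(F_test)
    lex = _decodable_lexicon(lexicon, ms)
    return decode_phrase(ms, X_red, lex, lm, cfg, mean_frames)


def leave_one_phrase_out(
    features: StackedFeatures,
    frame_labels: FrameLabels,
    phrase_words: list[list[str]],
    lexicon: PronunciationDict,
    cfg: PipelineConfig | None = None,
    dict_size: int = 10,
    sizes: list[int] | None = None,
    seed: int = 0,
    with_random: bool = True,
    word_pool: list[str] | None = None,
) -> EvalReport:
    """Full leave-one-phrase-out evaluation of one session.

    For every phrase: train on the remaining phrases (real and, when
    requested, half-shift-randomized), build the per-phrase dictionary of
    the spoken words plus seeded distractors (shared between arms),
    re-estimate the bigram LM restricted to that dictionary, decode, and
    score.  ``sizes`` adds the dictionary-size sweep on the same trained
    folds.
    """
    cfg = cfg or PipelineConfig()
    n_phrases = len(phrase_words)
    if n_phrases < 2:
        raise ValidationError("leave-one-phrase-out needs at least 2 phrases")
    F = features.F
    labels = frame_labels.as_array()
    masks = _phrase_masks(frame_labels, n_phrases)
    for i, m in enumerate(masks):
        if not m.any():
            raise ValidationError(f"phrase {i} has no frames")
    pool = word_pool if word_pool is not None else sorted({w for p in phrase_words for w in p})

    trained = [
        train_fold(F, labels, ~masks[i], i, cfg, with_random) for i in range(n_phrases)
    ]

    all_sizes = sorted(set([dict_size] + (sizes or [])))
    per_size: dict[int, tuple[list[FoldResult], list[FoldResult]]] = {
        s: ([], []) for s in all_sizes
    }
    root_rng = np.random.default_rng(seed)
    fold_seeds = root_rng.integers(0, 2**31 - 1, size=n_phrases)

    for i, tf in enumerate(trained):
        spoken = phrase_words[i]
        ref_frames = [labels[j] for j in np.nonzero(masks[i])[0]]
        F_test = F[masks[i]]
        train_sentences = [p for j, p in enumerate(phrase_words) if j != i]
        for size in all_sizes:
            rng = np.random.default_rng([int(fold_seeds[i]), size])
            words = _fold_dictionary(spoken, pool, size, rng)
            sub_lex = lexicon.restrict(words)
            lm = estimate_bigram_lm(train_sentences, vocabulary=words)
            arms = [("real", tf.real)] + ([("random", tf.random)] if with_random else [])
            for arm_name, ms in arms:
                try:
                    res = _decode_fold(ms, F_test, sub_lex, lm, cfg, tf.mean_frames)
                except DecodeError:
                    log.warning("fold %d (%s, size %d): no path; scoring empty", i, arm_name, size)
                    res = DecodeResult([], [], [SILENCE] * len(ref_frames), float("-inf"))
                fr = FoldResult.from_decode(i, spoken, ref_frames, res)
                per_size[size][0 if arm_name == "real" else 1].append(fr)

    folds_real, folds_random = per_size[dict_size]
    report = _summarize(folds_real, folds_random, with_random)
    for s in all_sizes:
        fr, fd = per_size[s]
        entry = {
            "mean_wer": float(np.mean([f.wer for f in fr])),
            "phone_tpr": phone_true_positive_rate(fr),
        }
        if with_random and fd:
            entry["mean_wer_random"] = float(np.mean([f.wer for f in fd]))
            entry["phone_tpr_random"] = phone_true_positive_rate(fd)
            entry["wer_p_value"] = _paired_p(
                [f.wer for f in fr], [f.wer for f in fd], alternative="less"
            )
        report.by_size[s] = entry
    return report


def _paired_p(a: list[float], b: list[float], alternative: str = "two-sided") -> float:
    a_arr, b_arr = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if np.allclose(a_arr, b_arr):
        return 1.0
    res = scipy.stats.ttest_rel(a_arr, b_arr, alternative=alternative)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def _summarize(
    folds_real: list[FoldResult],
    folds_random: list[FoldResult],
    with_random: bool,
) -> EvalReport:
    M, labels = confusion_matrix(folds_real)
    acc_r = [f.frame_acc for f in folds_real]
    wer_r = [f.wer for f in folds_real]
    if with_random and folds_random:
        acc_0 = [f.frame_acc for f in folds_random]
        wer_0 = [f.wer for f in folds_random]
        p_acc = _paired_p(acc_r, acc_0, "two-sided")
        p_wer = _paired_p(wer_r, wer_0, "less")
        mean_wer_rand = float(np.mean(wer_0))
        mean_acc_rand = float(np.mean(acc_0))
    else:
        p_acc = p_wer = float("nan")
        mean_wer_rand = mean_acc_rand = float("nan")
    return EvalReport(
        folds_real,
        folds_random,
        float(np.mean(wer_r)),
        mean_wer_rand,
        float(np.mean(acc_r)),
        mean_acc_rand,
        p_acc,
        p_wer,
        M,
        labels,
        {},
    )
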