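"""Raw signal -> labelled, context-stacked log broadband-gamma features.

Processing chain (order fixed): per-channel linear detrend -> anti-aliased
downsampling (9600 -> 600 Hz) -> line-noise channel rejection (58-62 Hz
energy above Q3 + 2*IQR) -> common-average re-reference -> elliptic IIR
band filters isolating 70-170 Hz broadband gamma with a 118-122 Hz notch
(first line-noise harmonic) -> 50 ms / 25 ms-hop log mean-square energy
per channel -> context stacking with the +-4 neighbouring frames.

Filters are applied causally (forward only) by default so the same chain
is usable online; a zero-phase option exists for offline analysis parity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .io_session import PipelineConfig, RawRecording, SegmentLabel, ValidationError
from .phones import DEFAULT_GROUPING, SILENCE, group_phone  # noqa: F401  (re-export)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class FrameSequence:
    """Per-frame log gamma-band power, frames x kept channels."""

    E: np.ndarray
    frame_times: np.ndarray  # start second of each frame
    window_s: float
    hop_s: float
    kept_channel_names: list[str]

    def __post_init__(self) -> None:
        if self.E.size and not np.isfinite(self.E).all():
            raise ValidationError("frame energies contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.E.shape[0]


@dataclass
class StackedFeatures:
    """Context-stacked features: row i = [E_{i-k} ... E_i ... E_{i+k}]."""

    F: np.ndarray
    feature_index_map: list[tuple[str, int]]  # column -> (channel, frame offset)
    context_frames: int
    frame_times: np.ndarray
    window_s: float
    hop_s: float

    @property
    def n_frames(self) -> int:
        return self.F.shape[0]

    @property
    def n_features(self) -> int:
        return self.F.shape[1]


@dataclass
class FrameLabels:
    """Per-frame grouped phone (or ``sil``) and phrase membership."""

    phone: list[str]
    phrase_id: list[int | None]

    def __len__(self) -> int:
        return len(self.phone)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.phone, dtype=object)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def _check_stable(sos: np.ndarray, stage: str) -> np.ndarray:
    poles = np.concatenate([np.roots([1.0, s[4], s[5]]) for s in sos])
    if np.any(np.abs(poles) >= 1.0):
        raise ValidationError(f"unstable filter design in stage {stage!r}")
    return sos


def _ellip_sos(cfg: PipelineConfig, rate: float, btype: str, wn, order: int, stage: str):
    sos = scipy.signal.ellip(
        order,
        cfg.passband_ripple_db,
        cfg.stopband_atten_db,
        wn,
        btype=btype,
        fs=rate,
        output="sos",
    )
    return _check_stable(sos, stage)


def _apply_sos(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return scipy.signal.sosfiltfilt(sos, x, axis=-1)
    return scipy.signal.sosfilt(sos, x, axis=-1)


def gamma_band_filter(
    rec: RawRecording, cfg: PipelineConfig | None = None
) -> RawRecording:
    """Isolate broadband gamma: high-pass, low-pass and line-harmonic notch."""
    cfg = cfg or PipelineConfig()
    rate = rec.sampling_rate
    if rate < 2 * cfg.gamma_high_hz:
        raise ValidationError(
            f"sampling rate {rate} Hz too low for a {cfg.gamma_high_hz} Hz band edge"
        )
    hp = _ellip_sos(cfg, rate, "highpass", cfg.gamma_low_hz, cfg.gamma_filter_order, "highpass")
    lp = _ellip_sos(cfg, rate, "lowpass", cfg.gamma_high_hz, cfg.gamma_filter_order, "lowpass")
    notch = _ellip_sos(
        cfg, rate, "bandstop", [cfg.notch_low_hz, cfg.notch_high_hz], cfg.notch_order, "notch"
    )
    x = rec.signal
    for sos in (hp, lp, notch):
        x = _apply_sos(sos, x, cfg.zero_phase)
    return RawRecording(x, rate, rec.channel_names, rec.session_id)


def detrend_downsample(
    rec: RawRecording, target_rate: float, cfg: PipelineConfig | None = None
) -> RawRecording:
    """Remove per-channel linear trends, then anti-aliased integer-ratio resample."""
    ratio = rec.sampling_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValidationError(
            f"target rate {target_rate} must divide the sampling rate {rec.sampling_rate}"
        )
    q = int(round(ratio))
    x = scipy.signal.detrend(rec.signal, axis=-1, type="linear")
    if q > 1:
        x = scipy.signal.resample_poly(x, up=1, down=q, axis=-1)
    n_out = int(rec.n_samples * target_rate // rec.sampling_rate)
    x = x[:, :n_out]
    return RawRecording(x, target_rate, rec.channel_names, rec.session_id)


def car_reference(rec: RawRecording) -> RawRecording:
    """Common-average re-reference: subtract the cross-channel mean per sample."""
    if rec.n_channels < 2:
        raise ValidationError("common-average reference needs at least 2 channels")
    x = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return RawRecording(x, rec.sampling_rate, rec.channel_names, rec.session_id)


def _channel_band_energy(
    rec: RawRecording, low: float, high: float, cfg: PipelineConfig
) -> np.ndarray:
    """Mean framed energy of the band-passed channel (same framing machinery)."""
    sos = _ellip_sos(cfg, rec.sampling_rate, "bandpass", [low, high], 4, "line-noise band")
    x = _apply_sos(sos, rec.signal, cfg.zero_phase)
    w = int(round(cfg.window_s * rec.sampling_rate))
    h = int(round(cfg.hop_s * rec.sampling_rate))
    frames = _frame_view(x, w, h)
    if frames.shape[1] == 0:  # shorter than one window: fall back to whole-signal energy
        return np.mean(x**2, axis=-1)
    return np.mean(frames**2, axis=(1, 2))


def remove_noisy_channels(
    rec: RawRecording,
    cfg: PipelineConfig | None = None,
) -> tuple[RawRecording, list[str]]:
    """Drop channels whose 58-62 Hz (line-noise) energy exceeds Q3 + 2*IQR.

    Quartiles are taken over all channels' band energies; survivor order is
    preserved.  Requires >= 4 channels for the quartiles to be meaningful.
    """
    cfg = cfg or PipelineConfig()
    if rec.n_channels < 4:
        raise ValidationError("channel rejection needs at least 4 channels")
    energy = _channel_band_energy(rec, cfg.line_noise_low_hz, cfg.line_noise_high_hz, cfg)
    q1, q3 = np.percentile(energy, [25, 75])
    threshold = q3 + 2.0 * (q3 - q1)
    keep = energy <= threshold
    removed = [n for n, k in zip(rec.channel_names, keep) if not k]
    if not keep.any():
        raise ValidationError("channel rejection removed every channel")
    if removed:
        log.info("removed %d noisy channel(s): %s", len(removed), removed)
    out = RawRecording(
        rec.signal[keep],
        rec.sampling_rate,
        [n for n, k in zip(rec.channel_names, keep) if k],
        rec.session_id,
    )
    return out, removed


# ---------------------------------------------------------------------------
# Framing and stacking
# ---------------------------------------------------------------------------


def _frame_view(x: np.ndarray, window: int, hop: int) -> np.ndarray:
    """channels x samples -> channels x n_frames x window (full windows only)."""
    n = x.shape[-1]
    if n < window:
        return np.empty((x.shape[0], 0, window), dtype=x.dtype)
    n_frames = (n - window) // hop + 1
    idx = np.arange(window)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[:, idx]


def frame_log_energy(rec: RawRecording, cfg: PipelineConfig | None = None) -> FrameSequence:
    """E_{i,c} = log( (1/n) * sum_t X_{i,c}(t)^2 ) over 50 ms windows, 25 ms hop.

    Zero-energy windows are floored at ``log_energy_floor`` so no -inf enters
    the feature matrix.
    """
    cfg = cfg or PipelineConfig()
    w = int(round(cfg.window_s * rec.sampling_rate))
    h = int(round(cfg.hop_s * rec.sampling_rate))
    if abs(cfg.window_s * rec.sampling_rate - w) > 1e-6:
        raise ValidationError("window must span an integer number of samples")
    frames = _frame_view(rec.signal, w, h)
    mean_sq = np.mean(frames**2, axis=-1)  # channels x n_frames
    E = np.log(np.maximum(mean_sq, cfg.log_energy_floor)).T  # frames x channels
    times = cfg.hop_s * np.arange(E.shape[0])
    return FrameSequence(E, times, cfg.window_s, cfg.hop_s, list(rec.channel_names))


def stack_context(fs: FrameSequence, k: int = 4) -> StackedFeatures:
    """Stack each frame with its k past and k future neighbours.

    Edge frames replicate the first/last frame so the stacked matrix keeps
    one row per frame (and per label).
    """
    if k < 0:
        raise ValidationError("context_frames must be >= 0")
    n, d = fs.E.shape
    cols = []
    index_map: list[tuple[str, int]] = []
    for off in range(-k, k + 1):
        idx = np.clip(np.arange(n) + off, 0, max(n - 1, 0))
        cols.append(fs.E[idx] if n else np.empty((0, d)))
        index_map.extend((ch, off) for ch in fs.kept_channel_names)
    F = np.concatenate(cols, axis=1) if cols else np.empty((n, 0))
    return StackedFeatures(F, index_map, k, fs.frame_times, fs.window_s, fs.hop_s)


# ---------------------------------------------------------------------------
# Label alignment
# ---------------------------------------------------------------------------


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def align_labels_to_frames(
    labels: list[SegmentLabel],
    fs: FrameSequence | StackedFeatures,
    grouping: dict[str, tuple[str, ...]] | None = None,
) -> FrameLabels:
    """Assign each frame the phone with maximum overlap of its 50 ms window.

    Ties go to the earlier segment; frames overlapping no phone segment are
    silence.  Phone labels are passed through the grouping map (labels that
    are already grouped map to themselves).  Phrase membership uses the same
    maximum-overlap rule against the phrase tier.
    """
    grouping = grouping if grouping is not None else DEFAULT_GROUPING
    phones_tier = sorted(
        (s for s in labels if s.tier == "phone"), key=lambda s: (s.start_s, s.end_s)
    )
    phrase_tier = sorted(
        (s for s in labels if s.tier == "phrase"), key=lambda s: (s.start_s, s.end_s)
    )
    grouped_names = {g for t in grouping.values() for g in t}

    phone_out: list[str] = []
    phrase_out: list[int | None] = []
    for t0 in fs.frame_times:
        t1 = t0 + fs.window_s
        best, best_ov = SILENCE, 0.0
        for seg in phones_tier:
            if seg.start_s >= t1:
                break
            ov = _overlap(t0, t1, seg.start_s, seg.end_s)
            if ov > best_ov:  # strict: ties stay with the earlier segment
                lab = seg.label.lower()
                if lab == SILENCE or lab in grouped_names:
                    best = lab
                else:
                    g = group_phone(lab, grouping)
                    best = g[0]  # mid-diphthong frames take the first target
                best_ov = ov
        phone_out.append(best)

        pid, pid_ov = None, 0.0
        for i, seg in enumerate(phrase_tier):
            if seg.start_s >= t1:
                break
            ov = _overlap(t0, t1, seg.start_s, seg.end_s)
            if ov > pid_ov:
                pid, pid_ov = i, ov
        phrase_out.append(pid)
    return FrameLabels(phone_out, phrase_out)


# ---------------------------------------------------------------------------
# Features on disk
# ---------------------------------------------------------------------------


def write_features(
    path,
    features: StackedFeatures,
    frame_labels: FrameLabels | None,
    cfg: PipelineConfig,
) -> None:
    """Store stacked features (+labels, index map, config) in one HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("F", data=features.F, track_times=False)
        f.create_dataset("frame_times", data=features.frame_times, track_times=False)
        chans = [c.encode() for c, _ in features.feature_index_map]
        offs = np.asarray([o for _, o in features.feature_index_map])
        f.create_dataset("feature_channels", data=chans, track_times=False)
        f.create_dataset("feature_offsets", data=offs, track_times=False)
        kept = sorted({c for c, o in features.feature_index_map if o == 0})
        f.create_dataset(
            "kept_channels", data=[c.encode() for c in kept], track_times=False
        )
        if frame_labels is not None:
            f.create_dataset(
                "labels",
                data=[p.encode() for p in frame_labels.phone],
                track_times=False,
            )
            pid = np.asarray(
                [-1 if p is None else p for p in frame_labels.phrase_id], dtype=np.int64
            )
            f.create_dataset("phrase_ids", data=pid, track_times=False)
        f.attrs["config_json"] = cfg.to_json()
        f.attrs["context_frames"] = features.context_frames
        f.attrs["window_s"] = features.window_s
        f.attrs["hop_s"] = features.hop_s


def read_features(path) -> tuple[StackedFeatures, FrameLabels | None, PipelineConfig]:
    import h5py

    with h5py.File(path, "r") as f:
        F = np.asarray(f["F"])
        times = np.asarray(f["frame_times"])
        chans = [c.decode() for c in f["feature_channels"]]
        offs = [int(o) for o in f["feature_offsets"]]
        cfg = PipelineConfig.from_json(f.attrs["config_json"])
        stacked = StackedFeatures(
            F,
            list(zip(chans, offs)),
            int(f.attrs["context_frames"]),
            times,
            float(f.attrs["window_s"]),
            float(f.attrs["hop_s"]),
        )
        frame_labels = None
        if "labels" in f:
            phone = [p.decode() for p in f["labels"]]
            pid = [None if p < 0 else int(p) for p in f["phrase_ids"]]
            frame_labels = FrameLabels(phone, pid)
    return stacked, frame_labels, cfg


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def extract_features(
    rec: RawRecording,
    labels: list[SegmentLabel] | None = None,
    cfg: PipelineConfig | None = None,
    grouping: dict[str, tuple[str, ...]] | None = None,
) -> tuple[StackedFeatures, FrameLabels | None, list[str]]:
    """Run the full preprocessing chain; returns (features, frame labels, removed channels)."""
    cfg = cfg or PipelineConfig()
    rec = detrend_downsample(rec, cfg.target_rate_hz, cfg)
    rec, removed = remove_noisy_channels(rec, cfg)
    rec = car_reference(rec)
    rec = gamma_band_filter(rec, cfg)
    fs = frame_log_energy(rec, cfg)
    stacked = stack_context(fs, cfg.context_frames)
    frame_labels = (
        align_labels_to_frames(labels, stacked, grouping) if labels is not None else None
    )
    return stacked, frame_labels, removed
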