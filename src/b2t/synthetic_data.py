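"""Synthetic session generator: the test bed for every pipeline stage.

Emulates the data regime the decoder assumes — multichannel 9600 Hz
recordings in which a subset of channels carries phone-dependent
70-170 Hz (broadband gamma) amplitude patterns, 60 Hz line noise with its
120 Hz harmonic (strong on designated bad channels), inter-phrase pauses,
and exact ground-truth label tiers.

Gamma activity is amplitude-modulated band-limited noise, not an
oscillation, matching the broadband character of high-gamma power.  The
per-phone, per-channel modulation pattern is drawn once per session from
a unit Gaussian and scaled into the amplitude as exp(effect * z), so the
log-energy features the pipeline extracts are (up to estimation noise)
Gaussian per phone with planted, known mean structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.signal

from ._lexicon import builtin_lexicon, builtin_lexicon_text
from .io_session import (
    PronunciationDict,
    RawRecording,
    SegmentLabel,
    Session,
    ValidationError,
    write_labels,
    write_recording,
    write_transcript,
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the standard conditions.

    Defaults give a session comparable to a few minutes of read speech:
    40 phrases of 4-6 words, 32 channels of which 8 carry phone
    information and 2 (non-informative) are line-noise-dominated.
    Phone durations are lognormal (mean 80 ms, sd 30 ms, floored at one
    analysis window) so every phone covers at least one full frame.
    ``effect_size`` scales the planted per-phone log-amplitude pattern;
    0 removes all phone information while preserving every marginal
    property of the signal.
    """

    n_phrases: int = 40
    words_per_phrase: tuple[int, int] = (4, 6)
    n_channels: int = 32
    n_informative: int = 8
    n_bad: int = 2
    sampling_rate: float = 9600.0
    effect_size: float = 0.6
    phone_duration_mean_s: float = 0.080
    phone_duration_sd_s: float = 0.030
    phone_duration_floor_s: float = 0.050
    pause_mean_s: float = 0.9
    pause_sd_s: float = 0.2
    pause_floor_s: float = 0.4
    edge_silence_s: float = 0.5
    baseline_amplitude: float = 1.0
    background_noise_sd: float = 0.3
    line_noise_amplitude: float = 0.2
    bad_channel_factor: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_channels:
            raise ValidationError("n_informative must be <= n_channels")
        if self.n_informative + self.n_bad > self.n_channels:
            raise ValidationError("informative and bad channels must be disjoint")
        if min(self.phone_duration_mean_s, self.phone_duration_floor_s) <= 0:
            raise ValidationError("durations must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        if "words_per_phrase" in data:
            data["words_per_phrase"] = tuple(data["words_per_phrase"])
        return cls(**data)


@dataclass
class Schedule:
    """Timed phone/word/phrase segments plus the per-phrase transcript."""

    segments: list[SegmentLabel]
    phrases: list[list[str]]

    @property
    def total_duration_s(self) -> float:
        return max(s.end_s for s in self.segments)


@dataclass
class SyntheticSession:
    session: Session
    schedule: Schedule
    pattern: dict[str, np.ndarray] = field(repr=False)  # phone -> informative-channel z
    informative_channels: list[str] = field(default_factory=list)
    bad_channels: list[str] = field(default_factory=list)
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return max(float(rng.lognormal(mu, np.sqrt(sigma2))), floor)


def sample_phrase_schedule(
    cfg: SimulationConfig,
    phrases: list[list[str]],
    lexicon: PronunciationDict,
    rng: np.random.Generator,
) -> Schedule:
    """Expand phrases to timed phone/word/phrase tiers with pauses between."""
    segments: list[SegmentLabel] = []
    t = cfg.edge_silence_s
    for words in phrases:
        phrase_start = t
        for word in words:
            if word not in lexicon:
                raise ValidationError(f"word {word!r} not in the lexicon")
            word_start = t
            for phone in lexicon[word][0]:
                dur = _lognormal(
                    rng,
                    cfg.phone_duration_mean_s,
                    cfg.phone_duration_sd_s,
                    cfg.phone_duration_floor_s,
                )
                segments.append(SegmentLabel(t, t + dur, phone, "phone"))
                t += dur
            segments.append(SegmentLabel(word_start, t, word, "word"))
        segments.append(SegmentLabel(phrase_start, t, " ".join(words), "phrase"))
        t += _lognormal(rng, cfg.pause_mean_s, cfg.pause_sd_s, cfg.pause_floor_s)
    return Schedule(segments, phrases)


# ---------------------------------------------------------------------------
# Signal rendering
# ---------------------------------------------------------------------------


def render_signal(
    schedule: Schedule,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    pattern: dict[str, np.ndarray],
    informative: np.ndarray,
    bad: np.ndarray,
) -> RawRecording:
    """Render the multichannel potential for a schedule.

    Informative channels: unit-variance 70-170 Hz noise whose amplitude
    during each phone is baseline * exp(effect * z[phone, channel]), plus
    broadband background noise.  Other channels: background noise only.
    Every channel receives a 60 Hz sine and a weaker 120 Hz harmonic,
    scaled up ``bad_channel_factor``-fold on the designated bad channels.
    """
    rate = cfg.sampling_rate
    n = int(np.ceil((schedule.total_duration_s + cfg.edge_silence_s) * rate))
    names = [f"ch{c:02d}" for c in range(cfg.n_channels)]

    # per-sample amplitude-pattern index: -1 silence, else phone id
    phone_list = sorted(pattern)
    phone_id = {p: i for i, p in enumerate(phone_list)}
    idx = np.full(n, -1, dtype=np.int32)
    for seg in schedule.segments:
        if seg.tier != "phone":
            continue
        a, b = int(round(seg.start_s * rate)), int(round(seg.end_s * rate))
        idx[a:b] = phone_id[seg.label]

    # steep skirts keep the gamma carrier out of the 58-62 Hz screen band
    sos = scipy.signal.ellip(8, 0.5, 80.0, [70.0, 170.0], btype="bandpass", fs=rate, output="sos")
    tt = np.arange(n) / rate
    line60 = np.sin(2 * np.pi * 60.0 * tt)
    line120 = np.sin(2 * np.pi * 120.0 * tt)

    informative_set = set(informative.tolist())
    bad_set = set(bad.tolist())
    signal = np.empty((cfg.n_channels, n), dtype=np.float64)
    z_matrix = np.stack([pattern[p] for p in phone_list]) if phone_list else np.zeros((0, 0))
    for c in range(cfg.n_channels):
        x = cfg.background_noise_sd * rng.standard_normal(n)
        if c in informative_set:
            band = scipy.signal.sosfilt(sos, rng.standard_normal(n))
            band /= band.std()
            col = int(np.searchsorted(informative, c))
            amp = np.full(n, cfg.baseline_amplitude)
            if phone_list:
                speech = idx >= 0
                amp[speech] = cfg.baseline_amplitude * np.exp(
                    cfg.effect_size * z_matrix[idx[speech], col]
                )
            x = x + amp * band
        # line-noise pickup varies channel to channel, as on a real grid
        amp60 = (
            cfg.line_noise_amplitude
            * float(rng.uniform(0.5, 1.5))
            * (cfg.bad_channel_factor if c in bad_set else 1.0)
        )
        phase = rng.uniform(0, 2 * np.pi)
        x = x + amp60 * np.sin(2 * np.pi * 60.0 * tt + phase) + 0.3 * amp60 * line120
        signal[c] = x
    return RawRecording(signal, rate, names, "synthetic")


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------


def generate_session(
    cfg: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
    lexicon: PronunciationDict | None = None,
) -> SyntheticSession:
    """Generate a full synthetic session; optionally write it to ``out_dir``.

    Deterministic per seed: the same config regenerates byte-identical
    files.  Emits recording.h5, labels.tsv, transcript.txt, lexicon.txt
    and ground_truth.json when ``out_dir`` is given.
    """
    cfg = cfg or SimulationConfig()
    lexicon = lexicon or builtin_lexicon()
    rng = np.random.default_rng(cfg.seed)

    words = lexicon.words
    phrases = []
    lo, hi = cfg.words_per_phrase
    for _ in range(cfg.n_phrases):
        k = int(rng.integers(lo, hi + 1))
        phrases.append([words[int(i)] for i in rng.integers(0, len(words), size=k)])

    schedule = sample_phrase_schedule(cfg, phrases, lexicon, rng)

    used_phones = sorted(
        {s.label for s in schedule.segments if s.tier == "phone"}
    )
    channels = rng.permutation(cfg.n_channels)
    informative = np.sort(channels[: cfg.n_informative])
    bad = np.sort(channels[cfg.n_informative : cfg.n_informative + cfg.n_bad])
    pattern = {p: rng.standard_normal(cfg.n_informative) for p in used_phones}

    rec = render_signal(schedule, cfg, rng, pattern, informative, bad)
    transcript = [w for phrase in phrases for w in phrase]
    session = Session(rec, schedule.segments, transcript)
    out = SyntheticSession(
        session,
        schedule,
        pattern,
        [rec.channel_names[c] for c in informative],
        [rec.channel_names[c] for c in bad],
        cfg,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_recording(rec, out_dir / "recording.h5")
        write_labels(schedule.segments, out_dir / "labels.tsv")
        write_transcript(phrases, out_dir / "transcript.txt")
        (out_dir / "lexicon.txt").write_text(builtin_lexicon_text())
        truth = {
            "informative_channels": out.informative_channels,
            "bad_channels": out.bad_channels,
            "pattern": {p: v.tolist() for p, v in pattern.items()},
            "config": json.loads(cfg.to_json()),
        }
        (out_dir / "ground_truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n"
        )
    return out
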