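"""Session file formats, domain containers and the pipeline configuration.

A *session* is one continuous recording of a subject reading text aloud:
a multichannel electrical-potential matrix (HDF5), time-aligned label
tiers (TSV: phone / word / phrase segments), and the transcript of the
words that were read (plain text).  The pronunciation lexicon is a
CMUdict-style text file mapping words to fine-phone sequences.

All readers validate their inputs and all writer/reader pairs round-trip
canonical files byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np

from . import phones

TIERS = ("phone", "word", "phrase")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """Contents are well-formed but violate a domain invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class RawRecording:
    """Multichannel electrical potential, channels x samples, in microvolts."""

    signal: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be a 2-D channels x samples matrix")
        n_channels, n_samples = self.signal.shape
        if n_channels < 1 or n_samples < 1:
            raise ValidationError("signal must have at least 1 channel and 1 sample")
        if not np.isfinite(self.signal).all():
            raise ValidationError("signal contains non-finite samples")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != n_channels:
            raise ValidationError("channel_names length must equal n_channels")
        if len(set(self.channel_names)) != n_channels:
            raise ValidationError("channel_names must be distinct")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class SegmentLabel:
    """One labelled time interval on one tier, seconds, half-open [start, end)."""

    start_s: float
    end_s: float
    label: str
    tier: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.end_s):
            raise ValidationError(
                f"segment must satisfy 0 <= start < end, got [{self.start_s}, {self.end_s})"
            )
        if not self.label:
            raise ValidationError("segment label must be non-empty")
        if self.tier not in TIERS:
            raise ValidationError(f"unknown tier {self.tier!r}, expected one of {TIERS}")


@dataclass
class Session:
    """One recording with its label tiers and transcript (ordered word list)."""

    recording: RawRecording
    labels: list[SegmentLabel]
    transcript: list[str]

    def tier(self, name: str) -> list[SegmentLabel]:
        return [s for s in self.labels if s.tier == name]


class PronunciationDict:
    """Word -> list of grouped-phone sequences (>= 1 pronunciation each).

    Lookup is case-insensitive; phones are stored in the grouped inventory.
    """

    def __init__(self, entries: dict[str, list[tuple[str, ...]]] | None = None):
        self._entries: dict[str, list[tuple[str, ...]]] = {}
        for word, prons in (entries or {}).items():
            for p in prons:
                self.add(word, p)

    def add(self, word: str, pron: Iterable[str]) -> None:
        pron = tuple(pron)
        if not pron:
            raise ValidationError(f"empty pronunciation for {word!r}")
        self._entries.setdefault(word.lower(), [])
        if pron not in self._entries[word.lower()]:
            self._entries[word.lower()].append(pron)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._entries

    def __getitem__(self, word: str) -> list[tuple[str, ...]]:
        return self._entries[word.lower()]

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def words(self) -> list[str]:
        return sorted(self._entries)

    def restrict(self, vocabulary: Iterable[str]) -> "PronunciationDict":
        """Sub-lexicon containing only the given words (all must be present)."""
        sub = PronunciationDict()
        for w in vocabulary:
            if w not in self:
                raise ValidationError(f"word {w!r} not in lexicon")
            for pron in self[w]:
                sub.add(w, pron)
        return sub

    def phone_set(self) -> set[str]:
        return {ph for prons in self._entries.values() for p in prons for ph in p}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, JSON-serializable, unknown keys rejected.

    Defaults follow the published processing chain where it states a value
    (50/25 ms framing, +-4 context frames, 70-170 Hz band, 118-122 Hz notch
    of order 13, 58-62 Hz line-noise screen, selection threshold t = -0.05);
    the remainder are conventional values documented in docs/methods.md.
    """

    # framing
    window_s: float = 0.050
    hop_s: float = 0.025
    context_frames: int = 4
    # rates and filters
    target_rate_hz: float = 600.0
    gamma_low_hz: float = 70.0
    gamma_high_hz: float = 170.0
    gamma_filter_order: int = 8
    passband_ripple_db: float = 0.5
    stopband_atten_db: float = 40.0
    notch_low_hz: float = 118.0
    notch_high_hz: float = 122.0
    notch_order: int = 13
    line_noise_low_hz: float = 58.0
    line_noise_high_hz: float = 62.0
    zero_phase: bool = False
    log_energy_floor: float = 1e-12
    # discriminability / selection
    kl_mode: str = "eq1_verbatim"  # or "natural"
    kl_normalization: str = "mean"  # or "sum"
    selection_threshold: float = -0.05
    selection_fallback_frac: float = 0.05
    n_shifts: int = 1
    # models
    variance_floor: float = 1e-6
    min_frames_per_phone: int = 5
    # decoding
    lm_weight: float = 1.0
    word_insertion_penalty: float = 0.0
    allow_silence_in_decoding: bool = True
    min_phone_duration_frames: int = 1
    default_mean_phone_frames: float = 3.0
    min_self_loop_prob: float = 0.05
    max_self_loop_prob: float = 0.999
    # misc
    rng_seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_recording(path: str | Path) -> RawRecording:
    """Read a RawRecording from HDF5 (dataset /signal + attributes)."""
    with h5py.File(path, "r") as f:
        if "signal" not in f:
            raise FormatError(f"{path}: missing dataset '/signal'")
        dset = f["signal"]
        for attr in ("sampling_rate_hz", "channel_names", "session_id"):
            if attr not in dset.attrs:
                raise FormatError(f"{path}: missing attribute {attr!r} on /signal")
        signal = np.asarray(dset, dtype=np.float64)
        rate = float(dset.attrs["sampling_rate_hz"])
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in dset.attrs["channel_names"]
        ]
        session_id = str(dset.attrs["session_id"])
    return RawRecording(signal, rate, names, session_id)


def write_recording(rec: RawRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        # track_times=False keeps files byte-identical across rewrites
        dset = f.create_dataset("signal", data=rec.signal, track_times=False)
        dset.attrs["sampling_rate_hz"] = float(rec.sampling_rate)
        dset.attrs["channel_names"] = [n.encode() for n in rec.channel_names]
        dset.attrs["session_id"] = rec.session_id


_LABEL_HEADER = "start_s\tend_s\tlabel\ttier"


def read_labels(path: str | Path) -> list[SegmentLabel]:
    """Read TSV label segments; sorted by (tier, start); overlap in a tier errors."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != _LABEL_HEADER:
        raise FormatError(f"{path}: expected header {_LABEL_HEADER!r}")
    segments: list[SegmentLabel] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{ln}: expected 4 tab-separated fields")
        start, end, label, tier = parts
        segments.append(SegmentLabel(float(start), float(end), label, tier))
    segments.sort(key=lambda s: (s.tier, s.start_s, s.end_s))
    _check_no_overlap(segments)
    return segments


def _check_no_overlap(sorted_segments: list[SegmentLabel]) -> None:
    prev: SegmentLabel | None = None
    for seg in sorted_segments:
        if prev is not None and seg.tier == prev.tier and seg.start_s < prev.end_s - 1e-12:
            raise ValidationError(
                f"overlapping {seg.tier!r} segments: "
                f"[{prev.start_s}, {prev.end_s}) and [{seg.start_s}, {seg.end_s})"
            )
        prev = seg


def write_labels(segments: list[SegmentLabel], path: str | Path) -> None:
    ordered = sorted(segments, key=lambda s: (s.tier, s.start_s, s.end_s))
    rows = [_LABEL_HEADER]
    rows += [f"{s.start_s!r}\t{s.end_s!r}\t{s.label}\t{s.tier}" for s in ordered]
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_transcript(path: str | Path) -> list[list[str]]:
    """Transcript file: one phrase per line, lowercase word tokens."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        words = line.split()
        if words:
            out.append([w.lower() for w in words])
    return out


def write_transcript(phrases: list[list[str]], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(" ".join(p) for p in phrases) + "\n", encoding="utf-8"
    )


def read_pronunciation_dict(
    path: str | Path, grouping: dict[str, tuple[str, ...]] | None = None
) -> PronunciationDict:
    """Read a CMUdict-style lexicon and map fine phones to the grouped set.

    Each line is ``WORD ph1 ph2 ...``; repeated word lines add alternate
    pronunciations.  Every phone token must be in the grouping map (fine
    ARPABET inventory, user-extensible); diphthongs expand in place.
    """
    grouping = grouping if grouping is not None else phones.DEFAULT_GROUPING
    lex = PronunciationDict()
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        word, fine = tokens[0], tokens[1:]
        if not fine:
            raise FormatError(f"{path}:{ln}: word {word!r} has no phones")
        grouped: list[str] = []
        for tok in fine:
            t = tok.lower()
            if t not in grouping:
                raise ValidationError(
                    f"{path}:{ln}: phone token {tok!r} not in the phone inventory"
                )
            grouped.extend(phones.group_phone(t, grouping))
        lex.add(word, grouped)
    return lex


def write_pronunciation_dict(lex: PronunciationDict, path: str | Path) -> None:
    """Write grouped-phone lexicon lines (already-grouped tokens)."""
    rows = []
    for word in lex.words:
        for pron in lex[word]:
            rows.append(word.upper() + "  " + " ".join(pron))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def load_session(directory: str | Path) -> Session:
    """Load ``recording.h5``, ``labels.tsv`` and ``transcript.txt`` from a dir."""
    directory = Path(directory)
    rec = read_recording(directory / "recording.h5")
    labels = read_labels(directory / "labels.tsv")
    transcript = [w for phrase in read_transcript(directory / "transcript.txt") for w in phrase]
    session = Session(rec, labels, transcript)
    _validate_session(session)
    return session


def _validate_session(session: Session) -> None:
    words = [s.label for s in sorted(session.tier("word"), key=lambda s: s.start_s)]
    if words != session.transcript[: len(words)] or len(words) != len(session.transcript):
        raise ValidationError("word-tier labels do not match the transcript order")
    phrases = sorted(session.tier("phrase"), key=lambda s: s.start_s)
    for ph in sorted(session.tier("phone"), key=lambda s: s.start_s):
        inside = any(
            p.start_s - 1e-9 <= ph.start_s and ph.end_s <= p.end_s + 1e-9 for p in phrases
        )
        if not inside:
            raise ValidationError(
                f"phone segment [{ph.start_s}, {ph.end_s}) lies outside every phrase"
            )
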