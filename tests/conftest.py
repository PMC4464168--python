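import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import b2t
from b2t._lexicon import builtin_lexicon
from b2t.synthetic_data import SimulationConfig, generate_session

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

logging.getLogger("b2t").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def lexicon():
    return builtin_lexicon()


@pytest.fixture(scope="session")
def small_session():
    """High-SNR session small enough for per-test use (10 phrases, 12 channels)."""
    cfg = SimulationConfig(
        n_phrases=14,
        n_channels=12,
        n_informative=6,
        n_bad=2,
        words_per_phrase=(4, 6),
        pause_mean_s=0.6,
        seed=11,
    )
    sim = generate_session(cfg)
    pcfg = b2t.PipelineConfig()
    stacked, frame_labels, removed = b2t.extract_features(
        sim.session.recording, sim.session.labels, pcfg
    )
    return {
        "sim": sim,
        "cfg": pcfg,
        "features": stacked,
        "frame_labels": frame_labels,
        "removed": removed,
    }


@pytest.fixture(scope="session")
def default_eval(lexicon):
    """The standard-conditions session (40 phrases, 32 channels, 8 informative,
    seed 7) evaluated leave-one-phrase-out with the dictionary-size sweep."""
    sim = generate_session(SimulationConfig(seed=7))
    pcfg = b2t.PipelineConfig()
    stacked, frame_labels, removed = b2t.extract_features(
        sim.session.recording, sim.session.labels, pcfg
    )
    report = b2t.leave_one_phrase_out(
        stacked,
        frame_labels,
        sim.schedule.phrases,
        lexicon,
        pcfg,
        dict_size=10,
        sizes=[10, 20, 50],
        seed=7,
    )
    return {"sim": sim, "report": report, "features": stacked, "frame_labels": frame_labels}


def run_null_session(seed: int) -> float:
    """One zero-effect session through the full pipeline; returns the
    real-vs-randomized frame-accuracy p-value."""
    cfg = SimulationConfig(
        n_phrases=8,
        n_channels=8,
        n_informative=4,
        n_bad=0,
        words_per_phrase=(3, 4),
        pause_mean_s=0.5,
        effect_size=0.0,
        seed=seed,
    )
    sim = generate_session(cfg)
    pcfg = b2t.PipelineConfig()
    stacked, frame_labels, _ = b2t.extract_features(
        sim.session.recording, sim.session.labels, pcfg
    )
    report = b2t.leave_one_phrase_out(
        stacked,
        frame_labels,
        sim.schedule.phrases,
        builtin_lexicon(),
        pcfg,
        dict_size=8,
        seed=seed,
    )
    return report.frame_acc_p_value


@pytest.fixture(scope="session")
def null_calibration_pvalues():
    """Frame-accuracy p-values from 50 zero-effect sessions (the no-signal null)."""
    return np.array([run_null_session(1000 + i) for i in range(50)])
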