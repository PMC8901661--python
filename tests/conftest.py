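"""Shared fixtures: synthetic datasets and a trained band-task CNN.

Session scope keeps the expensive artifacts (audio synthesis, feature
extraction, spectrograms, CNN training) computed once per run.
"""

import numpy as np
import pytest

from vocalence import features, synth
from vocalence.classifier import SpectrogramConfig, TrainConfig, spectrogram_stack, train_classifier
from vocalence.synth import CallRecording

#: expected sign of the positive-vs-negative valence contrast per call type,
#: mirroring the four directional patterns the generator encodes
EXPECTED_DIRECTIONS = {
    "LF": {"Dur": -1, "AmpModRate": -1, "Q25": +1, "Q50": +1, "Q75": +1,
           "FPeak": +1, "WienEntropy": -1, "Harmonicity": +1},
    "HF": {"Dur": -1, "AmpModRate": -1, "Q25": -1, "Q50": -1, "Q75": -1,
           "FPeak": -1, "WienEntropy": +1, "Harmonicity": -1},
}


@pytest.fixture(scope="session")
def cell_data():
    """Balanced 200-calls-per-cell dataset (LF/HF x negative/positive) with
    its extracted feature table."""
    spec = synth.default_spec(rng_seed=1)
    calls, meta = synth.synthesize_cells(spec, 200)
    table = features.extract_table(calls)
    merged = table.merge(meta[["call_id", "synth_call_type"]], on="call_id")
    return calls, meta, merged


@pytest.fixture(scope="session")
def mixed_dataset():
    """Imbalanced 600-call dataset drawn from the default context weights."""
    spec = synth.default_spec(rng_seed=2, n_calls=600)
    calls, meta = synth.synthesize_dataset(spec)
    table = features.extract_table(calls)
    return calls, meta, table


def make_band_call(rng, i, low_band, sr=8000, dur=0.5):
    """A call whose energy sits in one of two disjoint spectral bands."""
    n = int(dur * sr)
    t = np.arange(n) / sr
    f = rng.uniform(*((500.0, 900.0) if low_band else (2500.0, 2900.0)))
    w = np.sin(2 * np.pi * f * t) + 0.05 * rng.standard_normal(n)
    return CallRecording(
        call_id=f"band{i:04d}", waveform=w, sample_rate=sr, pig_id="pig000",
        team_id="team", age_days=10, age_class=1, context="Isolation" if low_band else "Reunion",
        valence="negative" if low_band else "positive",
    )


@pytest.fixture(scope="session")
def band_task():
    """240 two-band calls, their spectrogram stack, and labels."""
    rng = np.random.default_rng(42)
    calls = [make_band_call(rng, i, i % 2 == 0) for i in range(240)]
    cfg = SpectrogramConfig(hop_fraction=0.25)
    X = spectrogram_stack(calls, cfg)
    labels = np.array([c.valence for c in calls])
    return calls, X, labels, cfg


@pytest.fixture(scope="session")
def trained_band_model(band_task):
    _, X, labels, _ = band_task
    cfg = TrainConfig(task="valence", epochs=4, n_trials=1, rng_seed=0)
    model, classes, trials, _ = train_classifier(X, labels, cfg)
    return model, classes, trials
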