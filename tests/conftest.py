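"""Shared fixtures: small synthetic cohorts and toy models.

Everything is generated at test time from seeds; session scope keeps the
expensive video-rendering cohorts shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pawprint as pp
from pawprint.features import FeatureBackendSpec, FeatureMatrix


@pytest.fixture(scope="session")
def grid() -> pp.OpenFieldGrid:
    return pp.build_grid()


@pytest.fixture(scope="session")
def small_cohort():
    """Tracks-only cohort (no rendering): 8 + 8 trials, default conditions."""
    cfg = pp.SynthConfig(n_trials_per_group=8, seed=42)
    manifest, trials = pp.generate_cohort(cfg)
    return cfg, manifest, trials


def make_planted_feature_cohort(
    n_per_group: int = 20,
    n_features: int = 12,
    n_frames: int = 60,
    period: int = 11,
    amplitude: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, FeatureMatrix]]:
    """Feature-level cohort with a temporal planted signal.

    Group B carries a bump of ``amplitude`` on half the features at
    frames 0, period, 2*period, ... on top of unit Gaussian noise; group
    A is pure noise.  Cheap stand-in for the full video pipeline when a
    test only exercises the classifier/relevance machinery.
    """
    rng = np.random.default_rng(seed)
    spec = FeatureBackendSpec(
        name="synthetic-planted", n_features=n_features,
        deterministic=True, requires_pretrained_weights=False,
    )
    rows, feats = [], {}
    for g, gname in enumerate(("control", "mpne")):
        for i in range(n_per_group):
            values = rng.normal(size=(n_features, n_frames))
            if gname == "mpne":
                values[: n_features // 2, ::period] += amplitude
            tid = f"{gname}_{i:03d}"
            feats[tid] = FeatureMatrix(values=values, backend=spec, trial_id=tid)
            rows.append(
                {"trial_id": tid, "animal_id": f"{gname}_a{i}",
                 "litter_id": f"{gname}_L{i // 5}", "group": gname,
                 "video_path": "", "track_path": "", "start_offset_frames": 0}
            )
    return pd.DataFrame(rows), feats


@pytest.fixture(scope="session")
def planted_feature_cohort():
    return make_planted_feature_cohort()


def make_graded_feature_cohort(
    n_per_group: int = 16,
    n_features: int = 8,
    n_frames: int = 20,
    seed: int = 9,
) -> tuple[pd.DataFrame, dict[str, FeatureMatrix]]:
    """Feature-level cohort whose group signal sits at a few frames with
    *distinct* amplitudes, so per-frame importance has a meaningful
    ground-truth ranking (used against the occlusion oracle)."""
    rng = np.random.default_rng(seed)
    spec = FeatureBackendSpec(
        name="synthetic-graded", n_features=n_features,
        deterministic=True, requires_pretrained_weights=False,
    )
    planted = {2: 0.75, 7: 1.5, 12: 2.25, 17: 3.0}
    rows, feats = [], {}
    for gname in ("control", "mpne"):
        for i in range(n_per_group):
            values = rng.normal(size=(n_features, n_frames))
            if gname == "mpne":
                for frame, amp in planted.items():
                    values[: n_features // 2, frame] += amp
            tid = f"{gname}_{i:03d}"
            feats[tid] = FeatureMatrix(values=values, backend=spec, trial_id=tid)
            rows.append(
                {"trial_id": tid, "animal_id": tid, "litter_id": tid,
                 "group": gname, "video_path": "", "track_path": "",
                 "start_offset_frames": 0}
            )
    return pd.DataFrame(rows), feats


@pytest.fixture(scope="session")
def tiny_trained_lstm(planted_feature_cohort):
    """A small LSTM trained on the planted feature cohort."""
    manifest, feats = planted_feature_cohort
    config = pp.ModelConfig(
        lstm_units=16, epochs=40, batch_size=8, learning_rate=3e-3, seed=3
    )
    model = pp.train_fold(
        [feats[t] for t in manifest.trial_id],
        manifest.group.to_numpy(),
        config=config,
    )
    return model, manifest, feats
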