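"""Shared fixtures: small synthetic subjects and their feature tables.

The heavier pipeline fixtures are session-scoped because the Choi-Williams
transform of every window of a 60 s trial is the dominant cost of the suite.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tfemotion import classify_eval, features, io_dataset, synth
from tfemotion.cli import label_table

#: Reduced problem sizes for cross-validated pipeline checks: one subject,
#: twenty 63 s trials, one symmetric channel pair, and a coarse SVM grid.
#: Twenty trials give ten grouped folds holding one trial of each class, so
#: the training split stays class-balanced in every fold.
PIPELINE_SEED = 42
PIPELINE_TRIALS = 20
PIPELINE_PAIR = "C1:T7-T8"
PIPELINE_GRID = dict(c_grid=(1.0, 32.0), gamma_grid=(2.0**-7, 2.0**-3), inner_folds=3)


def make_subject_table(arousal_effect: float, valence_effect: float, seed: int = PIPELINE_SEED):
    """Features of one synthetic subject on one symmetric channel pair."""
    config = synth.SynthConfig(
        n_subjects=1,
        trials_per_subject=PIPELINE_TRIALS,
        seed=seed,
        scheme="1D-2CLS-arousal",
        arousal_effect=arousal_effect,
        valence_effect=valence_effect,
    )
    trials = synth.generate_dataset(config)
    pair = io_dataset.channel_config(PIPELINE_PAIR)
    return features.extract_feature_table(trials, pair)


def run_subject_cv(table, labels, seed=1):
    """Grouped, leakage-safe 10-fold CV with top-25% selection."""
    pair = io_dataset.channel_config(PIPELINE_PAIR)
    columns = list(features.feature_names_for(pair))
    return classify_eval.cross_validate_subject(
        table[columns].to_numpy(),
        np.asarray(labels),
        scheme="1D-2CLS-arousal",
        seed=seed,
        selection_scenario="top25",
        groups=table["trial_id"].to_numpy(),
        **PIPELINE_GRID,
    )


@pytest.fixture(scope="session")
def subject_table():
    """Feature table of a subject generated with the default effect sizes."""
    return make_subject_table(
        arousal_effect=synth.SynthConfig.arousal_effect,
        valence_effect=synth.SynthConfig.valence_effect,
    )


@pytest.fixture(scope="session")
def zero_effect_table():
    """Feature table of a subject whose ratings have no effect on the EEG."""
    return make_subject_table(arousal_effect=0.0, valence_effect=0.0)


@pytest.fixture(scope="session")
def subject_labels(subject_table):
    return label_table(subject_table, "1D-2CLS-arousal").to_numpy()


@pytest.fixture(scope="session")
def zero_effect_labels(zero_effect_table):
    return label_table(zero_effect_table, "1D-2CLS-arousal").to_numpy()
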