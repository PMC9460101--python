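"""Shared fixtures: synthetic corpora and trained desk-scale models.

The heavier fixtures are session-scoped so that end-to-end training runs
once and is reused by every test that inspects the trained system.
"""

from __future__ import annotations

import numpy as np
import pytest

from sincvoice.networks import compact_cnn1d_spec, compact_sincnet_spec
from sincvoice.pipeline import Hyperparams, split_dataset, train_on_split
from sincvoice.vowelsynth import SynthParams, make_dataset

FOURCLASS_ORDER = ["FD", "Neo", "Pho", "VP"]


def _split_utts(manifest, seed):
    ids = manifest["utterance_id"].tolist()
    labels = manifest["label"].tolist()
    plan = split_dataset(ids, 0.8, seed=seed, labels=labels)
    by = {w.utterance_id: w for w in manifest["waveform"]}
    return [by[u] for u in plan.train_val_ids], [by[u] for u in plan.test_ids]


@pytest.fixture(scope="session")
def fourclass_dataset():
    """Default 4-class synthetic task: 40 utterances/class, 1 s, 16 kHz."""
    params = SynthParams(duration_s=1.0, sample_rate=16000.0)
    return make_dataset(
        {lbl: 40 for lbl in FOURCLASS_ORDER}, seed=11, params=params
    )


@pytest.fixture(scope="session")
def trained_sincnet(fourclass_dataset):
    """Compact SincNet trained on the default 4-class task (seed 11).

    Returns (model, train_state, test_utterances, class_order).
    """
    train_val, test = _split_utts(fourclass_dataset, seed=11)
    rng = np.random.default_rng(11)
    order = rng.permutation(len(train_val))
    val = [train_val[i] for i in order[:16]]
    train = [train_val[i] for i in order[16:]]
    model, state = train_on_split(
        compact_sincnet_spec(4), train, val, FOURCLASS_ORDER,
        Hyperparams(epochs=20), seed=11,
    )
    return model, state, test, FOURCLASS_ORDER


@pytest.fixture(scope="session")
def small_trained_pair():
    """A (SincNet, CNN1D) pair trained briefly on a reduced 4-class task.

    Used by interpretability tests that only need plausibly trained front
    ends, not converged classifiers.
    """
    params = SynthParams(duration_s=1.0, sample_rate=16000.0)
    manifest = make_dataset({lbl: 12 for lbl in FOURCLASS_ORDER}, seed=5,
                            params=params)
    utts = manifest["waveform"].tolist()
    rng = np.random.default_rng(5)
    order = rng.permutation(len(utts))
    val = [utts[i] for i in order[:8]]
    train = [utts[i] for i in order[8:]]
    hp = Hyperparams(epochs=4)
    sinc, _ = train_on_split(compact_sincnet_spec(4), train, val,
                             FOURCLASS_ORDER, hp, seed=5)
    cnn, _ = train_on_split(compact_cnn1d_spec(4), train, val,
                            FOURCLASS_ORDER, hp, seed=5)
    return sinc, cnn
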