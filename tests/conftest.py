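"""Shared fixtures.

The trained bubble detector is expensive (several minutes of CPU), so it
is built once per session and shared between the detector unit tests and
the end-to-end acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from hbsense import bubblenet as bn


@pytest.fixture(scope="session")
def benchmark_splits():
    """The default synthetic benchmark, rendered and split once."""
    scenarios, ids = bn.default_benchmark_scenarios(seed=0)
    config = bn.NetConfig(seed=0)
    seqs = bn.prepare_sequences(scenarios, config, ids=ids)
    train, val, test = bn.make_training_set(seqs, seed=0)
    return {"train": train, "val": val, "test": test,
            "scenarios": dict(zip(ids, scenarios)), "config": config}


@pytest.fixture(scope="session")
def trained_detector(benchmark_splits):
    """The recurrent detector trained on the benchmark's train split."""
    config = benchmark_splits["config"]
    detector, metrics = bn.train_detector(
        config, benchmark_splits["train"], benchmark_splits["val"], seed=0
    )
    return detector, metrics


@pytest.fixture(scope="session")
def trained_baseline(benchmark_splits):
    """Per-frame-only baseline: same conv stack, no recurrence. A short
    schedule suffices — its role is to show what single frames cannot do."""
    config = bn.NetConfig(seed=0, recurrent=False, max_epochs=15, patience=6)
    baseline, metrics = bn.train_detector(
        config, benchmark_splits["train"], benchmark_splits["val"], seed=0
    )
    return baseline, metrics


@pytest.fixture(scope="session")
def static_pair_set():
    """Matched static-bubble / lower-concentration pairs (held out)."""
    scenarios, ids = bn.static_pair_scenarios(seed=1000, n_pairs=6)
    config = bn.NetConfig(seed=0)
    return bn.prepare_sequences(scenarios, config, ids=ids)


def ambiguous_frame_accuracy(model, pair_seqs) -> float:
    """Per-frame accuracy restricted to the ambiguous part of the matched
    pairs: frames after the entry transient (first third of the sequence),
    where bubble and no-bubble frames are statistically identical."""
    hits = total = 0
    for s in pair_seqs:
        probs = model.net.forward(s.frames)
        k = len(s.frames) // 3
        pred = probs[k:] > bn.DECISION_THRESHOLD
        hits += int(np.sum(pred == s.labels[k:]))
        total += len(pred)
    return hits / total
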