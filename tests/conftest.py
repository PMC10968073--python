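"""Shared fixtures: one desk-scale synthetic cohort reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hasdetect.core import EegRecord
from hasdetect.synth import (
    COHORT_COMPOSITION,
    SyntheticCohortConfig,
    generate_background,
    generate_cohort,
    generate_has_event,
    make_classification_dataset,
)


@pytest.fixture(scope="session")
def desk_config() -> SyntheticCohortConfig:
    return SyntheticCohortConfig.desk(seed=7)


@pytest.fixture(scope="session")
def desk_cohort(desk_config):
    return generate_cohort(desk_config)


@pytest.fixture(scope="session")
def desk_dataset(desk_config, desk_cohort):
    records, truth = desk_cohort
    return make_classification_dataset(records, truth, desk_config)


@pytest.fixture(scope="session")
def table3_manifest() -> pd.DataFrame:
    """A manifest with the reference study's exact per-group segment counts."""
    rows = []
    for g, comp in COHORT_COMPOSITION.items():
        for ch_i, ch in enumerate(("left", "right")):
            rows += [{"label": "HAS", "group": g, "channel": ch}] * comp["seizures"][ch_i]
            rows += [{"label": "non-HAS", "group": g, "channel": ch}] * comp[
                "non_seizures"
            ][ch_i]
    return pd.DataFrame(rows)


@pytest.fixture()
def burst_record():
    """A 5-min record with one long peaked-envelope seizure at a known center."""

    def _make(seed: int, duration_s: float = 75.0, amplitude: float = 100.0):
        fs = 256
        rng = np.random.default_rng(seed)
        bg = generate_background(300, "term", seed=seed + 1000, rms_uV=5.0)
        x = bg.samples.copy()
        wav = generate_has_event(
            duration_s, amplitude, (0.5, 4.0), fs, seed=seed + 2000, envelope="peaked"
        )
        onset = int(rng.uniform(70, 180) * fs)
        x[onset : onset + wav.size] += wav
        true_center = onset + int(np.argmax(np.abs(wav)))
        return EegRecord(samples=x, fs=fs), true_center

    return _make
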