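"""Synthetic cohort generator: determinism, definitional compliance,
spectral structure, composition."""

import numpy as np
import pytest
from scipy.signal import periodogram, welch

from hasdetect.core import EegRecord
from hasdetect.synth import (
    COHORT_COMPOSITION,
    SyntheticCohortConfig,
    generate_artifact,
    generate_background,
    generate_cohort,
    generate_has_event,
    make_classification_dataset,
)


class TestBackground:
    def test_deterministic_under_fixed_seed(self):
        a = generate_background(600, "preterm", seed=1)
        b = generate_background(600, "preterm", seed=1)
        assert np.array_equal(a.samples, b.samples)

    def test_term_has_more_high_frequency_power_than_preterm(self):
        """Term EEG is broader-band; preterm concentrates in slow delta."""
        term = generate_background(600, "term", seed=1, rms_uV=10.0)
        pre = generate_background(600, "preterm", seed=1, rms_uV=10.0)
        f, p_term = welch(term.samples, fs=256, nperseg=4096)
        _, p_pre = welch(pre.samples, fs=256, nperseg=4096)
        # matched total power by construction (equal RMS)
        assert np.isclose(np.std(term.samples), np.std(pre.samples), rtol=1e-6)
        assert p_term[f > 8].sum() > 3 * p_pre[f > 8].sum()

    def test_preterm_background_is_discontinuous(self):
        """Burst/interburst alternation shows as bimodal short-time RMS."""
        pre = generate_background(600, "preterm", seed=3, rms_uV=10.0)
        seg_rms = np.sqrt(
            np.mean(pre.samples[: 600 * 256].reshape(-1, 256) ** 2, axis=1)
        )
        # suppressed seconds should be markedly quieter than active ones
        assert np.percentile(seg_rms, 90) > 3 * np.percentile(seg_rms, 10)

    def test_rms_is_parameterized_and_below_seizure_floor(self):
        bg = generate_background(120, "term", seed=0, rms_uV=12.0)
        assert np.isclose(np.sqrt(np.mean(bg.samples**2)), 12.0, rtol=1e-6)
        assert np.abs(bg.samples).mean() < 20.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            generate_background(0, "term", seed=1)


class TestHasEvent:
    def test_below_definitional_minimums_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            generate_has_event(9.0, 50.0)
        with pytest.raises(ValueError, match="20"):
            generate_has_event(30.0, 20.0)

    @pytest.mark.parametrize("envelope", ["waxing", "peaked"])
    def test_peak_amplitude_and_determinism(self, envelope):
        w1 = generate_has_event(30, 100, (0.5, 4), 256, seed=7, envelope=envelope)
        w2 = generate_has_event(30, 100, (0.5, 4), 256, seed=7, envelope=envelope)
        assert np.array_equal(w1, w2)
        assert np.isclose(np.max(np.abs(w1)), 100.0, rtol=0.05)

    def test_dominant_rhythm_inside_delta_band(self):
        w = generate_has_event(30, 100, (0.5, 4.0), 256, seed=7)
        f, p = periodogram(w, fs=256)
        assert 0.5 <= f[np.argmax(p)] <= 4.0

    def test_envelope_waxes_and_wanes(self):
        w = generate_has_event(40, 100, (0.5, 4.0), 256, seed=3)
        env = np.abs(w).reshape(-1, 256).max(axis=1)  # 1 s envelope
        core = env[2:-2]
        assert core.max() > 1.5 * core.min()  # modulated, not flat


class TestArtifact:
    def test_kinds_differ_spectrally(self):
        mov = generate_artifact(5, 100, "movement", seed=1)
        ele = generate_artifact(5, 100, "electronic", seed=1)
        f, p_m = periodogram(mov, fs=256)
        _, p_e = periodogram(ele, fs=256)
        assert f[np.argmax(p_m)] < 3.0  # slow lurch
        assert p_e[f > 20].sum() > p_m[f > 20].sum()  # broadband content

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_artifact(5, 100, "ocular", seed=1)


class TestCohort:
    def test_sham_group_has_zero_seizures(self, desk_cohort):
        _, truth = desk_cohort
        g3 = [
            e
            for (animal, _), evs in truth.events.items()
            for e in evs
            if animal.startswith("G3") and e.event_type == "HAS"
        ]
        assert g3 == []

    def test_requesting_seizures_in_sham_rejected(self):
        with pytest.raises(ValueError, match="G3"):
            SyntheticCohortConfig.desk(has_segment_targets={"G3": 5})

    def test_truth_covers_every_inserted_event(self, desk_config, desk_cohort):
        """Every annotated HAS re-measures above the definitional floor."""
        records, truth = desk_cohort
        by_key = {(r.animal_id, r.channel): r for r in records}
        n_checked = 0
        for (animal, ch), events in truth.events.items():
            rec = by_key[(animal, ch)]
            prev_offset = 0
            for ev in sorted(events, key=lambda e: e.onset_sample):
                assert ev.onset_sample >= prev_offset, "events overlap"
                prev_offset = ev.offset_sample
                if ev.event_type != "HAS":
                    continue
                dur = (ev.offset_sample - ev.onset_sample) / rec.fs
                chunk = rec.samples[ev.onset_sample : ev.offset_sample]
                assert dur >= 10.0
                assert np.ptp(chunk) > 2 * 20.0  # peak-to-peak over +/-20 uV
                n_checked += 1
        assert n_checked == truth.n_events("HAS") > 0

    def test_determinism_byte_for_byte(self, desk_config, desk_cohort):
        records, truth = desk_cohort
        records2, truth2 = generate_cohort(desk_config)
        assert all(
            np.array_equal(a.samples, b.samples) for a, b in zip(records, records2)
        )
        assert truth.events.keys() == truth2.events.keys()

    def test_infeasible_rate_rejected_with_message(self):
        cfg = SyntheticCohortConfig.desk(record_duration=600.0, has_rate=1.0)
        with pytest.raises(ValueError, match="has_rate"):
            generate_cohort(cfg)

    def test_two_channels_per_animal(self, desk_config, desk_cohort):
        records, _ = desk_cohort
        n_animals = sum(desk_config.animals_per_group.values())
        assert len(records) == 2 * n_animals
        assert {r.channel for r in records} == {"left", "right"}


class TestDataset:
    def test_ratio_tracks_reference_composition(self, desk_dataset):
        """Scaled per-group targets preserve the ~1:6.8 HAS:non-HAS ratio."""
        _, manifest = desk_dataset
        counts = manifest["label"].value_counts()
        ratio = counts["non-HAS"] / counts["HAS"]
        assert abs(ratio - 27_060 / 3955) / (27_060 / 3955) < 0.10

    def test_zero_rate_yields_only_non_has(self):
        cfg = SyntheticCohortConfig.desk(
            seed=3,
            has_rate=0.0,
            size_factor=0.002,
            animals_per_group={"G1": 1, "G2": 1, "G3": 1, "G4": 1},
        )
        records, truth = generate_cohort(cfg)
        segs, manifest = make_classification_dataset(records, truth, cfg)
        assert truth.n_events("HAS") == 0
        assert set(manifest["label"]) == {"non-HAS"}

    def test_segments_have_configured_length(self, desk_config, desk_dataset):
        segs, _ = desk_dataset
        assert {s.length for s in segs} == {desk_config.segment_length}

    def test_separability_dial_energy_threshold(self, desk_dataset):
        """At the default contrast a plain RMS threshold separates classes
        well -- the anchor for scaled-down training runs."""
        from hasdetect.evaluation import EnergyThresholdBaseline, confusion

        segs, manifest = desk_dataset
        y = (manifest["label"] == "HAS").to_numpy().astype(int)
        baseline = EnergyThresholdBaseline().fit(segs, y)
        acc = confusion(y, baseline.predict(segs)).accuracy
        assert acc >= 95.0
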