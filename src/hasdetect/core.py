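"""Core domain containers.

The pipeline works on continuous two-channel fetal EEG sampled at 256 Hz in
microvolts.  Seizure epochs ("HAS": high-amplitude stereotypic evolving
seizures, >=10 s and >20 uV by definition) are cut into fixed-length labeled
segments centered on the seizure.  Four experimental cohorts are tracked:

* ``G1`` - hypoxia-ischemia (HI), normothermia, term
* ``G2`` - HI, therapeutic hypothermia, term
* ``G3`` - sham, normothermia, term (control: no seizures)
* ``G4`` - HI, normothermia, preterm
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FS_DEFAULT = 256
"""Canonical sampling rate of the recordings, in Hz."""

SEGMENT_LENGTH = 51_302
"""Canonical seizure-segment length in samples (~3.34 min at 256 Hz)."""

GROUPS = ("G1", "G2", "G3", "G4")

GROUP_LABELS = {
    "G1": "HI-normothermia term",
    "G2": "HI-hypothermia term",
    "G3": "sham-normothermia term",
    "G4": "HI-normothermia preterm",
}

CHANNELS = ("left", "right")

HAS_MIN_DURATION_S = 10.0
"""Definitional minimum HAS duration in seconds."""

HAS_MIN_AMPLITUDE_UV = 20.0
"""Definitional HAS amplitude threshold in microvolts (strictly exceeded)."""


@dataclass
class EegRecord:
    """Continuous single-channel EEG in microvolts.

    Parameters
    ----------
    samples : ndarray
        1-D float array, microvolts.
    fs : float
        Sampling rate in Hz (canonically 256).
    channel : str
        ``"left"`` or ``"right"``.
    animal_id : str
        Subject identifier, e.g. ``"G1_a00"``.
    group : str
        Cohort code, one of :data:`GROUPS`.
    t0 : int
        Acquisition origin in samples (offset of ``samples[0]`` in the
        original recording's coordinate system).
    """

    samples: np.ndarray
    fs: float = FS_DEFAULT
    channel: str = "left"
    animal_id: str = ""
    group: str = "G1"
    t0: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("EegRecord samples must be a 1-D array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EegRecord samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EegSegment:
    """Fixed-length labeled EEG epoch.

    ``label`` is ``"HAS"`` or ``"non-HAS"``.  Provenance points back to the
    continuous record the segment was cut from.
    """

    samples: np.ndarray
    label: str
    animal_id: str = ""
    channel: str = "left"
    group: str = "G1"
    center_sample: int = 0
    fs: float = FS_DEFAULT
    padded: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("EegSegment samples must be a 1-D array")
        if self.label not in ("HAS", "non-HAS"):
            raise ValueError(f"label must be 'HAS' or 'non-HAS', got {self.label!r}")

    @property
    def length(self) -> int:
        return self.samples.size


@dataclass
class EegEvent:
    """One annotated event on one channel: a HAS or an artifact.

    Sample coordinates are 0-based, with half-open extent
    ``[onset_sample, offset_sample)``.
    """

    event_type: str  # "HAS" | "artifact"
    onset_sample: int
    offset_sample: int
    true_center_sample: int

    def __post_init__(self) -> None:
        if self.event_type not in ("HAS", "artifact"):
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not (self.onset_sample < self.true_center_sample < self.offset_sample):
            raise ValueError(
                "event must satisfy onset < center < offset, got "
                f"({self.onset_sample}, {self.true_center_sample}, {self.offset_sample})"
            )


@dataclass
class GroundTruth:
    """Per-(animal, channel) event annotations for a synthetic cohort.

    Maps ``(animal_id, channel)`` to a list of non-overlapping
    :class:`EegEvent`, sorted by onset.
    """

    events: dict[tuple[str, str], list[EegEvent]] = field(default_factory=dict)

    def add(self, animal_id: str, channel: str, event: EegEvent) -> None:
        self.events.setdefault((animal_id, channel), []).append(event)

    def get(self, animal_id: str, channel: str) -> list[EegEvent]:
        return self.events.get((animal_id, channel), [])

    def has_intervals(self, animal_id: str, channel: str) -> list[tuple[int, int]]:
        """Half-open [onset, offset) intervals of HAS events on a channel."""
        return [
            (e.onset_sample, e.offset_sample)
            for e in self.get(animal_id, channel)
            if e.event_type == "HAS"
        ]

    def n_events(self, event_type: str | None = None) -> int:
        return sum(
            1
            for evs in self.events.values()
            for e in evs
            if event_type is None or e.event_type == event_type
        )
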