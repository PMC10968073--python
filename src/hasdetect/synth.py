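"""Synthetic fetal-sheep-like EEG cohorts.

The study recordings this pipeline was designed around are not publicly
deposited, so this module generates cohorts with the statistical structure the
classifiers exploit:

* colored-noise background EEG (term: broader band, continuous; preterm:
  steeper spectrum with intermittent burst/interburst discontinuity),
* HAS events: trains of stereotyped sharpened discharges whose repetition
  rate evolves inside a delta-dominant band under a waxing/waning envelope,
  satisfying the definitional floor (duration >= 10 s, amplitude > 20 uV),
* non-HAS content: background plus movement artifacts and electronic noise
  bursts (high-energy distractors for the classifiers),
* four cohorts mirroring the study composition (G1 HI-normothermia term,
  G2 HI-hypothermia term, G3 sham-normothermia term with zero seizures,
  G4 HI-normothermia preterm), with per-group segment counts scaled from the
  reference composition by a single size factor, preserving the ~1:6.8
  HAS:non-HAS ratio.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import windows

from .core import (
    CHANNELS,
    FS_DEFAULT,
    GROUPS,
    HAS_MIN_AMPLITUDE_UV,
    HAS_MIN_DURATION_S,
    SEGMENT_LENGTH,
    EegEvent,
    EegRecord,
    EegSegment,
    GroundTruth,
)

#: Reference cohort composition: per group, number of animals and number of
#: annotated (seizure, non-seizure) segments on the (left, right) channels.
COHORT_COMPOSITION = {
    "G1": {"animals": 7, "seizures": (470, 538), "non_seizures": (2213, 2212)},
    "G2": {"animals": 14, "seizures": (594, 709), "non_seizures": (4423, 4437)},
    "G3": {"animals": 5, "seizures": (0, 0), "non_seizures": (2438, 2457)},
    "G4": {"animals": 14, "seizures": (844, 800), "non_seizures": (4443, 4437)},
}

#: Maturity of each cohort; drives background model and seizure rhythm band.
GROUP_MATURITY = {"G1": "term", "G2": "term", "G3": "term", "G4": "preterm"}

_BACKGROUND_MODELS = {
    # spectral exponent beta (power ~ 1/f^beta), upper band edge in Hz,
    # and discontinuity (burst/interburst amplitude modulation) parameters
    "term": {"beta": 1.0, "f_hi": 30.0, "discontinuous": False},
    "preterm": {
        "beta": 1.6,
        "f_hi": 15.0,
        "discontinuous": True,
        "burst_s": (4.0, 10.0),
        "interburst_s": (3.0, 8.0),
        "interburst_gain": 0.25,
    },
}


@dataclass
class SyntheticCohortConfig:
    """Conditions for one synthetic cohort.

    The defaults emulate the reference study composition scaled by
    ``size_factor`` so that desk-scale runs stay fast while preserving the
    per-group proportions (and hence the ~1:6.8 HAS:non-HAS segment ratio).

    Notes on selected fields
    ------------------------
    has_rate : float
        HAS events per hour per channel after the insult; caps how many
        seizures fit into ``record_duration``.
    has_amplitude_range : tuple
        Peak amplitude bounds in microvolts (lower bound must exceed 20).
        Multiplied by ``contrast``.
    contrast : float
        Separability dial: multiplies HAS amplitudes relative to background.
        At the default (1.0, with 60-300 uV seizures over 12 uV RMS
        background) a plain energy threshold already separates classes well.
    hypothermia_suppression : float
        Multiplicative factor on both HAS amplitude and rate for G2,
        modeling partial seizure suppression by brain cooling.
    size_factor : float
        Scales the reference per-group segment counts; 0.032 yields ~1000
        segments in total.
    """

    groups: tuple[str, ...] = GROUPS
    animals_per_group: dict[str, int] | None = None
    record_duration: float = 1200.0  # seconds per channel
    fs: float = FS_DEFAULT
    has_rate: float = 12.0  # events/hour/channel
    has_amplitude_range: tuple[float, float] = (60.0, 300.0)
    has_duration_range: tuple[float, float] = (10.0, 60.0)
    has_rhythm_band: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"term": (0.5, 4.0), "preterm": (0.5, 2.5)}
    )
    background_rms_uV: float = 12.0
    contrast: float = 1.0
    hypothermia_suppression: float = 0.6
    artifact_rate: float = 6.0  # events/hour/channel
    artifact_amplitude_range: tuple[float, float] = (50.0, 250.0)
    segment_length: int = SEGMENT_LENGTH
    size_factor: float = 0.032
    has_segment_targets: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.animals_per_group is None:
            self.animals_per_group = {
                g: COHORT_COMPOSITION[g]["animals"] for g in self.groups
            }
        if self.has_amplitude_range[0] * self.contrast <= HAS_MIN_AMPLITUDE_UV:
            raise ValueError(
                "lower HAS amplitude bound (x contrast) must exceed "
                f"{HAS_MIN_AMPLITUDE_UV} uV"
            )
        if self.has_duration_range[0] < HAS_MIN_DURATION_S:
            raise ValueError(
                f"lower HAS duration bound must be >= {HAS_MIN_DURATION_S} s"
            )
        if self.record_duration <= 0:
            raise ValueError("record_duration must be positive")
        if self.has_segment_targets is not None and self.has_segment_targets.get("G3", 0) > 0:
            raise ValueError("G3 is a sham cohort and cannot contain HAS events")

    @classmethod
    def desk(cls, **overrides) -> "SyntheticCohortConfig":
        """Desk-scale profile: short segments, small cohort, fast to generate."""
        params = dict(segment_length=2560, record_duration=1200.0)
        params.update(overrides)
        return cls(**params)

    def scaled_counts(self) -> dict[str, dict[str, tuple[int, int]]]:
        """Per-group (left, right) segment targets after size_factor scaling."""
        out = {}
        for g in self.groups:
            comp = COHORT_COMPOSITION[g]
            if self.has_segment_targets is not None:
                tot = self.has_segment_targets.get(g, 0)
                seiz = (tot - tot // 2, tot // 2)
            else:
                seiz = tuple(
                    int(round(n * self.size_factor)) for n in comp["seizures"]
                )
            if self.has_rate == 0:
                seiz = (0, 0)
            non = tuple(
                int(round(n * self.size_factor)) for n in comp["non_seizures"]
            )
            out[g] = {"seizures": seiz, "non_seizures": non}
        return out


def generate_background(
    duration_s: float,
    maturity: str,
    seed: int,
    fs: float = FS_DEFAULT,
    rms_uV: float = 12.0,
) -> EegRecord:
    """Zero-mean colored-noise EEG background.

    Term background is continuous with a broader band (up to ~30 Hz,
    1/f spectrum); preterm background has a steeper spectrum confined below
    ~15 Hz and intermittent suppression (burst/interburst alternation), the
    hallmark of immature discontinuous EEG.

    Parameters
    ----------
    duration_s : float
        Length in seconds; must be positive.
    maturity : {"term", "preterm"}
    seed : int
        Same seed, same output, bit for bit.
    rms_uV : float
        Target RMS amplitude in microvolts (well below the 20 uV seizure
        definition threshold by default).
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if maturity not in _BACKGROUND_MODELS:
        raise ValueError(f"maturity must be 'term' or 'preterm', got {maturity!r}")
    model = _BACKGROUND_MODELS[maturity]
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))

    # shape white Gaussian noise in the frequency domain: ~1/f^(beta/2)
    # amplitude above a 0.5 Hz knee, hard band edge at f_hi
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    knee = 0.5
    shaping = np.ones_like(freqs)
    above = freqs > knee
    shaping[above] = (knee / freqs[above]) ** (model["beta"] / 2.0)
    shaping[freqs > model["f_hi"]] = 0.0
    shaping[0] = 0.0  # zero mean
    x = np.fft.irfft(spec * shaping, n)

    if model["discontinuous"]:
        x *= _burst_suppression_envelope(n, fs, model, rng)

    x -= x.mean()
    scale = rms_uV / max(np.sqrt(np.mean(x**2)), 1e-30)
    return EegRecord(samples=x * scale, fs=fs)


def _burst_suppression_envelope(n, fs, model, rng) -> np.ndarray:
    """Alternating burst/interburst amplitude gate with smooth edges."""
    env = np.empty(n)
    pos = 0
    in_burst = bool(rng.integers(0, 2))
    while pos < n:
        lo, hi = model["burst_s"] if in_burst else model["interburst_s"]
        length = int(rng.uniform(lo, hi) * fs)
        gain = 1.0 if in_burst else model["interburst_gain"]
        env[pos : pos + length] = gain
        pos += length
        in_burst = not in_burst
    # ~0.5 s raised-cosine smoothing of the gate transitions
    win = windows.hann(int(0.5 * fs) | 1)
    win /= win.sum()
    return np.convolve(env, win, mode="same")


def generate_has_event(
    duration_s: float,
    amplitude_uV: float,
    rhythm_band: tuple[float, float] = (0.5, 4.0),
    fs: float = FS_DEFAULT,
    seed: int = 0,
    envelope: str = "waxing",
    peak_frac: float | None = None,
) -> np.ndarray:
    """One high-amplitude stereotypic evolving seizure waveform.

    A train of sharpened quasi-sinusoidal discharges whose instantaneous
    repetition frequency drifts downwards within ``rhythm_band`` (seizure
    rhythms typically slow as the event evolves).  The waveform peak equals
    ``amplitude_uV`` exactly.

    ``envelope`` selects the amplitude profile: ``"waxing"`` (default) is a
    waxing/waning modulated plateau; ``"peaked"`` is a single smooth
    Gaussian crescendo-decrescendo whose maximum sits at ``peak_frac`` of
    the duration (seeded in [0.4, 0.6] when not given) -- a burst with one
    unambiguous center of weight.

    Raises
    ------
    ValueError
        If the request violates the HAS definition (duration < 10 s or
        amplitude <= 20 uV).
    """
    if duration_s < HAS_MIN_DURATION_S:
        raise ValueError(
            f"a HAS lasts at least {HAS_MIN_DURATION_S} s, got {duration_s} s"
        )
    if amplitude_uV <= HAS_MIN_AMPLITUDE_UV:
        raise ValueError(
            f"a HAS exceeds {HAS_MIN_AMPLITUDE_UV} uV, got {amplitude_uV} uV"
        )
    lo, hi = rhythm_band
    if not 0 < lo < hi:
        raise ValueError(f"invalid rhythm band {rhythm_band}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # instantaneous discharge frequency: drift from the upper toward the
    # lower part of the band, with slow seeded jitter
    f_start = lo + 0.85 * (hi - lo)
    f_end = lo + 0.15 * (hi - lo)
    f_inst = f_start + (f_end - f_start) * (t / duration_s)
    jitter = _smooth_noise(n, rng) * 0.08 * (hi - lo)
    f_inst = np.clip(f_inst + jitter, lo, hi)

    phase = 2 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
    base = np.sin(phase)
    # mild odd-harmonic sharpening keeps the fundamental dominant while
    # giving discharges their peaked, stereotyped look
    wave = 0.7 * base + 0.3 * base**3

    if envelope == "waxing":
        mod_period = max(duration_s / 3.0, 4.0)
        env = windows.tukey(n, alpha=0.3) * (
            0.7 + 0.3 * np.sin(2 * np.pi * t / mod_period + rng.uniform(0, 2 * np.pi))
        )
    elif envelope == "peaked":
        p = rng.uniform(0.4, 0.6) if peak_frac is None else peak_frac
        env = np.exp(-0.5 * ((t - p * duration_s) / (duration_s / 5.0)) ** 2)
    else:
        raise ValueError(f"unknown envelope {envelope!r}")
    x = env * wave
    return amplitude_uV * x / np.max(np.abs(x))


def _smooth_noise(n: int, rng) -> np.ndarray:
    """Unit-RMS noise low-passed to ~0.2 Hz-scale wander."""
    raw = rng.standard_normal(max(n // 256, 4))
    idx = np.linspace(0, raw.size - 1, n)
    smooth = np.interp(idx, np.arange(raw.size), raw)
    return smooth / max(np.sqrt(np.mean(smooth**2)), 1e-30)


def generate_artifact(
    duration_s: float,
    amplitude_uV: float,
    kind: str = "movement",
    fs: float = FS_DEFAULT,
    seed: int = 0,
) -> np.ndarray:
    """A non-seizure high-energy transient.

    ``movement``: large slow (<2 Hz) non-rhythmic excursion.
    ``electronic``: broadband noise burst with a mains (50 Hz) component.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if kind not in ("movement", "electronic"):
        raise ValueError(f"unknown artifact kind {kind!r}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if kind == "movement":
        # integrated noise, band-limited low: a wandering baseline lurch
        x = np.cumsum(rng.standard_normal(n))
        x -= np.poly1d(np.polyfit(t, x, 3))(t)  # detrend, keep slow wiggle
    else:
        x = rng.standard_normal(n) + 1.5 * np.sin(
            2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
        )
    x *= windows.tukey(n, alpha=0.5)
    peak = np.max(np.abs(x))
    return amplitude_uV * x / max(peak, 1e-30)


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[EegRecord], GroundTruth]:
    """Generate every record of the configured cohort plus its ground truth.

    Each animal yields two channel records (left, right).  HAS events are
    placed so each channel carries its share of the scaled per-group segment
    targets; G2 amplitudes and rates are scaled by the hypothermia
    suppression factor; G3 (sham) never receives a HAS.  Artifacts are
    added everywhere at ``artifact_rate``.

    Raises
    ------
    ValueError
        If the configured record duration / HAS rate cannot host the
        requested number of events.
    """
    counts = config.scaled_counts()
    ss = np.random.SeedSequence(config.seed)
    records: list[EegRecord] = []
    truth = GroundTruth()
    hours = config.record_duration / 3600.0

    for g in config.groups:
        n_animals = config.animals_per_group[g]
        rate = config.has_rate
        if g == "G2":
            rate *= config.hypothermia_suppression
        max_per_channel = math.floor(rate * hours)
        for ch_i, ch in enumerate(CHANNELS):
            target = counts[g]["seizures"][ch_i]
            if g == "G3" and target > 0:
                raise ValueError("sham cohort G3 cannot contain HAS events")
            # spread the group's target across its animals
            per_animal = _spread(target, n_animals)
            if max(per_animal, default=0) > max_per_channel:
                raise ValueError(
                    f"group {g} channel {ch}: need up to {max(per_animal)} HAS "
                    f"events per record but has_rate x duration allows only "
                    f"{max_per_channel}; lengthen record_duration or raise has_rate"
                )
        for a in range(n_animals):
            animal_id = f"{g}_a{a:02d}"
            for ch_i, ch in enumerate(CHANNELS):
                child = np.random.SeedSequence(
                    entropy=config.seed,
                    spawn_key=(config.groups.index(g), a, ch_i),
                )
                rec = _generate_channel(
                    config,
                    g,
                    animal_id,
                    ch,
                    n_has=_spread(counts[g]["seizures"][ch_i], n_animals)[a],
                    truth=truth,
                    seedseq=child,
                )
                records.append(rec)
    return records, truth


def _spread(total: int, bins: int) -> list[int]:
    """Distribute `total` items over `bins`, remainder to the earliest."""
    base, rem = divmod(total, bins)
    return [base + (1 if i < rem else 0) for i in range(bins)]


def _generate_channel(
    config: SyntheticCohortConfig,
    group: str,
    animal_id: str,
    channel: str,
    n_has: int,
    truth: GroundTruth,
    seedseq: np.random.SeedSequence,
) -> EegRecord:
    maturity = GROUP_MATURITY[group]
    seeds = seedseq.generate_state(4)
    rng = np.random.default_rng(seeds[0])
    fs = config.fs
    n = int(round(config.record_duration * fs))

    rec = generate_background(
        config.record_duration,
        maturity,
        seed=int(seeds[1] % (2**31)),
        fs=fs,
        rms_uV=config.background_rms_uV,
    )
    x = rec.samples

    n_art = math.floor(config.artifact_rate * config.record_duration / 3600.0)
    amp_scale = config.contrast
    if group == "G2":
        amp_scale *= config.hypothermia_suppression

    # one scheduling block per event keeps events apart and leaves
    # seizure-free spans long enough to cut non-HAS segments from
    n_events = n_has + n_art
    events: list[tuple[str, int, np.ndarray]] = []
    if n_events > 0:
        block = n // n_events
        kinds = ["HAS"] * n_has + ["artifact"] * n_art
        rng.shuffle(kinds)
        for i, kind in enumerate(kinds):
            if kind == "HAS":
                dur = rng.uniform(*config.has_duration_range)
                amp = rng.uniform(*config.has_amplitude_range) * amp_scale
                wav = generate_has_event(
                    dur,
                    amp,
                    rhythm_band=config.has_rhythm_band[maturity],
                    fs=fs,
                    seed=int(rng.integers(0, 2**31)),
                )
            else:
                dur = rng.uniform(2.0, 8.0)
                amp = rng.uniform(*config.artifact_amplitude_range)
                wav = generate_artifact(
                    dur,
                    amp,
                    kind=rng.choice(["movement", "electronic"]),
                    fs=fs,
                    seed=int(rng.integers(0, 2**31)),
                )
            wlen = wav.size
            lo = i * block
            hi = min((i + 1) * block, n) - wlen
            if hi <= lo:
                raise ValueError(
                    f"record too short to host event {i} ({kind}) on "
                    f"{animal_id}/{channel}"
                )
            onset = int(rng.integers(lo, hi))
            events.append((kind, onset, wav))

    for kind, onset, wav in events:
        x[onset : onset + wav.size] += wav
        center = onset + int(np.argmax(np.abs(wav)))
        truth.add(
            animal_id,
            channel,
            EegEvent(
                event_type=kind,
                onset_sample=onset,
                offset_sample=onset + wav.size,
                true_center_sample=center,
            ),
        )

    return EegRecord(
        samples=x,
        fs=fs,
        channel=channel,
        animal_id=animal_id,
        group=group,
    )


def make_classification_dataset(
    records: list[EegRecord],
    truth: GroundTruth,
    config: SyntheticCohortConfig,
    seed: int | None = None,
) -> tuple[list[EegSegment], pd.DataFrame]:
    """Cut the labeled segment dataset out of a generated cohort.

    HAS segments are centered on the true event centers; non-HAS segments
    are sampled outside HAS intervals (artifacts allowed by design) to hit
    the scaled per-group targets.  Returns the segments and a manifest
    DataFrame (label/group/animal/channel/center).
    """
    from .trend import extract_segment, sample_non_has

    if seed is None:
        seed = config.seed + 1
    counts = config.scaled_counts()
    L = config.segment_length
    segments: list[EegSegment] = []
    rows = []
    rng = np.random.default_rng(seed)

    for g in config.groups:
        group_recs = [r for r in records if r.group == g]
        for ch_i, ch in enumerate(CHANNELS):
            ch_recs = [r for r in group_recs if r.channel == ch]
            for rec in ch_recs:
                for ev in truth.get(rec.animal_id, ch):
                    if ev.event_type != "HAS":
                        continue
                    seg = extract_segment(rec, ev.true_center_sample, L=L)
                    seg = replace_label(seg, "HAS")
                    segments.append(seg)
                    rows.append(_row(seg))
            # distribute the non-HAS target across the group's records
            target_non = counts[g]["non_seizures"][ch_i]
            per_rec = _spread(target_non, len(ch_recs))
            for rec, n_non in zip(ch_recs, per_rec):
                if n_non == 0:
                    continue
                segs = sample_non_has(
                    rec,
                    truth,
                    n=n_non,
                    L=L,
                    seed=int(rng.integers(0, 2**31)),
                )
                for seg in segs:
                    segments.append(seg)
                    rows.append(_row(seg))

    manifest = pd.DataFrame(
        rows, columns=["label", "group", "animal_id", "channel", "center_sample"]
    )
    return segments, manifest


def replace_label(seg: EegSegment, label: str) -> EegSegment:
    seg.label = label
    return seg


def _row(seg: EegSegment) -> dict:
    return {
        "label": seg.label,
        "group": seg.group,
        "animal_id": seg.animal_id,
        "channel": seg.channel,
        "center_sample": seg.center_sample,
    }
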