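"""Reading and writing EEG records, segment stores and annotations.

Formats:

* **EDF** for continuous records -- written by a minimal 16-bit EDF writer
  (fixed-field header, one data record per second) and read back through
  :mod:`mne`, honoring the physical-dimension fields (canonical unit: uV);
* **array container** (.npz) for records and segment stores, float32 by
  default (sufficient for EEG dynamic range at half the disk usage);
* **delimited text** (TSV) for annotation tables and segment manifests.
  Sample coordinates are 0-based with half-open [onset, offset) intervals.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FS_DEFAULT, EegRecord, EegSegment, EegEvent, GroundTruth

logger = logging.getLogger(__name__)

_EDF_CHANNEL_NAMES = {"left": "EEG Left", "right": "EEG Right"}


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(records: list[EegRecord], path) -> None:
    """Write channel records of one animal to a 16-bit EDF file.

    All records must share fs and length; each becomes one signal, labeled
    from its channel name, physical dimension uV.  Data records are 1 s
    long; a trailing partial second is dropped (EDF stores whole records).
    """
    if not records:
        raise ValueError("no records to write")
    fs = records[0].fs
    n = min(r.n_samples for r in records)
    if any(r.fs != fs for r in records):
        raise ValueError("all channels must share one sampling rate")
    spr = int(round(fs))  # samples per 1 s data record
    n_rec = n // spr
    if n_rec == 0:
        raise ValueError("records must span at least one second")
    ns = len(records)

    def fixed(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            fixed("0", 8),
            fixed("X X X X", 80),  # local patient id (anonymous)
            fixed("Startdate X X X X", 80),
            fixed("01.01.00", 8),
            fixed("00.00.00", 8),
            fixed(str(256 + 256 * ns), 8),
            fixed("", 44),
            fixed(str(n_rec), 8),
            fixed("1", 8),  # record duration, seconds
            fixed(str(ns), 4),
        ]
    )

    phys_min, phys_max, dig_min, dig_max, scaled = [], [], [], [], []
    for r in records:
        x = r.samples[: n_rec * spr]
        lo = float(np.floor(x.min())) if x.size else -1.0
        hi = float(np.ceil(x.max())) if x.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        dig_min.append(-32768)
        dig_max.append(32767)
        gain = (hi - lo) / (32767 - (-32768))
        scaled.append(np.round((x - lo) / gain + (-32768)).astype("<i2"))

    labels = [
        _EDF_CHANNEL_NAMES.get(r.channel, r.channel or f"ch{i}")
        for i, r in enumerate(records)
    ]
    sig_header = b"".join(
        [
            b"".join(fixed(lab, 16) for lab in labels),
            b"".join(fixed("synthetic EEG", 80) for _ in records),
            b"".join(fixed("uV", 8) for _ in records),
            b"".join(fixed(f"{v:g}", 8) for v in phys_min),
            b"".join(fixed(f"{v:g}", 8) for v in phys_max),
            b"".join(fixed(str(v), 8) for v in dig_min),
            b"".join(fixed(str(v), 8) for v in dig_max),
            b"".join(fixed("", 80) for _ in records),
            b"".join(fixed(str(spr), 8) for _ in records),
            b"".join(fixed("", 32) for _ in records),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for rec_i in range(n_rec):
            for sig in scaled:
                fh.write(sig[rec_i * spr : (rec_i + 1) * spr].tobytes())


def read_record(
    path,
    fmt: str | None = None,
    channels: tuple[str, ...] = ("left", "right"),
    animal_id: str = "",
    group: str = "G1",
) -> list[EegRecord]:
    """Read continuous EEG from EDF, an array container, or delimited text.

    Returns one :class:`EegRecord` per requested channel, samples in uV.
    A sampling rate other than 256 Hz triggers a warning (the record is
    returned as-is; resampling is deliberately not performed).  Extra EDF
    channels are ignored with a logged notice.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".edf": "edf", ".npz": "npz", ".tsv": "delimited", ".csv": "delimited"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.suffix!r}")
    if fmt == "edf":
        records = _read_edf(path, channels, animal_id, group)
    elif fmt == "npz":
        records = _read_npz_record(path)
    elif fmt == "delimited":
        records = _read_delimited_record(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    for r in records:
        if r.fs != FS_DEFAULT:
            warnings.warn(
                f"{path.name}: sampling rate {r.fs} Hz != {FS_DEFAULT} Hz; "
                "returning unresampled data",
                stacklevel=2,
            )
    return records


def _read_edf(path, channels, animal_id, group) -> list[EegRecord]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    wanted = {_EDF_CHANNEL_NAMES[ch]: ch for ch in channels}
    extra = [name for name in raw.ch_names if name not in wanted]
    if extra:
        logger.info("%s: ignoring channels %s", path, extra)
    records = []
    for name, ch in wanted.items():
        if name not in raw.ch_names:
            raise ValueError(f"{path}: channel {name!r} not found")
        data = raw.get_data(picks=[name])[0] * 1e6  # volts -> uV
        records.append(
            EegRecord(
                samples=data,
                fs=float(raw.info["sfreq"]),
                channel=ch,
                animal_id=animal_id,
                group=group,
            )
        )
    return records


# ---------------------------------------------------------------------------
# array container
# ---------------------------------------------------------------------------

def write_npz_record(records: list[EegRecord], path, dtype=np.float32) -> None:
    """Portable array container: float32 samples + JSON metadata."""
    meta = [
        {
            "channel": r.channel,
            "animal_id": r.animal_id,
            "group": r.group,
            "fs": r.fs,
            "t0": r.t0,
        }
        for r in records
    ]
    arrays = {f"samples_{i}": r.samples.astype(dtype) for i, r in enumerate(records)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def _read_npz_record(path) -> list[EegRecord]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        return [
            EegRecord(
                samples=data[f"samples_{i}"].astype(np.float64),
                fs=m["fs"],
                channel=m["channel"],
                animal_id=m["animal_id"],
                group=m["group"],
                t0=m.get("t0", 0),
            )
            for i, m in enumerate(meta)
        ]


def _read_delimited_record(path) -> list[EegRecord]:
    df = pd.read_csv(path, sep="\t")
    if "samples_uV" not in df.columns:
        raise ValueError(f"{path}: malformed delimited record (no samples_uV)")
    sidecar = Path(path).with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return [
        EegRecord(
            samples=df["samples_uV"].to_numpy(),
            fs=meta.get("fs", FS_DEFAULT),
            channel=meta.get("channel", "left"),
            animal_id=meta.get("animal_id", ""),
            group=meta.get("group", "G1"),
        )
    ]


def write_delimited_record(record: EegRecord, path) -> None:
    pd.DataFrame({"samples_uV": record.samples}).to_csv(path, sep="\t", index=False)
    Path(path).with_suffix(".json").write_text(
        json.dumps(
            {
                "fs": record.fs,
                "channel": record.channel,
                "animal_id": record.animal_id,
                "group": record.group,
            }
        )
    )


# ---------------------------------------------------------------------------
# segment stores
# ---------------------------------------------------------------------------

def write_segment_store(segments: list[EegSegment], path) -> pd.DataFrame:
    """Store segments as one float32 matrix plus a TSV manifest.

    All segments must share one length.  Returns the manifest written to
    ``<path>.manifest.tsv``.
    """
    path = Path(path)
    lengths = {s.length for s in segments}
    if len(lengths) > 1:
        raise ValueError(f"mixed segment lengths in one store: {sorted(lengths)}")
    mat = (
        np.stack([s.samples for s in segments]).astype(np.float32)
        if segments
        else np.empty((0, 0), dtype=np.float32)
    )
    manifest = pd.DataFrame(
        [
            {
                "label": s.label,
                "animal_id": s.animal_id,
                "channel": s.channel,
                "group": s.group,
                "center_sample": s.center_sample,
                "fs": s.fs,
                "padded": s.padded,
            }
            for s in segments
        ],
        columns=["label", "animal_id", "channel", "group", "center_sample", "fs", "padded"],
    )
    np.savez(path, samples=mat)
    manifest.to_csv(_manifest_path(path), sep="\t", index=False)
    return manifest


def read_segment_store(path) -> list[EegSegment]:
    path = Path(path)
    with np.load(path) as data:
        mat = data["samples"].astype(np.float64)
    manifest = pd.read_csv(_manifest_path(path), sep="\t")
    if len(manifest) != mat.shape[0]:
        raise ValueError("manifest row count does not match stored segments")
    return [
        EegSegment(
            samples=mat[i],
            label=row["label"],
            animal_id=str(row["animal_id"]),
            channel=row["channel"],
            group=row["group"],
            center_sample=int(row["center_sample"]),
            fs=float(row["fs"]),
            padded=bool(row["padded"]),
        )
        for i, row in manifest.iterrows()
    ]


def _manifest_path(path: Path) -> Path:
    p = Path(path)
    suffix = p.suffix if p.suffix == ".npz" else ""
    return p.with_name(p.name.replace(suffix, "") + ".manifest.tsv")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def write_annotations(truth: GroundTruth, path) -> None:
    """Ground-truth events as a TSV table (0-based, half-open intervals)."""
    rows = [
        {
            "animal_id": animal,
            "channel": channel,
            "type": ev.event_type,
            "onset_sample": ev.onset_sample,
            "offset_sample": ev.offset_sample,
            "center_sample": ev.true_center_sample,
        }
        for (animal, channel), events in sorted(truth.events.items())
        for ev in events
    ]
    pd.DataFrame(
        rows,
        columns=["animal_id", "channel", "type", "onset_sample", "offset_sample", "center_sample"],
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    truth = GroundTruth()
    for _, row in df.iterrows():
        truth.add(
            str(row["animal_id"]),
            row["channel"],
            EegEvent(
                event_type=row["type"],
                onset_sample=int(row["onset_sample"]),
                offset_sample=int(row["offset_sample"]),
                true_center_sample=int(row["center_sample"]),
            ),
        )
    return truth
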