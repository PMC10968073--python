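"""Per-minute EEG power trend and seizure-epoch centering.

Long-term monitoring works off a per-minute power trend: for every complete
minute of signal, the periodogram power summed over 1-20 Hz, log-transformed
as 20*log10(intensity) (dB).  Seizures are marked on that trend at 1-min
granularity, so the marked minute only coarsely localizes the event.  The
centering procedure refines it:

1. take a +/-1 min excerpt around the marked minute's midpoint (``sig_1``),
2. zero-mean it and raise it elementwise to the 10th power to exaggerate the
   high-energy section (``sig_2``; computed on an amplitude-normalized copy
   so the power stays in floating range -- the argmax is scale-equivariant,
   so this changes nothing downstream),
3. slide a moving median absolute deviation (movmad) of window 8000 samples
   over ``sig_2`` (``sig_3``),
4. the argmax of ``sig_3`` is the seizure's center of weight; a fixed-length
   segment (canonically 51,302 samples, ~3.34 min) is cut around it.

``sig_3`` is rescaled to the excerpt's range for QC plotting only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import periodogram

from .core import EegRecord, EegSegment, GroundTruth, SEGMENT_LENGTH

logger = logging.getLogger(__name__)

TREND_BAND = (1.0, 20.0)
TREND_BIN_S = 60.0
MOVMAD_WINDOW = 8000


@dataclass
class PowerTrend:
    """Per-minute 1-20 Hz power trend in dB (20*log10 of summed power)."""

    values: np.ndarray
    bin_duration: float = TREND_BIN_S
    band: tuple[float, float] = TREND_BAND
    fs: float = 256.0

    @property
    def n_bins(self) -> int:
        return self.values.size


@dataclass
class CenteringTrace:
    """Full centering diagnostics for one marked minute.

    ``sig_1``: the raw +/-1 min excerpt; ``sig_2``: zero-meaned,
    amplitude-normalized excerpt to the 10th power; ``sig_3``: movmad of
    ``sig_2`` rescaled to ``sig_1``'s range (for plotting);
    ``center_sample``: the chosen center in record coordinates.
    """

    sig_1: np.ndarray
    sig_2: np.ndarray
    sig_3: np.ndarray
    excerpt_start: int
    center_sample: int


def compute_power_trend(record: EegRecord) -> PowerTrend:
    """Per-minute summed 1-20 Hz periodogram power, in dB.

    One rectangular-window periodogram per complete minute; power summed
    over bins with 1 <= f <= 20 Hz inclusive; trailing partial minute
    dropped.  Records shorter than one minute are rejected.
    """
    fs = record.fs
    bin_n = int(round(TREND_BIN_S * fs))
    n_bins = record.n_samples // bin_n
    if n_bins == 0:
        raise ValueError(
            f"record must span at least one full minute ({bin_n} samples), "
            f"got {record.n_samples}"
        )
    values = np.empty(n_bins)
    lo, hi = TREND_BAND
    for i in range(n_bins):
        chunk = record.samples[i * bin_n : (i + 1) * bin_n]
        freqs, pxx = periodogram(chunk, fs=fs, window="boxcar")
        intensity = pxx[(freqs >= lo) & (freqs <= hi)].sum()
        with np.errstate(divide="ignore"):
            values[i] = 20.0 * np.log10(intensity)
    return PowerTrend(values=values, fs=fs)


def movmad(x: np.ndarray, window: int = MOVMAD_WINDOW) -> np.ndarray:
    """Moving median absolute deviation with centered, shrinking windows.

    For output index ``i`` the window covers samples
    ``[i - window//2, i + (window-1)//2]`` intersected with the signal
    (moving-statistic "shrink" endpoint semantics).  Median of an
    even-length window is the mean of the two middle order statistics.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if window < 1:
        raise ValueError("window must be >= 1")
    if x.size == 0:
        return np.empty(0)
    return _movmad_numba(x, window)


@njit(cache=True)
def _sorted_insert(buf, m, v):
    """Insert v into buf[:m] (sorted), return new length."""
    lo, hi = 0, m
    while lo < hi:
        mid = (lo + hi) // 2
        if buf[mid] < v:
            lo = mid + 1
        else:
            hi = mid
    for j in range(m, lo, -1):
        buf[j] = buf[j - 1]
    buf[lo] = v
    return m + 1


@njit(cache=True)
def _sorted_remove(buf, m, v):
    lo, hi = 0, m
    while lo < hi:
        mid = (lo + hi) // 2
        if buf[mid] < v:
            lo = mid + 1
        else:
            hi = mid
    for j in range(lo, m - 1):
        buf[j] = buf[j + 1]
    return m - 1


@njit(cache=True)
def _median_sorted(buf, m):
    if m % 2 == 1:
        return buf[m // 2]
    return 0.5 * (buf[m // 2 - 1] + buf[m // 2])


@njit(cache=True)
def _mad_sorted(buf, m, med):
    """Median of |buf[:m] - med| for sorted buf, by outward two-pointer merge."""
    # position of med in buf
    lo, hi = 0, m
    while lo < hi:
        mid = (lo + hi) // 2
        if buf[mid] < med:
            lo = mid + 1
        else:
            hi = mid
    left = lo - 1  # walks down
    right = lo  # walks up
    k1 = (m - 1) // 2  # 0-based ranks of the middle deviation(s)
    k2 = m // 2
    d1 = -1.0
    d2 = -1.0
    count = 0
    while count <= k2:
        if left >= 0:
            dl = med - buf[left]
        else:
            dl = np.inf
        if right < m:
            dr = buf[right] - med
        else:
            dr = np.inf
        if dl <= dr:
            d = dl
            left -= 1
        else:
            d = dr
            right += 1
        if count == k1:
            d1 = d
        if count == k2:
            d2 = d
        count += 1
    return 0.5 * (d1 + d2)


@njit(cache=True)
def _movmad_numba(x, window):
    n = x.size
    out = np.empty(n)
    half_lo = window // 2  # samples before i (inclusive window start)
    half_hi = (window - 1) // 2  # samples after i
    buf = np.empty(window, dtype=np.float64)
    m = 0
    # incremental sweep: at output i the window is [i-half_lo, i+half_hi]
    start = 0
    end = 0  # current buffer covers x[start:end]
    for i in range(n):
        w_start = i - half_lo
        if w_start < 0:
            w_start = 0
        w_end = i + half_hi + 1
        if w_end > n:
            w_end = n
        while end < w_end:
            m = _sorted_insert(buf, m, x[end])
            end += 1
        while start < w_start:
            m = _sorted_remove(buf, m, x[start])
            start += 1
        med = _median_sorted(buf, m)
        out[i] = _mad_sorted(buf, m, med)
    return out


def center_seizure(record: EegRecord, marked_minute: int) -> CenteringTrace:
    """Refine a per-minute seizure mark to a sample-accurate center.

    The excerpt spans one minute either side of the marked minute's
    midpoint, truncated at record edges.  Ties in the movmad trace resolve
    to the earliest index; an all-flat trace falls back to the excerpt
    midpoint.
    """
    fs = record.fs
    bin_n = int(round(TREND_BIN_S * fs))
    n_minutes = record.n_samples / bin_n
    if marked_minute < 0 or marked_minute >= int(np.ceil(n_minutes)):
        raise ValueError(
            f"marked_minute {marked_minute} outside record "
            f"({n_minutes:.1f} minutes)"
        )
    mid = int((marked_minute + 0.5) * bin_n)
    start = max(0, mid - bin_n)
    stop = min(record.n_samples, mid + bin_n)
    sig_1 = record.samples[start:stop].copy()

    z = sig_1 - sig_1.mean()
    peak = np.max(np.abs(z))
    if peak > 0:
        z = z / peak
    # |x|^10 == x^10 for even exponent; normalized first so it stays in range
    sig_2 = np.abs(z) ** 10
    mad = movmad(sig_2, MOVMAD_WINDOW)

    if np.ptp(mad) == 0.0:
        center_local = sig_1.size // 2
    else:
        center_local = int(np.argmax(mad))

    # rescale movmad trace to sig_1's range -- visualization only
    rng_1 = np.ptp(sig_1)
    rng_m = np.ptp(mad)
    if rng_m > 0:
        sig_3 = (mad - mad.min()) / rng_m * rng_1 + sig_1.min()
    else:
        sig_3 = np.full_like(mad, sig_1.min())

    return CenteringTrace(
        sig_1=sig_1,
        sig_2=sig_2,
        sig_3=sig_3,
        excerpt_start=start,
        center_sample=start + center_local,
    )


def extract_segment(
    record: EegRecord, center_sample: int, L: int = SEGMENT_LENGTH
) -> EegSegment:
    """Cut an L-sample window centered on ``center_sample``.

    The window is ``[center - L//2, center + ceil(L/2))`` -- exactly L
    samples.  Windows overrunning the record edges are zero-padded and
    flagged.
    """
    lo = center_sample - L // 2
    hi = center_sample + (L + 1) // 2
    out = np.zeros(L)
    src_lo = max(lo, 0)
    src_hi = min(hi, record.n_samples)
    padded = src_lo != lo or src_hi != hi
    if src_hi > src_lo:
        out[src_lo - lo : src_hi - lo] = record.samples[src_lo:src_hi]
    if padded:
        logger.info(
            "segment at center %d overruns record %s/%s; zero-padded",
            center_sample,
            record.animal_id,
            record.channel,
        )
    return EegSegment(
        samples=out,
        label="non-HAS",
        animal_id=record.animal_id,
        channel=record.channel,
        group=record.group,
        center_sample=center_sample,
        fs=record.fs,
        padded=padded,
    )


def sample_non_has(
    record: EegRecord,
    truth: GroundTruth,
    n: int,
    L: int = SEGMENT_LENGTH,
    seed: int = 0,
) -> list[EegSegment]:
    """Randomly cut ``n`` L-sample segments that avoid every HAS interval.

    Segments must lie fully inside the record and must not intersect any
    annotated HAS ``[onset, offset)`` interval; artifacts and background are
    fair game by design.  Raises with the shortfall if the seizure-free
    material cannot host ``n`` distinct windows.
    """
    half_lo = L // 2
    half_hi = (L + 1) // 2
    n_samp = record.n_samples
    ok = np.ones(n_samp, dtype=bool)  # candidate centers
    ok[:half_lo] = False
    if half_hi > 0:
        ok[n_samp - half_hi + 1 :] = False
    for onset, offset in truth.has_intervals(record.animal_id, record.channel):
        # window [c-half_lo, c+half_hi) intersects [onset, offset) iff
        # c > onset - half_hi and c < offset + half_lo
        lo = max(0, onset - half_hi + 1)
        hi = min(n_samp, offset + half_lo)
        ok[lo:hi] = False
    candidates = np.flatnonzero(ok)
    if candidates.size < n:
        raise ValueError(
            f"cannot cut {n} non-HAS segments of length {L} from "
            f"{record.animal_id}/{record.channel}: only {candidates.size} "
            "admissible centers outside HAS intervals"
        )
    rng = np.random.default_rng(seed)
    centers = np.sort(rng.choice(candidates, size=n, replace=False))
    return [extract_segment(record, int(c), L=L) for c in centers]


def plot_centering(trace: CenteringTrace, segment: EegSegment, path) -> None:
    """Write the two-panel centering QC figure (excerpt + centered segment)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(10, 6))
    t1 = np.arange(trace.sig_1.size)
    axes[0].plot(t1, trace.sig_1, lw=0.5, label="sig_1 (excerpt)")
    axes[0].plot(t1, trace.sig_3, lw=1.0, label="sig_3 (movmad, rescaled)")
    axes[0].axvline(
        trace.center_sample - trace.excerpt_start,
        color="r",
        ls="--",
        label="center of weight",
    )
    axes[0].set_xlabel("sample")
    axes[0].set_ylabel("uV")
    axes[0].legend(loc="upper right", fontsize=8)
    axes[1].plot(np.arange(segment.length), segment.samples, lw=0.5)
    axes[1].set_title(f"centered segment ({segment.length} samples)")
    axes[1].set_xlabel("sample")
    axes[1].set_ylabel("uV")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
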