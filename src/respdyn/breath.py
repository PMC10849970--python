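"""Diaphragm EMG processing, breath segmentation, respiratory phase.

The respiratory phase convention used throughout the package: breath
onset is phi = 0, breath offset is phi = +pi, and the inter-breath
interval (expiration) spans (-pi, 0), so inspiratory samples have
0 <= phi <= pi.  Phase is piecewise linear in time within inspiration
and within expiration of each breath.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

logger = logging.getLogger(__name__)


@dataclass
class DiaphragmTrace:
    """Integrated, unit-variance diaphragm trace."""

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("diaphragm trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class PhaseSignal:
    """Respiratory phase phi(t) in [-pi, pi] on a uniform timebase.

    Samples outside complete breaths (before the first onset or at/after
    the last usable onset) are NaN.
    """

    phi: np.ndarray
    rate: float
    t0: float = 0.0

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.phi)

    def at_times(self, times: np.ndarray) -> np.ndarray:
        """Nearest-sample phase lookup (NaN outside the signal)."""
        idx = np.round((np.asarray(times) - self.t0) * self.rate).astype(int)
        out = np.full(len(idx), np.nan)
        ok = (idx >= 0) & (idx < len(self.phi))
        out[ok] = self.phi[idx[ok]]
        return out


def integrate_emg(raw: np.ndarray, rate: float) -> DiaphragmTrace:
    """Integrate a raw diaphragm EMG into a normalized 1-kHz envelope.

    Processing order: band-pass 300-5,000 Hz, full-wave rectification,
    50-ms median filter, downsample to 1 kHz, division by the standard
    deviation.  The median filter is evaluated exactly at the retained
    1-kHz output instants (identical to filtering then decimating).

    Parameters
    ----------
    raw : array
        Raw EMG samples.
    rate : float
        Sampling rate in Hz; must be at least 10 kHz (callers with
        already-integrated traces construct :class:`DiaphragmTrace`
        directly).
    """
    raw = np.asarray(raw, dtype=float)
    if rate < 10_000:
        raise ValueError(
            f"raw EMG rate {rate:.0f} Hz is below the 10 kHz minimum needed "
            "for the 300-5,000 Hz band; supply an integrated trace instead"
        )
    high = min(5000.0, 0.45 * rate)
    sos = signal.butter(4, [300.0, high], btype="bandpass", fs=rate, output="sos")
    x = np.abs(signal.sosfiltfilt(sos, raw))

    out_rate = 1000.0
    half = int(round(0.025 * rate))  # 50-ms window
    n_out = int(len(x) * out_rate / rate)
    centers = (np.arange(n_out) * rate / out_rate).astype(int)
    win = 2 * half + 1
    padded = np.pad(x, half, mode="edge")
    windows = sliding_window_view(padded, win)  # windows[i] is centred on x[i]
    env = np.empty(n_out)
    chunk = 200_000
    for s in range(0, n_out, chunk):
        e = min(s + chunk, n_out)
        env[s:e] = np.median(windows[centers[s:e]], axis=1)
    sd = env.std()
    if sd > 0:
        env = env / sd
    return DiaphragmTrace(env, out_rate)


def detect_breaths(
    trace: DiaphragmTrace,
    min_height: float = 0.5,
    min_distance_s: float = 0.1,
    offset_fraction: float = 0.1,
) -> pd.DataFrame:
    """Detect diaphragm bursts and build a breath table.

    Peaks are found with :func:`scipy.signal.find_peaks` (height
    ``min_height`` in s.d. units, minimum separation ``min_distance_s``).
    Each breath's onset and offset are the nearest crossings of
    ``offset_fraction * peak_height`` flanking the peak; ``auc`` is the
    integral of the trace between them; ``ibi`` is onset-to-next-onset.

    Returns a table with columns ``onset, offset, auc, ibi`` (seconds,
    normalized-amplitude * s).  No detected bursts gives an empty table
    with a logged warning.
    """
    x = trace.samples
    peaks, _ = signal.find_peaks(
        x, height=min_height, distance=max(1, int(round(min_distance_s * trace.rate)))
    )
    rows: list[tuple[int, int]] = []
    last_offset = -1
    for p in peaks:
        thr = offset_fraction * x[p]
        below = x[: p + 1] < thr
        onset = int(np.flatnonzero(below)[-1]) + 1 if below.any() else 0
        after = np.flatnonzero(x[p:] < thr)
        offset = int(p + after[0]) if len(after) else len(x) - 1
        if rows and onset <= last_offset:
            # second peak of a merged burst: same envelope crossing pair
            continue
        rows.append((onset, offset))
        last_offset = offset
    if not rows:
        logger.warning("no diaphragm bursts detected")
        return pd.DataFrame(columns=["onset", "offset", "auc", "ibi"])
    df = pd.DataFrame(rows, columns=["onset_idx", "offset_idx"])
    df["onset"] = trace.t0 + df.onset_idx / trace.rate
    df["offset"] = trace.t0 + df.offset_idx / trace.rate
    df["auc"] = [
        np.trapezoid(x[a:b + 1]) / trace.rate
        for a, b in zip(df.onset_idx, df.offset_idx)
    ]
    df["ibi"] = np.append(np.diff(df.onset.values), np.nan)
    return df.drop(columns=["onset_idx", "offset_idx"])


def compute_phase(
    breaths: pd.DataFrame, rate: float, duration: float, t0: float = 0.0
) -> PhaseSignal:
    """Map breath onsets/offsets to a respiratory phase signal.

    phi is exactly 0 at each onset sample and exactly +pi at each offset
    sample, linear in between; from offset to the next onset the
    (unwrapped) phase continues linearly from pi to 2*pi and is wrapped
    to [-pi, pi), so the sample immediately after an offset sits at
    -pi + pi*dt/T_exp and the expiration midpoint is exactly -pi/2.
    Samples before the first onset and at/after the last onset (which
    has no following offset/onset pair) are NaN.
    """
    n = int(round(duration * rate))
    phi = np.full(n, np.nan)
    onsets = np.asarray(breaths["onset"], dtype=float)
    offsets = np.asarray(breaths["offset"], dtype=float)
    if len(onsets) < 2:
        raise ValueError(
            "phase requires at least one complete breath plus the following onset"
        )
    if np.any(np.diff(onsets) <= 0) or np.any(offsets <= onsets):
        raise ValueError("breaths must be strictly increasing and non-overlapping")
    if np.any(offsets[:-1] >= onsets[1:]):
        raise ValueError("overlapping breaths: offset_i >= onset_{i+1}")

    def to_idx(t: float) -> int:
        return int(round((t - t0) * rate))

    for i in range(len(onsets) - 1):
        a, b, c = to_idx(onsets[i]), to_idx(offsets[i]), to_idx(onsets[i + 1])
        b, c = min(b, n - 1), min(c, n)
        if a >= n:
            break
        idx = np.arange(a, b + 1)  # inspiration: 0 -> pi at the offset sample
        phi[idx] = np.pi * ((idx - a) / max(b - a, 1))
        idx = np.arange(b + 1, c)  # expiration: unwrapped pi -> 2 pi, wrapped
        unwrapped = np.pi + np.pi * ((idx - b) / max(c - b, 1))
        phi[idx] = np.mod(unwrapped + np.pi, 2 * np.pi) - np.pi
    return PhaseSignal(phi=phi, rate=rate, t0=t0)


def phase_bin_edges(n_bins: int = 100) -> np.ndarray:
    """Edges of the standard pi/50-wide phase bins spanning [-pi, pi]."""
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def bin_phase(phi: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Assign each phase sample to a bin index in [0, n_bins)."""
    b = np.floor((np.asarray(phi) + np.pi) / (2 * np.pi) * n_bins).astype(int)
    return np.clip(b, 0, n_bins - 1)


def _rolling_center(values: np.ndarray, window: int, fn) -> np.ndarray:
    """Centered rolling statistic with truncated windows at the edges."""
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = fn(values[lo:hi])
    return out


def detect_sighs(
    breaths: pd.DataFrame,
    window: int = 51,
    mad_factor: float = 7.0,
    mad_floor: float = 1e-9,
) -> pd.DataFrame:
    """Flag sighs: breaths whose area exceeds the local median by more
    than ``mad_factor`` times the local median absolute deviation.

    Both rolling statistics use a centered ``window``-breath window
    (truncated at the record edges).  The MAD is floored at
    ``mad_floor`` so a run of identical breaths yields no flags.
    Returns a copy of the table with an ``is_sigh`` column.
    """
    out = breaths.copy()
    auc = np.asarray(breaths["auc"], dtype=float)
    med = _rolling_center(auc, window, np.median)
    mad = _rolling_center(
        auc, window, lambda v: np.median(np.abs(v - np.median(v)))
    )
    out["is_sigh"] = (auc - med) > mad_factor * np.maximum(mad, mad_floor)
    return out


def detect_gasp_epochs(
    breaths: pd.DataFrame,
    window: int = 7,
    start_ibi_s: float = 1.0,
    stop_ibi_s: float = 0.85,
) -> pd.DataFrame:
    """Detect gasping epochs from smoothed inter-breath intervals.

    The IBI series is smoothed with a centered ``window``-breath median
    filter (edges truncated).  An epoch begins at the first breath whose
    smoothed IBI exceeds ``start_ibi_s`` and persists until the smoothed
    IBI falls below ``stop_ibi_s`` (hysteresis: intervals between the
    two thresholds continue the epoch).  Returns one row per epoch with
    breath-index and time bounds.
    """
    ibi = np.asarray(breaths["ibi"], dtype=float)
    valid = ~np.isnan(ibi)
    smoothed = np.full(len(ibi), np.nan)
    if valid.any():
        smoothed[valid] = _rolling_center(ibi[valid], window, np.median)
    epochs = []
    in_epoch = False
    start = 0
    for i, v in enumerate(smoothed):
        if np.isnan(v):
            continue
        if not in_epoch and v > start_ibi_s:
            in_epoch, start = True, i
        elif in_epoch and v < stop_ibi_s:
            epochs.append((start, i - 1))
            in_epoch = False
    if in_epoch:
        epochs.append((start, int(np.max(np.flatnonzero(valid)))))
    rows = [
        {
            "first_breath": a,
            "last_breath": b,
            "start": float(breaths["onset"].iloc[a]),
            "stop": float(breaths["offset"].iloc[b]),
        }
        for a, b in epochs
    ]
    return pd.DataFrame(rows, columns=["first_breath", "last_breath", "start", "stop"])


def gasp_epoch_ids(breaths: pd.DataFrame, epochs: pd.DataFrame) -> np.ndarray:
    """Per-breath gasp-epoch membership (-1 outside any epoch)."""
    ids = np.full(len(breaths), -1)
    for k, row in epochs.iterrows():
        ids[int(row.first_breath): int(row.last_breath) + 1] = k
    return ids
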