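"""Physiological feature extraction.

Computes the 36 indexes of the feature registry from two asynchronous
streams per trial:

* an EEG band-power stream (~1 Hz, 8 relative band powers per sample),
  from which composite wide bands (alpha = low + high alpha, beta =
  low + high beta, gamma = low + mid gamma) and 15-sample moving
  averages are derived;
* an inter-beat-interval (IBI) stream, from which time-domain HRV
  statistics are recomputed over the trailing 30 beats each time a new
  IBI arrives, and frequency-domain statistics (LF, HF, LF/HF) over the
  trailing 200 s.

The two streams are unsynchronised; the per-second feature record takes,
for every index, the most recently computed value at or before that
second.  Values are missing (NaN), never zero-filled, until their window
has filled.

Spectral estimation for LF/HF: the irregularly sampled IBI tachogram in
the trailing 200-s window is linearly interpolated onto a uniform 4 Hz
grid, mean-removed, Hann-tapered, and its periodogram integrated over
bins whose centres fall in 0.04–0.15 Hz (LF, upper edge exclusive) and
0.15–0.40 Hz (HF, inclusive).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import periodogram

from .registry import ALL_FEATURES, EEG_BASE, RAW_BANDS

__all__ = [
    "composite_bands",
    "moving_average",
    "hr_from_ibi",
    "pnnx",
    "time_domain_stats",
    "lf_hf",
    "hrv_records",
    "align_streams",
    "extract_features",
    "read_study_dir",
]

PNN_THRESHOLDS = (10, 20, 30, 40, 50)
IBI_WINDOW = 30  # beats, time-domain sliding window
SPECTRAL_SPAN = 200.0  # s, frequency-domain sliding window
SPECTRAL_FS = 4.0  # Hz, tachogram resampling rate
MIN_SPECTRAL_BEATS = 8
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


def composite_bands(sample: pd.Series | dict) -> dict[str, float]:
    """Extend the 8 raw band powers with alpha, beta and gamma.

    alpha = low_alpha + high_alpha; beta = low_beta + high_beta;
    gamma = low_gamma + mid_gamma.  Raw bands pass through unchanged.
    """
    out = {band: float(sample[band]) for band in RAW_BANDS}
    if any(v < 0 for v in out.values()):
        raise ValueError("band powers must be non-negative")
    out["alpha"] = out["low_alpha"] + out["high_alpha"]
    out["beta"] = out["low_beta"] + out["high_beta"]
    out["gamma"] = out["low_gamma"] + out["mid_gamma"]
    return out


def moving_average(values: Iterable[float], window: int = 15) -> np.ndarray:
    """Trailing moving average; NaN until the window fills.

    Output position ``i`` (for ``i >= window - 1``) is the mean of
    inputs ``i - window + 1 .. i``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = np.asarray(list(values), dtype=float)
    out = np.full(arr.shape, np.nan)
    if arr.size >= window:
        out[window - 1:] = sliding_window_view(arr, window).mean(axis=1)
    return out


def hr_from_ibi(ibi_ms: float) -> float:
    """Heart rate in beats per minute from one IBI in ms."""
    if ibi_ms <= 0:
        raise ValueError("IBI must be positive")
    return 60000.0 / ibi_ms


def pnnx(window_ibis: Iterable[float], x: float) -> float:
    """Proportion of successive IBI differences with \\|diff\\| > x ms."""
    arr = np.asarray(list(window_ibis), dtype=float)
    if arr.size < 2:
        raise ValueError("pNNx needs at least 2 IBIs")
    diffs = np.abs(np.diff(arr))
    return float(np.mean(diffs > x))


def time_domain_stats(window_ibis: Iterable[float]) -> dict[str, float]:
    """SDNN, RMSSD, SDNN/RMSSD and CVNN over one IBI window.

    SDNN is the population (divide-by-N) standard deviation; CVNN is
    SDNN divided by the window mean; the SDNN/RMSSD ratio is NaN when
    RMSSD is zero.
    """
    arr = np.asarray(list(window_ibis), dtype=float)
    if arr.size < 2:
        raise ValueError("time-domain statistics need at least 2 IBIs")
    sdnn = float(np.std(arr))
    diffs = np.diff(arr)
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    return {
        "sdnn": sdnn,
        "rmssd": rmssd,
        "sdnn_rmssd": sdnn / rmssd if rmssd > 0 else np.nan,
        "cvnn": sdnn / float(np.mean(arr)),
    }


def lf_hf(times_s: Iterable[float], ibis_ms: Iterable[float]) -> dict[str, float]:
    """LF and HF spectral power and their ratio for one IBI segment.

    The segment should span >= 200 s with >= 8 beats; shorter input
    raises.  LF/HF is NaN when HF is zero.
    """
    t = np.asarray(list(times_s), dtype=float)
    x = np.asarray(list(ibis_ms), dtype=float)
    if t.size < MIN_SPECTRAL_BEATS or t[-1] - t[0] <= 0:
        raise ValueError("spectral estimation needs >= 8 beats over a positive span")
    grid = np.arange(t[-1] - SPECTRAL_SPAN, t[-1], 1.0 / SPECTRAL_FS)
    resampled = np.interp(grid, t, x)
    freqs, power = periodogram(
        resampled, fs=SPECTRAL_FS, window="hann", detrend="constant"
    )
    df = freqs[1] - freqs[0]
    lf_mask = (freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])
    hf_mask = (freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])
    lf = float(np.sum(power[lf_mask]) * df)
    hf = float(np.sum(power[hf_mask]) * df)
    return {"lf": lf, "hf": hf, "lf_hf": lf / hf if hf > 0 else np.nan}


def hrv_records(ibi: pd.DataFrame) -> pd.DataFrame:
    """Recompute every HRV index at each IBI arrival.

    Parameters
    ----------
    ibi
        Columns ``time_s`` (strictly increasing arrival times) and
        ``ibi_ms`` (positive intervals).

    Returns
    -------
    One row per arrival: ``time_s`` plus the 14 HRV feature columns.
    Windowed indexes are NaN until 30 beats (time domain) or 200 s with
    8 beats (frequency domain) have accumulated.
    """
    t = ibi["time_s"].to_numpy(dtype=float)
    x = ibi["ibi_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("IBI arrival times must be strictly increasing")
    if np.any(x <= 0):
        raise ValueError("IBIs must be positive")
    n = t.size
    out = {name: np.full(n, np.nan) for name in
           ("sdnn", "rmssd", "sdnn_rmssd", "cvnn", "lf", "hf", "lf_hf")}
    out["ibi"] = x.copy()
    out["hr"] = 60000.0 / x
    for thr in PNN_THRESHOLDS:
        out[f"pnn{thr}"] = np.full(n, np.nan)

    if n >= IBI_WINDOW:
        win = sliding_window_view(x, IBI_WINDOW)  # (n-29, 30)
        idx = np.arange(IBI_WINDOW - 1, n)
        sdnn = win.std(axis=1)
        dif = np.diff(win, axis=1)
        rmssd = np.sqrt(np.mean(dif**2, axis=1))
        out["sdnn"][idx] = sdnn
        out["rmssd"][idx] = rmssd
        with np.errstate(divide="ignore", invalid="ignore"):
            out["sdnn_rmssd"][idx] = np.where(rmssd > 0, sdnn / rmssd, np.nan)
        out["cvnn"][idx] = sdnn / win.mean(axis=1)
        adiff = np.abs(dif)
        for thr in PNN_THRESHOLDS:
            out[f"pnn{thr}"][idx] = np.mean(adiff > thr, axis=1)

    for i in range(n):
        if t[i] - t[0] < SPECTRAL_SPAN:
            continue
        lo = np.searchsorted(t, t[i] - SPECTRAL_SPAN, side="left")
        if i + 1 - lo < MIN_SPECTRAL_BEATS:
            continue
        spec = lf_hf(t[lo : i + 1], x[lo : i + 1])
        out["lf"][i], out["hf"][i], out["lf_hf"][i] = spec["lf"], spec["hf"], spec["lf_hf"]

    frame = pd.DataFrame(out)
    frame.insert(0, "time_s", t)
    return frame


def eeg_records(eeg: pd.DataFrame, ma_window: int = 15) -> pd.DataFrame:
    """Per-sample table of the 22 EEG indexes (composites + MA15)."""
    t = eeg["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("EEG sample times must be strictly increasing")
    raw = {band: eeg[band].to_numpy(dtype=float) for band in RAW_BANDS}
    if any(np.any(v < 0) for v in raw.values()):
        raise ValueError("band powers must be non-negative")
    raw["alpha"] = raw["low_alpha"] + raw["high_alpha"]
    raw["beta"] = raw["low_beta"] + raw["high_beta"]
    raw["gamma"] = raw["low_gamma"] + raw["mid_gamma"]
    frame = pd.DataFrame({"time_s": t})
    for name in EEG_BASE:
        frame[name] = raw[name]
    for name in EEG_BASE:
        frame[f"ma15_{name}"] = moving_average(frame[name].to_numpy(), ma_window)
    return frame


def align_streams(
    eeg_feats: pd.DataFrame,
    hrv_feats: pd.DataFrame,
    span: tuple[float, float],
    rate: float = 1.0,
) -> pd.DataFrame:
    """Sample both feature streams at whole seconds of a trial span.

    One record is emitted per whole second in ``(start, stop]``; each
    feature takes the most recent value at or before that second (NaN
    when no prior sample exists).  ``time_s`` in the output counts
    seconds from the span start (1..duration at the default 1 Hz).
    """
    start, stop = span
    step = 1.0 / rate
    queries = start + step * np.arange(1, int(np.floor((stop - start) * rate)) + 1)
    if queries.size == 0:
        return pd.DataFrame(columns=["time_s", *ALL_FEATURES])
    grid = pd.DataFrame({"_query": queries})

    def asof(stream: pd.DataFrame) -> pd.DataFrame:
        s = stream.sort_values("time_s")
        merged = pd.merge_asof(
            grid, s, left_on="_query", right_on="time_s", direction="backward"
        )
        return merged.drop(columns=["_query", "time_s"])

    eeg_part = asof(eeg_feats)
    hrv_part = asof(hrv_feats)
    out = pd.concat([eeg_part, hrv_part], axis=1)
    out.insert(0, "time_s", queries - start)
    return out[["time_s", *ALL_FEATURES]]


def extract_features(
    trials: Iterable,
    span: tuple[float, float],
    rate: float = 1.0,
) -> pd.DataFrame:
    """Build the tidy feature table for a collection of trials.

    Parameters
    ----------
    trials
        Objects with ``pid``, ``trial``, ``eeg`` (time_s + 8 band
        columns) and ``ibi`` (time_s, ibi_ms) attributes — e.g.
        :class:`~emophys.synthetic.SimulatedTrial`.
    span
        (start, stop) of the labelled window within each trial stream.

    Returns
    -------
    DataFrame with ``pid, trial, time_s`` keys and the 36 feature
    columns in registry order (22 EEG-derived, 14 HRV-derived).
    """
    pieces = []
    for t in trials:
        aligned = align_streams(eeg_records(t.eeg), hrv_records(t.ibi), span, rate)
        aligned.insert(0, "trial", t.trial)
        aligned.insert(0, "pid", t.pid)
        pieces.append(aligned)
    if not pieces:
        return pd.DataFrame(columns=["pid", "trial", "time_s", *ALL_FEATURES])
    return pd.concat(pieces, ignore_index=True)


class _TrialStreams:
    """Minimal trial container for streams read back from disk."""

    def __init__(self, pid: int, trial: int, eeg: pd.DataFrame, ibi: pd.DataFrame):
        self.pid, self.trial, self.eeg, self.ibi = pid, trial, eeg, ibi


def read_study_dir(path: str | Path):
    """Read the CSV stream layout written by the synthetic module.

    Returns ``(trials, sam, span)`` where ``trials`` is a list of
    per-trial stream holders, ``sam`` the ratings table and ``span`` the
    labelled window recorded in ``ground_truth.json`` (``None`` when the
    file is absent — the caller must then supply a span).
    """
    import json

    path = Path(path)
    trials = []
    for eeg_file in sorted(path.glob("eeg_*_*.csv")):
        _, pid, trial = eeg_file.stem.split("_")
        ibi_file = path / f"ibi_{pid}_{trial}.csv"
        trials.append(
            _TrialStreams(
                int(pid), int(trial), pd.read_csv(eeg_file), pd.read_csv(ibi_file)
            )
        )
    trials.sort(key=lambda t: (t.pid, t.trial))
    sam = pd.read_csv(path / "sam.csv") if (path / "sam.csv").exists() else None
    span = None
    truth_file = path / "ground_truth.json"
    if truth_file.exists():
        span = tuple(json.loads(truth_file.read_text())["span"])
    return trials, sam, span
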