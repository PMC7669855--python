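"""Preprocessing: from raw epochs to the two analysis streams.

The conventional (ERP) stream band-pass filters to 2–40 Hz, flags trials with
amplitude deviations above 100 uV inside the window of interest, and
baseline-corrects to the −150…0 ms mean. The decoding stream filters to
2–25 Hz, averages non-overlapping 20-ms bins and vectorizes the
channel × bin matrix into per-trial feature vectors (301 = 7 × 43 dimensions
for the default whole-epoch span; 7 for a single interval). Rejection only
flags trials — it never drops or reorders them — and the decoding stream
deliberately keeps all trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochsSet


@dataclass
class FeatureMatrix:
    """Per-trial feature vectors with column provenance.

    ``X`` is ``(n_trials, n_features)`` of bin-averaged amplitudes (uV);
    ``columns`` is a DataFrame with one row per feature: ``channel``,
    ``bin_start_ms``, ``bin_end_ms``. ``labels`` aligns with rows.
    """

    X: np.ndarray
    labels: np.ndarray
    columns: pd.DataFrame
    subject: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (trials x features)")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels length must match rows")
        if len(self.columns) != self.X.shape[1]:
            raise ValueError("column metadata must cover every column exactly once")


def bandpass_filter(epochs: EpochsSet, low: float, high: float) -> EpochsSet:
    """Zero-phase band-pass (4th-order Butterworth, forward-backward).

    Applied with odd-reflection padding of at least three time constants of
    the high-pass edge (capped at the epoch length), so a DC offset is
    removed and a symmetric pulse keeps its peak latency.
    """
    nyq = epochs.sfreq / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(4, [low, high], btype="bandpass", fs=epochs.sfreq, output="sos")
    padlen = min(epochs.n_samples - 1, int(3 * epochs.sfreq / low))
    out = signal.sosfiltfilt(sos, epochs.data, axis=-1, padtype="odd", padlen=padlen)
    return epochs.with_data(out)


def remove_trigger_leak(epochs: EpochsSet, leak_template: np.ndarray) -> EpochsSet:
    """Remove a stimulus trigger leak by a per-trace general linear model.

    For every trial and channel the least-squares projection of the trace
    onto ``[intercept, leak_template]`` is subtracted, leaving a residual
    orthogonal to the regressor.
    """
    leak = np.asarray(leak_template, dtype=np.float64).ravel()
    if leak.size != epochs.n_samples:
        raise ValueError("leak template length must equal samples per epoch")
    if np.all(leak == 0):
        warnings.warn("all-zero leak regressor: nothing to remove", stacklevel=2)
        return epochs.copy()
    design = np.column_stack([np.ones_like(leak), leak])  # (n_samples, 2)
    # beta for every (trial, channel) trace at once
    pinv = np.linalg.pinv(design)  # (2, n_samples)
    flat = epochs.data.reshape(-1, epochs.n_samples)
    beta = flat @ pinv.T  # (n_traces, 2)
    resid = flat - beta @ design.T
    return epochs.with_data(resid.reshape(epochs.data.shape))


def amplitude_deviations(epochs: EpochsSet, window_ms: tuple) -> pd.DataFrame:
    """Per trial and channel, the maximum absolute deviation from the
    trace's own within-window mean; the statistic behind rejection."""
    t0, t1 = window_ms
    mask = epochs.time_mask(t0, t1)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    seg = epochs.data[:, :, mask]
    dev = np.abs(seg - seg.mean(axis=-1, keepdims=True)).max(axis=-1)
    n_tr, n_ch = dev.shape
    return pd.DataFrame(
        {
            "trial": np.repeat(np.arange(n_tr), n_ch),
            "channel": np.tile(epochs.channels, n_tr),
            "max_deviation_uV": dev.ravel(),
        }
    )


def reject_by_amplitude(
    epochs: EpochsSet, threshold_uV: float = 100.0,
    window_ms: tuple = (-150.0, 350.0),
) -> EpochsSet:
    """Flag trials whose deviation exceeds ``threshold_uV`` on any channel.

    Deviation is measured from each trace's own mean within ``window_ms``
    (robust to DC offsets). Kept trials are returned unmodified; flagged
    trials get ``kept = False`` and a reason naming the worst channel.
    """
    if threshold_uV <= 0:
        raise ValueError("threshold must be positive")
    dev_long = amplitude_deviations(epochs, window_ms)
    dev = dev_long["max_deviation_uV"].to_numpy().reshape(epochs.n_trials, -1)
    out = epochs.copy()
    bad = dev.max(axis=1) > threshold_uV
    for idx in np.flatnonzero(bad):
        ch = epochs.channels[int(np.argmax(dev[idx]))]
        out.kept[idx] = False
        out.reject_reason[idx] = f"amplitude {dev[idx].max():.1f}uV>{threshold_uV:g}uV@{ch}"
    return out


def baseline_correct(epochs: EpochsSet, window_ms: tuple = (-150.0, 0.0)) -> EpochsSet:
    """Subtract each trace's mean over the baseline window (idempotent)."""
    t0, t1 = window_ms
    mask = epochs.time_mask(t0, t1)
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} contains no samples")
    base = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return epochs.with_data(epochs.data - base)


def bin_starts(times_ms: np.ndarray, sfreq: float, bin_width_ms: float) -> np.ndarray:
    """Start times of the complete half-open bins tiling the epoch.

    Bins are defined on the millisecond time axis, not on sample counts:
    ``[t0 + k*w, t0 + (k+1)*w)``. A trailing bin whose end exceeds the epoch
    coverage (last sample time plus one sample period) is dropped.
    """
    if bin_width_ms < 1000.0 / sfreq:
        raise ValueError("bin width must be at least one sample period")
    t0 = times_ms[0]
    t_end = times_ms[-1] + 1000.0 / sfreq
    n_bins = int(np.floor((t_end - t0) / bin_width_ms + 1e-9))
    return t0 + np.arange(n_bins) * bin_width_ms


def bin_epochs(epochs: EpochsSet, bin_width_ms: float = 20.0) -> EpochsSet:
    """Average temporally adjacent samples in non-overlapping bins.

    Each output sample is the mean of the input samples whose timestamps
    fall in ``[start, start + w)``; because 20 ms at 512 Hz is 10.24
    samples, bins contain 10 or 11 samples. The output time axis holds bin
    start times at rate ``1000 / w``.
    """
    starts = bin_starts(epochs.times, epochs.sfreq, bin_width_ms)
    idx = np.floor((epochs.times - epochs.times[0]) / bin_width_ms + 1e-9).astype(int)
    out = np.empty((epochs.n_trials, epochs.n_channels, starts.size))
    for k in range(starts.size):
        out[:, :, k] = epochs.data[:, :, idx == k].mean(axis=-1)
    binned = EpochsSet(
        data=out,
        times=starts,
        sfreq=1000.0 / bin_width_ms,
        channels=list(epochs.channels),
        labels=epochs.labels.copy(),
        subject=epochs.subject,
        kept=epochs.kept.copy(),
        reject_reason=epochs.reject_reason.copy(),
        info={**epochs.info, "bin_width_ms": float(bin_width_ms)},
    )
    return binned


def vectorize_features(
    binned: EpochsSet, mode: str = "whole-epoch", interval_index: int | None = None
) -> FeatureMatrix:
    """Flatten binned epochs to per-trial feature vectors.

    ``whole-epoch`` concatenates channels channel-major (all bins of F3,
    then all bins of F4, ...), giving ``n_channels * n_bins`` columns —
    301 for 7 channels x 43 bins. ``single-interval`` takes one bin,
    giving ``n_channels`` columns.
    """
    w = float(binned.info.get("bin_width_ms", 1000.0 / binned.sfreq))
    n_bins = binned.n_samples
    if mode == "whole-epoch":
        if interval_index is not None:
            raise ValueError("interval_index is only valid in single-interval mode")
        X = binned.data.reshape(binned.n_trials, -1)  # channel-major
        cols = pd.DataFrame(
            {
                "channel": np.repeat(binned.channels, n_bins),
                "bin_start_ms": np.tile(binned.times, binned.n_channels),
            }
        )
    elif mode == "single-interval":
        if interval_index is None:
            raise ValueError("single-interval mode requires interval_index")
        if not (0 <= interval_index < n_bins):
            raise ValueError(
                f"interval_index {interval_index} out of range [0, {n_bins})"
            )
        X = binned.data[:, :, interval_index]
        cols = pd.DataFrame(
            {
                "channel": list(binned.channels),
                "bin_start_ms": np.full(binned.n_channels, binned.times[interval_index]),
            }
        )
    else:
        raise ValueError("mode must be 'whole-epoch' or 'single-interval'")
    cols["bin_end_ms"] = cols["bin_start_ms"] + w
    return FeatureMatrix(X=X, labels=binned.labels.copy(), columns=cols,
                         subject=binned.subject)


def erp_stream(
    epochs: EpochsSet,
    band: tuple = (2.0, 40.0),
    reject_uV: float = 100.0,
    reject_window_ms: tuple = (-150.0, 350.0),
    baseline_ms: tuple = (-150.0, 0.0),
    leak_template: np.ndarray | None = None,
) -> EpochsSet:
    """The conventional-analysis stream: filter, reject, baseline-correct."""
    out = epochs
    if leak_template is not None:
        out = remove_trigger_leak(out, leak_template)
    out = bandpass_filter(out, *band)
    out = reject_by_amplitude(out, reject_uV, reject_window_ms)
    return baseline_correct(out, baseline_ms)


def decoding_stream(
    epochs: EpochsSet,
    band: tuple = (2.0, 25.0),
    bin_width_ms: float = 20.0,
    leak_template: np.ndarray | None = None,
) -> EpochsSet:
    """The machine-learning stream: filter and bin; all trials kept."""
    out = epochs
    if leak_template is not None:
        out = remove_trigger_leak(out, leak_template)
    out = bandpass_filter(out, *band)
    return bin_epochs(out, bin_width_ms)
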