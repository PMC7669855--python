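"""Epoched multi-channel EEG container.

:class:`EpochsSet` is the substrate of every pipeline stage: a
``trials x channels x samples`` tensor in microvolts, a millisecond time axis
relative to stimulus onset, per-trial category labels and kept/rejected
bookkeeping. The on-disk form is a ``.npz`` tensor next to a JSON sidecar
(format documented in :func:`save_epochs`) so that it stays readable with
plain numpy and a JSON parser.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .labels import CategoryLabel, as_label

CONTAINER_VERSION = 1


@dataclass
class EpochsSet:
    """Epoched EEG for one subject.

    Parameters
    ----------
    data
        ``(n_trials, n_channels, n_samples)`` array, microvolts.
    times
        ``(n_samples,)`` time axis in milliseconds relative to stimulus
        onset; strictly increasing and uniform at ``sfreq``.
    sfreq
        Sampling frequency in Hz.
    channels
        Channel names, length ``n_channels``.
    labels
        Per-trial :class:`~caneeg.labels.CategoryLabel` codes.
    subject
        Subject identifier.
    kept
        Per-trial boolean flag; rejection stages clear it but never drop or
        reorder trials.
    reject_reason
        Per-trial string, empty for kept trials.
    info
        Free-form provenance (seeds, ground-truth artifact indices, ...).
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    channels: list[str]
    labels: np.ndarray
    subject: str = "sim"
    kept: np.ndarray | None = None
    reject_reason: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n_trials, n_channels, n_samples = self.data.shape
        if self.times.shape != (n_samples,):
            raise ValueError("times length does not match data samples")
        if len(self.channels) != n_channels:
            raise ValueError("channel names do not match data channels")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        dt = np.diff(self.times)
        if n_samples > 1:
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(dt, 1000.0 / self.sfreq, rtol=1e-6, atol=1e-6):
                raise ValueError("time axis is not uniform at the stated rate")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        self.labels = np.asarray(
            [as_label(lb).value for lb in np.asarray(self.labels).ravel()],
            dtype=object,
        )
        if self.labels.shape != (n_trials,):
            raise ValueError("labels length does not match trial count")
        if self.kept is None:
            self.kept = np.ones(n_trials, dtype=bool)
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.kept.shape != (n_trials,):
            raise ValueError("kept flags do not match trial count")
        if self.reject_reason is None:
            self.reject_reason = np.array([""] * n_trials, dtype=object)
        self.reject_reason = np.asarray(self.reject_reason, dtype=object)

    # -- basic introspection -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochsSet":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            channels=list(self.channels),
            labels=self.labels.copy(),
            kept=self.kept.copy(),
            reject_reason=self.reject_reason.copy(),
            info=dict(self.info),
        )

    def with_data(self, data: np.ndarray) -> "EpochsSet":
        """Same metadata, new tensor of identical shape."""
        out = self.copy()
        data = np.asarray(data, dtype=np.float64)
        if data.shape != self.data.shape:
            raise ValueError("replacement tensor must keep the shape")
        out.data = data
        return out

    def trial_mask(self, condition=None, kept_only: bool = False) -> np.ndarray:
        """Boolean mask selecting trials of ``condition`` (a label, an
        iterable of labels, or None for all), optionally kept trials only."""
        mask = np.ones(self.n_trials, dtype=bool)
        if condition is not None:
            if isinstance(condition, (str, CategoryLabel)):
                condition = [condition]
            codes = {as_label(c).value for c in condition}
            mask &= np.array([lb in codes for lb in self.labels])
        if kept_only:
            mask = mask & self.kept
        return mask

    def select(self, condition=None, kept_only: bool = False) -> "EpochsSet":
        """Subset of trials as a new :class:`EpochsSet`."""
        m = self.trial_mask(condition, kept_only)
        return replace(
            self,
            data=self.data[m],
            labels=self.labels[m],
            kept=self.kept[m],
            reject_reason=self.reject_reason[m],
            info=dict(self.info),
        )

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Mask over samples with ``start_ms <= t < stop_ms`` (half-open)."""
        if not stop_ms > start_ms:
            raise ValueError("empty time window")
        return (self.times >= start_ms) & (self.times < stop_ms)


def save_epochs(epochs: EpochsSet, path: "str | Path") -> Path:
    """Write ``<path>.npz`` (key ``data``) and ``<path>.json`` sidecar.

    Sidecar fields: ``version``, ``subject``, ``sfreq``, ``channels``,
    ``times_ms``, ``labels``, ``kept``, ``reject_reason``, ``info``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), data=epochs.data)
    sidecar = {
        "version": CONTAINER_VERSION,
        "subject": epochs.subject,
        "sfreq": epochs.sfreq,
        "channels": list(epochs.channels),
        "times_ms": epochs.times.tolist(),
        "labels": [str(lb) for lb in epochs.labels],
        "kept": epochs.kept.astype(int).tolist(),
        "reject_reason": [str(r) for r in epochs.reject_reason],
        "info": _jsonable(epochs.info),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path.with_suffix(".npz")


def load_epochs(path: "str | Path") -> EpochsSet:
    """Inverse of :func:`save_epochs`; exact round-trip of tensor and metadata."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar.get("version") != CONTAINER_VERSION:
        raise ValueError(f"unsupported container version {sidecar.get('version')!r}")
    with np.load(path.with_suffix(".npz")) as npz:
        data = npz["data"]
    return EpochsSet(
        data=data,
        times=np.asarray(sidecar["times_ms"], dtype=np.float64),
        sfreq=float(sidecar["sfreq"]),
        channels=list(sidecar["channels"]),
        labels=np.asarray(sidecar["labels"], dtype=object),
        subject=sidecar["subject"],
        kept=np.asarray(sidecar["kept"], dtype=bool),
        reject_reason=np.asarray(sidecar["reject_reason"], dtype=object),
        info=sidecar.get("info", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
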