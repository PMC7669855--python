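"""Continuous-recording input and epoching.

Continuous EEG arrives as European Data Format (EDF/EDF+) with stimulus
onsets as annotations whose descriptions name the stimulus categories (a
mapping can translate recording-specific descriptions). Reading goes
through MNE's EDF reader; epochs are cut on a half-open millisecond span
around each event into the package's :class:`~caneeg.epochs.EpochsSet`
container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import EpochsSet
from .labels import as_label


@dataclass
class ContinuousRecording:
    """Continuous multi-channel EEG in microvolts, with onset events."""

    data: np.ndarray  # (n_channels, n_samples), uV
    sfreq: float
    channels: list
    events: pd.DataFrame  # columns: sample, onset_s, label

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_edf(path, event_map: dict | None = None, channels=None) -> ContinuousRecording:
    """Read an EDF/EDF+ file and its annotation events.

    Parameters
    ----------
    path
        EDF file path.
    event_map
        Optional mapping from annotation description to category code; by
        default descriptions are used verbatim and non-category
        annotations are ignored.
    channels
        Channel subset/order to keep (default: all, file order).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw.pick(list(channels))
    data = raw.get_data() * 1e6  # MNE holds volts
    rows = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        desc = str(desc)
        if event_map is not None:
            if desc not in event_map:
                continue
            desc = event_map[desc]
        try:
            label = as_label(desc).value
        except ValueError:
            continue
        rows.append({"sample": int(round(onset * raw.info["sfreq"])),
                     "onset_s": float(onset), "label": label})
    events = pd.DataFrame(rows, columns=["sample", "onset_s", "label"])
    return ContinuousRecording(
        data=data,
        sfreq=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        events=events,
    )


def epoch(
    recording: ContinuousRecording,
    span_ms: tuple = (-150.0, 350.0),
    subject: str = "edf",
    events: pd.DataFrame | None = None,
) -> EpochsSet:
    """Cut epochs around stimulus onsets.

    The epoch covers ``[span[0], span[1])`` ms relative to each event,
    with ``ceil(span * sfreq / 1000)`` samples. Events whose epoch would
    leave the recording are skipped with a warning reporting the count.
    """
    ev = recording.events if events is None else events
    if ev.empty:
        raise ValueError("no resolvable events to epoch around")
    t0, t1 = span_ms
    if not t1 > t0:
        raise ValueError("epoch span must be non-empty")
    fs = recording.sfreq
    n_samp = int(np.ceil((t1 - t0) * fs / 1000.0))
    offset = int(round(t0 * fs / 1000.0))
    trials, labels, skipped = [], [], 0
    for _, row in ev.iterrows():
        start = int(row["sample"]) + offset
        stop = start + n_samp
        if start < 0 or stop > recording.n_samples:
            skipped += 1
            continue
        trials.append(recording.data[:, start:stop])
        labels.append(row["label"])
    if skipped:
        warnings.warn(
            f"skipped {skipped} event(s) whose epoch leaves the recording",
            stacklevel=2,
        )
    if not trials:
        raise ValueError("every event fell outside the recording")
    times = t0 + np.arange(n_samp) * (1000.0 / fs)
    return EpochsSet(
        data=np.stack(trials),
        times=times,
        sfreq=fs,
        channels=list(recording.channels),
        labels=np.asarray(labels, dtype=object),
        subject=subject,
        info={"source": "edf", "n_events_skipped": skipped},
    )
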