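"""Shared fixtures: small simulation configs and a minimal EDF writer."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from caneeg.simulate import ComponentSpec, SimulationConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_config():
    """Two subjects, few trials, short epochs; fast but full-featured."""
    return SimulationConfig(
        n_subjects=2,
        trials_per_condition=(10, 12),
        epoch_span_ms=(-150.0, 350.0),
        seed=7,
    )


@pytest.fixture
def clean_config():
    """Noise-free, artifact-free single component on P3 for category S."""
    comp = ComponentSpec(
        latency_ms=100.0, width_ms=10.0, amplitude={"P3": 5.0}, categories=("S",)
    )
    return SimulationConfig(
        n_subjects=1,
        trials_per_condition=(5, 5),
        epoch_span_ms=(-150.0, 350.0),
        components=(comp,),
        noise_sd=0.0,
        white_sd=0.0,
        amplitude_jitter_sd=0.0,
        artifact_prob=0.0,
        trigger_leak_amplitude=0.0,
        seed=1,
    )


def write_edf(path, data_uV: np.ndarray, sfreq: float, ch_names,
              annotations=None) -> None:
    """Write a minimal single-record EDF+C file.

    ``data_uV`` is (n_channels, n_samples); ``annotations`` is a list of
    ``(onset_seconds, description)``. Only what the tests need: one data
    record spanning the whole signal, 16-bit samples, microvolt scaling.
    No installed package writes EDF, hence this test-only helper.
    """
    data_uV = np.asarray(data_uV, dtype=np.float64)
    n_ch, n_samp = data_uV.shape
    duration = n_samp / sfreq
    annotations = annotations or []

    # timestamp TAL + one TAL per event, padded to an even byte count
    tal = b"+0\x14\x14\x00"
    for onset, desc in annotations:
        tal += f"+{onset:g}\x14{desc}\x14\x00".encode("ascii")
    if len(tal) % 2:
        tal += b"\x00"
    n_annot_samp = len(tal) // 2

    n_signals = n_ch + 1
    header_bytes = 256 * (n_signals + 1)

    def f(text, width):
        b = str(text).encode("ascii")
        assert len(b) <= width
        return b.ljust(width)

    hdr = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate 01-JAN-2020 X X X", 80),
        f("01.01.20", 8), f("00.00.00", 8), f(header_bytes, 8),
        f("EDF+C", 44), f(1, 8), f(f"{duration:g}", 8), f(n_signals, 4),
    ])
    labels = [f(ch, 16) for ch in ch_names] + [f("EDF Annotations", 16)]
    transducer = [f("", 80)] * n_signals
    phys_dim = [f("uV", 8)] * n_ch + [f("", 8)]
    phys_min = [f("-3276.8", 8)] * n_ch + [f(-1, 8)]
    phys_max = [f("3276.7", 8)] * n_ch + [f(1, 8)]
    dig_min = [f(-32768, 8)] * n_ch + [f(-32768, 8)]
    dig_max = [f(32767, 8)] * n_ch + [f(32767, 8)]
    prefilter = [f("", 80)] * n_signals
    n_per_rec = [f(n_samp, 8)] * n_ch + [f(n_annot_samp, 8)]
    reserved = [f("", 32)] * n_signals
    for block in (labels, transducer, phys_dim, phys_min, phys_max,
                  dig_min, dig_max, prefilter, n_per_rec, reserved):
        hdr += b"".join(block)

    body = b""
    for ch in range(n_ch):
        digital = np.clip(np.round(data_uV[ch] * 10.0), -32768, 32767).astype("<i2")
        body += digital.tobytes()
    body += tal

    with open(path, "wb") as fh:
        fh.write(hdr + body)


@pytest.fixture
def edf_writer():
    return write_edf
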