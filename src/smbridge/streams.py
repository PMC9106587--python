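"""Photon streams: the raw time-tagged record behind every fluctuation analysis.

A :class:`PhotonStream` is the in-memory form of a TTTR-style acquisition:
arrival times in seconds plus, per photon, the detection channel (donor ``D``
or acceptor ``A``) and the excitation gate (``Dex``/``Aex``) assigned by
pulsed interleaved excitation.  Streams round-trip losslessly through a
tab-delimited text layout and an equivalent HDF5 layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("D", "A")
GATES = ("Dex", "Aex")


@dataclass
class PhotonStream:
    """Timestamped photon events with channel and excitation-gate tags.

    Parameters
    ----------
    times:
        Arrival times in seconds, nondecreasing.
    channel:
        Per-photon detection channel code, 0 = donor, 1 = acceptor.
    gate:
        Per-photon excitation gate code, 0 = Dex, 1 = Aex.
    duration:
        Acquisition length in seconds; all times lie in [0, duration].
    """

    times: np.ndarray
    channel: np.ndarray
    gate: np.ndarray
    duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.channel = np.asarray(self.channel, dtype=np.uint8)
        self.gate = np.asarray(self.gate, dtype=np.uint8)
        if not (len(self.times) == len(self.channel) == len(self.gate)):
            raise ValueError("times/channel/gate must have equal length")
        if self.duration < 0:
            raise ValueError("duration must be nonnegative")
        if len(self.times):
            if np.any(np.diff(self.times) < 0):
                raise ValueError("photon times must be nondecreasing")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValueError("photon times must lie within [0, duration]")
            if self.channel.max() > 1 or self.gate.max() > 1:
                raise ValueError("channel/gate codes must be 0 or 1")

    def __len__(self) -> int:
        return len(self.times)

    def select(self, channel: str | None = None, gate: str | None = None) -> np.ndarray:
        """Arrival times of photons matching a channel and/or gate tag."""
        mask = np.ones(len(self.times), dtype=bool)
        if channel is not None:
            mask &= self.channel == CHANNELS.index(channel)
        if gate is not None:
            mask &= self.gate == GATES.index(gate)
        return self.times[mask]

    def counts(self, bin_time: float, channel: str | None = None,
               gate: str | None = None) -> np.ndarray:
        """Photon counts on a regular grid of ``bin_time``-wide bins."""
        if bin_time <= 0:
            raise ValueError("bin_time must be positive")
        n_bins = max(int(np.floor(self.duration / bin_time)), 1)
        t = self.select(channel, gate)
        idx = np.minimum((t / bin_time).astype(np.int64), n_bins - 1)
        return np.bincount(idx, minlength=n_bins).astype(np.int64)


def write_stream_tsv(stream: PhotonStream, path) -> None:
    df = pd.DataFrame({
        "time_s": stream.times,
        "channel": np.array(CHANNELS)[stream.channel],
        "gate": np.array(GATES)[stream.gate],
    })
    with open(path, "w") as fh:
        fh.write(f"#duration_s={stream.duration!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_stream_tsv(path) -> PhotonStream:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#duration_s="):
            raise ValueError("missing #duration_s sidecar header")
        duration = float(header.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return PhotonStream(
        times=df["time_s"].to_numpy(),
        channel=np.array([CHANNELS.index(c) for c in df["channel"]], dtype=np.uint8),
        gate=np.array([GATES.index(g) for g in df["gate"]], dtype=np.uint8),
        duration=duration,
    )


def write_stream_hdf5(stream: PhotonStream, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("time_s", data=stream.times)
        fh.create_dataset("channel", data=stream.channel)
        fh.create_dataset("gate", data=stream.gate)
        fh.attrs["duration_s"] = stream.duration


def read_stream_hdf5(path) -> PhotonStream:
    import h5py

    with h5py.File(path, "r") as fh:
        return PhotonStream(
            times=fh["time_s"][:],
            channel=fh["channel"][:],
            gate=fh["gate"][:],
            duration=float(fh.attrs["duration_s"]),
        )
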