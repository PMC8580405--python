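"""Core containers: region-level recordings and epoch sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegionRecording:
    """A multichannel (region-level) time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitude per region (microvolts for real EEG; arbitrary
        units for simulated data).
    fs : float
        Sampling rate in Hz.
    labels : list of str
        One unique label per channel/region.
    lesion_side : {"left", "right", "none"}
        Side of the occipital lesion; "none" for controls/simulated
        healthy subjects.
    meta : dict
        Free-form provenance (seed, subject id, time point, ...).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    lesion_side: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} channels but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")
        if self.lesion_side not in ("left", "right", "none"):
            raise ValueError(f"invalid lesion_side {self.lesion_side!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Overlapping fixed-length epochs cut from a recording.

    ``epochs`` has shape (n_epochs, n_channels, samples_per_epoch); epoch k
    starts at ``k * (epoch_length_s - overlap_s)`` seconds into the source
    recording.
    """

    epochs: np.ndarray
    fs: float
    labels: list[str]
    epoch_length_s: float = 2.0
    overlap_s: float = 0.5
    lesion_side: str = "none"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x channels x samples)")
        expected = int(round(self.epoch_length_s * self.fs))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} samples does not match "
                f"{self.epoch_length_s} s at {self.fs} Hz (= {expected})"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def step_s(self) -> float:
        return self.epoch_length_s - self.overlap_s
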