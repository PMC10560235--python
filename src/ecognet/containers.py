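"""In-memory containers for continuous recordings and epoched trial data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class Recording:
    """A continuous multichannel recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in physical units (conventionally microvolts).
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel labels.
    roi_map : dict, optional
        Mapping from channel label to region-of-interest label
        (e.g. HG, STG, IFGop, IFGtri, TP).
    """

    samples: np.ndarray
    fs: float
    labels: list[str]
    roi_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("number of labels must match number of channels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class Epochs:
    """Trial-segmented data: trials x channels x time plus annotations.

    The epoch window is half-open ``[tmin, tmin + n_times/fs)`` in seconds
    relative to the event onset, with 0-based sample indexing.
    """

    data: np.ndarray
    fs: float
    tmin: float
    labels: list[str]
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)
    baseline: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x time)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("number of labels must match number of channels")
        if len(self.annotations) not in (0, self.data.shape[0]):
            raise ValueError("annotations length must equal the number of trials")
        if len(self.annotations) and not isinstance(
            self.annotations.index, pd.RangeIndex
        ):
            self.annotations = self.annotations.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_times) / self.fs

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples in the half-open window ``[t0, t1)``."""
        t = self.times
        return (t >= window[0] - 1e-12) & (t < window[1] - 1e-12)

    def select_trials(self, idx) -> "Epochs":
        idx = np.asarray(idx)
        ann = (
            self.annotations.iloc[idx].reset_index(drop=True)
            if len(self.annotations)
            else self.annotations
        )
        return Epochs(
            self.data[idx], self.fs, self.tmin, list(self.labels), ann, self.baseline
        )

    def copy_with(self, **kw) -> "Epochs":
        return replace(self, **kw)
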