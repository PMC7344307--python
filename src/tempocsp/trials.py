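"""Epoched EEG trial container.

A :class:`TrialSet` is the universal in-memory object of this package: a
stack of equally sized epochs (trials x channels x samples) with per-trial
class labels in ``{1, 2}``, the sampling rate, and the cue-onset time.  All
time windows downstream are referenced to the cue onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["TrialSet"]


@dataclass
class TrialSet:
    """Epoched, labeled multichannel EEG trials.

    Parameters
    ----------
    signals : ndarray, shape (n_trials, n_channels, n_samples)
        Epoch data in the recording's amplitude units (typically microvolt).
    labels : ndarray, shape (n_trials,)
        Per-trial class, values in ``{1, 2}``.
    fs : float
        Sampling rate in Hz.
    cue_onset_s : float
        Time of the imagery cue relative to the start of each epoch, in
        seconds.
    channel_names : list of str, optional
        One name per channel; generated as ``ch00, ch01, ...`` if omitted.
    """

    signals: np.ndarray
    labels: np.ndarray
    fs: float
    cue_onset_s: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.signals.ndim != 3:
            raise ValueError(
                f"signals must be 3-D (trials, channels, samples); got shape {self.signals.shape}"
            )
        if self.labels.shape != (self.signals.shape[0],):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match {self.signals.shape[0]} trials"
            )
        bad = set(np.unique(self.labels)) - {1, 2}
        if bad:
            raise ValueError(f"labels must be in {{1, 2}}; found {sorted(bad)}")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be positive; got {self.fs}")
        if self.cue_onset_s < 0 or self.cue_onset_s * self.fs > self.signals.shape[2]:
            raise ValueError(f"cue_onset_s={self.cue_onset_s} lies outside the trial")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.signals.shape[1])]
        if len(self.channel_names) != self.signals.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.signals.shape[1]} channels"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def class_indices(self, label: int) -> np.ndarray:
        """Trial indices belonging to class ``label``."""
        return np.flatnonzero(self.labels == label)

    def subset(self, indices) -> "TrialSet":
        """A new TrialSet holding the given trials (order preserved)."""
        idx = np.asarray(indices)
        return TrialSet(
            signals=self.signals[idx].copy(),
            labels=self.labels[idx].copy(),
            fs=self.fs,
            cue_onset_s=self.cue_onset_s,
            channel_names=list(self.channel_names),
        )

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}") from None

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Write to the package's HDF5 container.

        Datasets: ``signals``, ``labels``, ``fs``, ``cue_onset_s``,
        ``channel_names``.  The round trip is bitwise exact for signals
        and labels.
        """
        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=self.signals)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("fs", data=float(self.fs))
            f.create_dataset("cue_onset_s", data=float(self.cue_onset_s))
            f.create_dataset(
                "channel_names",
                data=np.array([n.encode("utf-8") for n in self.channel_names]),
            )

    @classmethod
    def load(cls, path) -> "TrialSet":
        with h5py.File(path, "r") as f:
            return cls(
                signals=f["signals"][...],
                labels=f["labels"][...],
                fs=float(f["fs"][()]),
                cue_onset_s=float(f["cue_onset_s"][()]),
                channel_names=[n.decode("utf-8") for n in f["channel_names"][...]],
            )

    def equals(self, other: "TrialSet") -> bool:
        """Bitwise equality of data and metadata."""
        return (
            np.array_equal(self.signals, other.signals)
            and np.array_equal(self.labels, other.labels)
            and self.fs == other.fs
            and self.cue_onset_s == other.cue_onset_s
            and self.channel_names == other.channel_names
        )
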