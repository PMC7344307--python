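"""Event-related spectral perturbation (ERSP).

ERSP averages squared short-time spectral magnitudes across trials,
``ERSP(f, t) = (1/N) sum_i G_i(f, t)^2``, on a time-frequency grid
referenced to the cue onset.  The per-trial spectrogram ``G_i`` is a
short-time Fourier transform magnitude with a 0.5-s Hann window and 90%
overlap by default (both configurable).  No baseline normalization is
applied unless requested; the mode is recorded in the output so maps from
different modes are never silently mixed.  Event-related
desynchronization shows up as a power decrease relative to the
contralateral channel or to the pre-cue baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .trials import TrialSet

__all__ = ["ERSPMap", "compute_ersp", "band_topography", "ersp_to_csv"]


@dataclass
class ERSPMap:
    """Trial-averaged time-frequency power for one channel.

    ``power[f, t]`` covers ``freqs`` (Hz) x ``times`` (s relative to cue);
    non-negative everywhere in the absolute mode.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel: str
    n_trials: int
    mode: str = "absolute"


def _stft(fs: float, window_s: float, overlap: float) -> ShortTimeFFT:
    nperseg = int(round(window_s * fs))
    hop = max(1, int(round(nperseg * (1 - overlap))))
    return ShortTimeFFT(hann(nperseg, sym=False), hop=hop, fs=fs, fft_mode="onesided")


def compute_ersp(
    trials: TrialSet,
    channel: int | str,
    f_range: tuple[float, float] = (1.0, 35.0),
    t_range: tuple[float, float] | None = None,
    window_s: float = 0.5,
    overlap: float = 0.9,
    class_label: int | None = None,
    baseline_s: tuple[float, float] | None = None,
) -> ERSPMap:
    """Average squared STFT magnitude over trials for one channel.

    ``t_range`` is in seconds relative to the cue (defaults to the whole
    trial) and must lie within the trial; ``f_range`` must sit below the
    Nyquist frequency.  ``class_label`` restricts the average to one
    class.  With ``baseline_s`` the map is converted to dB relative to the
    mean power in that pre-cue window per frequency (``mode="db"``).
    """
    if trials.n_trials == 0:
        raise ValueError("empty trial set")
    ch = trials.channel_index(channel) if isinstance(channel, str) else int(channel)
    if not 0 <= ch < trials.n_channels:
        raise ValueError(f"channel {ch} out of range")
    if not 0 < f_range[0] < f_range[1] < trials.fs / 2:
        raise ValueError(f"f_range {f_range} must lie within (0, fs/2)")
    lo_t = -trials.cue_onset_s
    hi_t = trials.duration_s - trials.cue_onset_s
    if t_range is None:
        t_range = (lo_t, hi_t)
    if t_range[0] < lo_t - 1e-9 or t_range[1] > hi_t + 1e-9:
        raise ValueError(
            f"t_range {t_range} s outside the trial bounds ({lo_t:.2f}, {hi_t:.2f}) s"
        )
    idx = np.arange(trials.n_trials)
    if class_label is not None:
        idx = trials.class_indices(class_label)
        if len(idx) == 0:
            raise ValueError(f"no trials with label {class_label}")
    sft = _stft(trials.fs, window_s, overlap)
    x = trials.signals[idx, ch, :]
    g = np.abs(sft.stft(x, axis=-1))  # (n_trials, n_freq, n_time)
    power = (g**2).mean(axis=0)
    freqs = sft.f
    times = sft.t(trials.n_samples) - trials.cue_onset_s
    fmask = (freqs >= f_range[0]) & (freqs <= f_range[1])
    tmask = (times >= t_range[0]) & (times <= t_range[1])
    power = power[np.ix_(fmask, tmask)]
    times_sel = times[tmask]
    mode = "absolute"
    if baseline_s is not None:
        bmask = (times >= baseline_s[0]) & (times <= baseline_s[1])
        if not bmask.any():
            raise ValueError(f"baseline window {baseline_s} contains no STFT frames")
        full = (g**2).mean(axis=0)
        base = full[fmask][:, bmask].mean(axis=1, keepdims=True)
        power = 10.0 * np.log10(power / base)
        mode = "db"
    name = trials.channel_names[ch]
    return ERSPMap(
        power=power,
        freqs=freqs[fmask],
        times=times_sel,
        channel=name,
        n_trials=len(idx),
        mode=mode,
    )


def band_topography(
    trials: TrialSet,
    f_band: tuple[float, float] = (8.0, 13.0),
    t_window: tuple[float, float] = (0.0, 4.0),
    channels=None,
    class_label: int | None = None,
    window_s: float = 0.5,
    overlap: float = 0.9,
) -> np.ndarray:
    """Band- and window-averaged ERSP, one value per channel.

    The classic topography input: mean alpha-band power over the imagery
    period.  Returns an array aligned with ``channels`` (default: all).
    """
    if channels is None:
        channels = range(trials.n_channels)
    out = []
    for ch in channels:
        m = compute_ersp(
            trials,
            ch,
            f_range=f_band,
            t_range=t_window,
            window_s=window_s,
            overlap=overlap,
            class_label=class_label,
        )
        out.append(m.power.mean())
    return np.array(out)


def ersp_to_csv(ersp: ERSPMap, path) -> None:
    """2-D CSV power grid plus a JSON sidecar with axes and metadata."""
    path = str(path)
    np.savetxt(path, ersp.power, delimiter=",")
    sidecar = path + ".json"
    with open(sidecar, "w") as f:
        json.dump(
            {
                "freqs_hz": ersp.freqs.tolist(),
                "times_s": ersp.times.tolist(),
                "channel": ersp.channel,
                "n_trials": ersp.n_trials,
                "mode": ersp.mode,
            },
            f,
            indent=2,
        )
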