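"""Synthetic two-class motor-imagery EEG with controllable ERD.

Motor imagery attenuates the sensorimotor rhythm (event-related
desynchronization, ERD) over the hemisphere contralateral to the imagined
limb.  The generator emulates exactly that structure and nothing more: each
channel carries a band-limited sinusoidal rhythm over i.i.d. Gaussian
broadband noise, and on class-specific channels the rhythm amplitude is
multiplicatively attenuated during configurable sub-windows of the imagery
period.  The rhythm is a single sinusoid with per-trial random phase and
per-trial frequency jitter inside the band, which keeps band-power
expectations closed-form: outside ERD windows the per-channel variance is
``noise_sd**2 + rhythm_amplitude**2 / 2``.

Attenuation windows are gated with 100-ms raised-cosine ramps so that no
step discontinuity leaks broadband energy into the band-pass filters
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trials import TrialSet

__all__ = [
    "ErdSpec",
    "SynthConfig",
    "early_erd_config",
    "generate_mi_trialset",
    "generate_null_trialset",
]

#: length of the raised-cosine ramp at each attenuation-window edge, seconds
RAMP_S = 0.1


@dataclass(frozen=True)
class ErdSpec:
    """Where, when and how strongly one class desynchronizes.

    Attributes
    ----------
    class_label : int
        Class (1 or 2) whose trials show this ERD.
    channels : tuple of int
        Channel indices carrying the attenuation.
    band_hz : (float, float)
        Frequency range of the attenuated rhythm.
    windows_s : tuple of (float, float)
        Intervals relative to cue onset during which attenuation is active.
    depth : float
        Fraction in [0, 1) by which the rhythm amplitude is reduced inside
        the active windows (0 = no ERD, 0.8 = amplitude drops to 20%).
    """

    class_label: int
    channels: tuple[int, ...]
    band_hz: tuple[float, float] = (8.0, 12.0)
    windows_s: tuple[tuple[float, float], ...] = ((0.0, 4.0),)
    depth: float = 0.8

    def validate(self, cfg: "SynthConfig") -> None:
        if self.class_label not in (1, 2):
            raise ValueError(f"ErdSpec.class_label must be 1 or 2; got {self.class_label}")
        if not 0 <= self.depth < 1:
            raise ValueError(f"ErdSpec.depth must be in [0, 1); got {self.depth}")
        lo, hi = self.band_hz
        if not 0 < lo < hi < cfg.fs / 2:
            raise ValueError(f"ErdSpec.band_hz={self.band_hz} must lie within (0, fs/2)")
        for ch in self.channels:
            if not 0 <= ch < cfg.n_channels:
                raise ValueError(f"ErdSpec channel {ch} out of range for {cfg.n_channels} channels")
        imagery_end = cfg.trial_length_s - cfg.cue_onset_s
        for a, b in self.windows_s:
            if not (0 <= a < b <= imagery_end):
                raise ValueError(
                    f"ERD window ({a}, {b}) s must lie within the imagery period "
                    f"[0, {imagery_end}] s after cue onset"
                )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror a calibration run of a two-class competition-style
    recording: 100 trials per class, 100 Hz sampling, 8-s trials with the
    cue at 2 s, a 10-µV alpha rhythm over 2-µV noise, and opposite-channel
    ERD of depth 0.8 for the two classes throughout the imagery period.
    """

    n_trials_per_class: int = 100
    n_channels: int = 8
    fs: float = 100.0
    trial_length_s: float = 8.0
    cue_onset_s: float = 2.0
    rhythm_amplitude: float = 10.0
    noise_sd: float = 2.0
    erd_specs: tuple[ErdSpec, ...] = (
        ErdSpec(class_label=1, channels=(2,)),
        ErdSpec(class_label=2, channels=(5,)),
    )
    seed: int = 0
    mixing: np.ndarray | None = field(default=None, compare=False)

    def validate(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not 0 <= self.cue_onset_s < self.trial_length_s:
            raise ValueError("cue_onset_s must lie inside the trial")
        max_band = max((s.band_hz[1] for s in self.erd_specs), default=0.0)
        if self.fs <= 2 * max_band:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest rhythm frequency ({max_band} Hz)"
            )
        if self.noise_sd < 0 or self.rhythm_amplitude < 0:
            raise ValueError("noise_sd and rhythm_amplitude must be non-negative")
        for spec in self.erd_specs:
            spec.validate(self)
        if self.mixing is not None:
            m = np.asarray(self.mixing)
            if m.shape != (self.n_channels, self.n_channels):
                raise ValueError(
                    f"mixing must be ({self.n_channels}, {self.n_channels}); got {m.shape}"
                )


def _gate(t_rel_cue: np.ndarray, windows, depth: float, ramp_s: float = RAMP_S) -> np.ndarray:
    """Multiplicative amplitude gate: 1 outside windows, 1-depth inside.

    Raised-cosine ramps of ``ramp_s`` seconds connect the two levels at
    each window edge (ramps lie inside the window).
    """
    g = np.ones_like(t_rel_cue)
    for a, b in windows:
        ramp = min(ramp_s, (b - a) / 2)
        down = (t_rel_cue >= a) & (t_rel_cue < a + ramp)
        flat = (t_rel_cue >= a + ramp) & (t_rel_cue < b - ramp)
        up = (t_rel_cue >= b - ramp) & (t_rel_cue < b)
        if ramp > 0:
            frac_d = (t_rel_cue[down] - a) / ramp
            g[down] = np.minimum(g[down], 1 - depth * 0.5 * (1 - np.cos(np.pi * frac_d)))
            frac_u = (b - t_rel_cue[up]) / ramp
            g[up] = np.minimum(g[up], 1 - depth * 0.5 * (1 - np.cos(np.pi * frac_u)))
        g[flat] = np.minimum(g[flat], 1 - depth)
    return g


def _band_for_channel(cfg: SynthConfig, channel: int) -> tuple[float, float]:
    # channel carries the band of the first ErdSpec naming it, else the
    # first spec's band (all channels share a rhythm band by default)
    for spec in cfg.erd_specs:
        if channel in spec.channels:
            return spec.band_hz
    if cfg.erd_specs:
        return cfg.erd_specs[0].band_hz
    return (8.0, 12.0)


def early_erd_config(seed: int = 0, n_trials_per_class: int = 100) -> SynthConfig:
    """Study conditions with ERD confined to the early imagery period.

    ERD of depth 0.8 on two contralateral channels per class, active only
    during 0-1.5 s after the cue — entirely inside the span of the first
    three 2-s analysis windows (with the default 0.5-s shift, window 4
    starts at 1.5 s and sees none of it).  Two spatial sources per class
    give the selectors two genuinely informative early feature pairs, the
    regime where the early imagery period should dominate the selection.
    """
    burst = ((0.0, 1.5),)
    return SynthConfig(
        n_trials_per_class=n_trials_per_class,
        erd_specs=(
            ErdSpec(class_label=1, channels=(2, 3), windows_s=burst),
            ErdSpec(class_label=2, channels=(5, 6), windows_s=burst),
        ),
        seed=seed,
    )


def generate_mi_trialset(config: SynthConfig) -> TrialSet:
    """Simulate a balanced two-class motor-imagery trial set.

    Every trial is broadband Gaussian noise plus, on each channel, a
    sinusoid with random phase and frequency drawn uniformly inside the
    channel's rhythm band.  On the ERD channels of the trial's class the
    sinusoid amplitude is multiplied by ``1 - depth`` during the active
    windows (cosine-ramped).  Bitwise deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_per = config.n_trials_per_class
    n_trials = 2 * n_per
    n_samp = int(round(config.trial_length_s * config.fs))
    t = np.arange(n_samp) / config.fs
    t_rel = t - config.cue_onset_s
    labels = np.repeat([1, 2], n_per)

    # per-class gate per channel, precomputed
    gates: dict[tuple[int, int], np.ndarray] = {}
    for spec in config.erd_specs:
        for ch in spec.channels:
            key = (spec.class_label, ch)
            g = gates.get(key, np.ones(n_samp))
            gates[key] = g * _gate(t_rel, spec.windows_s, spec.depth)

    signals = np.empty((n_trials, config.n_channels, n_samp))
    for i in range(n_trials):
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_channels, n_samp))
        if config.mixing is not None:
            noise = np.asarray(config.mixing) @ noise
        for ch in range(config.n_channels):
            lo, hi = _band_for_channel(config, ch)
            freq = rng.uniform(lo, hi)
            phase = rng.uniform(0.0, 2 * np.pi)
            rhythm = config.rhythm_amplitude * np.sin(2 * np.pi * freq * t + phase)
            gate = gates.get((labels[i], ch))
            if gate is not None:
                rhythm = rhythm * gate
            noise[ch] += rhythm
        signals[i] = noise

    return TrialSet(
        signals=signals,
        labels=labels,
        fs=config.fs,
        cue_onset_s=config.cue_onset_s,
    )


def generate_null_trialset(config: SynthConfig) -> TrialSet:
    """Same signal model, but labels randomly permuted.

    The permutation destroys every label-signal association while keeping
    the class counts (measure-preserving), so any downstream classifier
    should perform at chance.  Reproducible given ``config.seed``.
    """
    ts = generate_mi_trialset(config)
    perm_rng = np.random.default_rng([config.seed, 1])
    ts.labels = ts.labels[perm_rng.permutation(ts.n_trials)]
    return ts
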