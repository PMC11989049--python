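"""Synthetic single-lead ECG generator.

Each record is a quasi-periodic train of PQRST-like beats: five Gaussian
bumps per beat, beat onsets placed at cumulative RR intervals drawn from a
floored normal distribution, with optional premature ("ectopic") beats,
sinusoidal baseline wander, and additive white noise.

The three class presets encode how the pathologies show up in rhythm and
amplitude rather than in beat morphology:

* ``NSR`` — regular rhythm (RR 0.78 +/- 0.03 s), unit amplitude;
* ``ARR`` — irregular rhythm (RR 0.80 +/- 0.12 s) with a 15% chance per
  beat of a premature ectopic beat (RR 0.45 +/- 0.05 s, widened and
  slightly taller R wave), and a larger global amplitude (scale 1.5);
* ``CHF`` — fast, metronomic rhythm (RR 0.60 +/- 0.01 s), globally
  attenuated amplitude (scale 0.6) and pronounced low-frequency baseline
  wander (0.1 a.u. at 0.3 Hz).

This is a phenomenological stand-in for real recordings, not a
physiologically validated dynamical model: it reproduces the rhythm
regularity and amplitude structure the downstream feature extractor keys
on, nothing more. Two modeling notes. First, the per-class amplitude
scales emulate the class-level calibration and morphology differences of
composite public ECG collections, where each diagnostic class originates
from a different source database; rhythm irregularity alone lands in the
low-frequency DCT band as zero-mean, class-symmetric coefficients, which
a Euclidean nearest-neighbor rule cannot use as a location cue. Second,
baseline wander is rendered with a fixed phase relative to record start
(a class-characteristic template) for the same reason; per-record random
phase is available via ``wander_random_phase``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigError
from .signal_io import DEFAULT_SAMPLING_RATE_HZ, ECGRecord, SignalDataset, normalize_label

#: Hard floor on any realized RR interval (s); prevents beat pile-up when a
#: draw from the RR distribution comes out pathologically short.
RR_FLOOR_S = 0.25


@dataclass(frozen=True)
class GaussianComponent:
    """One wave of the beat template: a Gaussian bump a*exp(-(t-c)^2/(2w^2))."""

    center_s: float
    amplitude: float
    width_s: float

    def __post_init__(self) -> None:
        if not self.width_s > 0:
            raise ConfigError("component width must be positive")


@dataclass(frozen=True)
class BeatTemplate:
    """PQRST beat morphology as five Gaussian components.

    The default is a qualitatively ECG-shaped beat with the R wave dominant;
    all values are configurable.
    """

    p: GaussianComponent = GaussianComponent(-0.20, 0.15, 0.05)
    q: GaussianComponent = GaussianComponent(-0.03, -0.10, 0.015)
    r: GaussianComponent = GaussianComponent(0.0, 1.0, 0.02)
    s: GaussianComponent = GaussianComponent(0.03, -0.15, 0.015)
    t: GaussianComponent = GaussianComponent(0.25, 0.30, 0.08)

    def __post_init__(self) -> None:
        amps = [abs(c.amplitude) for c in self.components]
        if abs(self.r.amplitude) < max(amps):
            raise ConfigError("R must be the largest-magnitude component")

    @property
    def components(self) -> tuple[GaussianComponent, ...]:
        return (self.p, self.q, self.r, self.s, self.t)

    @property
    def support_s(self) -> float:
        """Half-width of the window outside which the beat is negligible."""
        return max(abs(c.center_s) + 5.0 * c.width_s for c in self.components)


def render_beat(template: BeatTemplate, t: Sequence[float]) -> np.ndarray:
    """Evaluate the beat template at time offsets `t` (s, beat onset at 0)."""
    t = np.asarray(t, dtype=np.float64)
    if not np.all(np.isfinite(t)):
        raise ValueError("time offsets must be finite")
    out = np.zeros_like(t)
    for c in template.components:
        out += c.amplitude * np.exp(-((t - c.center_s) ** 2) / (2.0 * c.width_s**2))
    return out


@dataclass(frozen=True)
class ClassSimConfig:
    """Per-class simulation parameters.

    Ectopic beats are premature beats: their RR interval is drawn from the
    (shorter) ectopic distribution and their R wave is widened by
    ``ectopic_r_widening`` and scaled by ``ectopic_r_gain``.
    """

    label: str
    rr_mean_s: float
    rr_sd_s: float
    ectopic_prob: float = 0.0
    ectopic_rr_mean_s: float = 0.45
    ectopic_rr_sd_s: float = 0.05
    amplitude_scale: float = 1.0
    wander_amplitude: float = 0.0
    wander_freq_hz: float = 0.3
    wander_random_phase: bool = False
    noise_sd: float = 0.02
    template: BeatTemplate = field(default_factory=BeatTemplate)
    ectopic_r_widening: float = 2.5
    ectopic_r_gain: float = 1.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", normalize_label(self.label))
        if not self.rr_mean_s > 0 or not self.ectopic_rr_mean_s > 0:
            raise ConfigError("mean RR intervals must be positive")
        if self.rr_sd_s < 0 or self.ectopic_rr_sd_s < 0:
            raise ConfigError("RR standard deviations must be non-negative")
        if not 0.0 <= self.ectopic_prob <= 1.0:
            raise ConfigError("ectopic_prob must lie in [0, 1]")
        if self.noise_sd < 0 or self.wander_amplitude < 0:
            raise ConfigError("noise_sd and wander_amplitude must be non-negative")
        if not self.amplitude_scale > 0:
            raise ConfigError("amplitude_scale must be positive")

    def ectopic_template(self) -> BeatTemplate:
        r = self.template.r
        return replace(
            self.template,
            r=GaussianComponent(
                r.center_s,
                r.amplitude * self.ectopic_r_gain,
                r.width_s * self.ectopic_r_widening,
            ),
        )


def default_class_configs() -> dict[str, ClassSimConfig]:
    """The shipped per-class presets (see module docstring)."""
    return {
        "NSR": ClassSimConfig(label="NSR", rr_mean_s=0.78, rr_sd_s=0.03),
        "ARR": ClassSimConfig(
            label="ARR",
            rr_mean_s=0.80,
            rr_sd_s=0.12,
            ectopic_prob=0.15,
            ectopic_rr_mean_s=0.45,
            ectopic_rr_sd_s=0.05,
            amplitude_scale=1.5,
        ),
        "CHF": ClassSimConfig(
            label="CHF",
            rr_mean_s=0.60,
            rr_sd_s=0.01,
            amplitude_scale=0.6,
            wander_amplitude=0.1,
            wander_freq_hz=0.3,
        ),
    }


def generate_record(
    cfg: ClassSimConfig,
    n_samples: int,
    fs: float = DEFAULT_SAMPLING_RATE_HZ,
    seed: int = 0,
    record_id: str | None = None,
) -> ECGRecord:
    """Simulate one ECG record.

    Beats are placed at cumulative RR intervals; each interval is drawn from
    the normal (or, with probability ``ectopic_prob``, the ectopic) RR
    distribution and floored at 0.25 s. Identical ``(cfg, n_samples, fs,
    seed)`` give a bit-identical record.
    """
    if not isinstance(cfg, ClassSimConfig):
        raise ConfigError("cfg must be a ClassSimConfig")
    n_samples = int(n_samples)
    if n_samples < fs:
        raise ConfigError("n_samples must cover at least one second of signal")

    rng = np.random.default_rng(seed)
    duration = n_samples / fs
    t_axis = np.arange(n_samples, dtype=np.float64) / fs
    x = np.zeros(n_samples, dtype=np.float64)

    support = max(cfg.template.support_s, cfg.ectopic_template().support_s)
    normal_tpl, ectopic_tpl = cfg.template, cfg.ectopic_template()

    t = 0.0
    while True:
        is_ectopic = rng.random() < cfg.ectopic_prob
        if is_ectopic:
            rr = rng.normal(cfg.ectopic_rr_mean_s, cfg.ectopic_rr_sd_s)
        else:
            rr = rng.normal(cfg.rr_mean_s, cfg.rr_sd_s)
        t += max(rr, RR_FLOOR_S)
        if t > duration + support:
            break
        lo = max(0, int(math.floor((t - support) * fs)))
        hi = min(n_samples, int(math.ceil((t + support) * fs)) + 1)
        if hi > lo:
            tpl = ectopic_tpl if is_ectopic else normal_tpl
            x[lo:hi] += render_beat(tpl, t_axis[lo:hi] - t)

    x *= cfg.amplitude_scale
    if cfg.wander_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * math.pi) if cfg.wander_random_phase else 0.0
        x += cfg.wander_amplitude * np.sin(
            2.0 * math.pi * cfg.wander_freq_hz * t_axis + phase
        )
    if cfg.noise_sd > 0:
        x += rng.normal(0.0, cfg.noise_sd, n_samples)

    rid = record_id if record_id is not None else f"{cfg.label}-seed{seed}"
    return ECGRecord(rid, x, cfg.label, fs)


def generate_dataset(
    per_class_counts: Mapping[str, int],
    n_samples: int,
    fs: float = DEFAULT_SAMPLING_RATE_HZ,
    seed: int = 1,
    configs: Mapping[str, ClassSimConfig] | None = None,
) -> SignalDataset:
    """Simulate a labeled dataset.

    Classes are generated in the order of ``per_class_counts``; record *i*
    (global, 0-based) uses the derived seed ``seed + i``, so any record can
    be regenerated in isolation.
    """
    counts = {normalize_label(k): int(v) for k, v in per_class_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ConfigError("per-class counts must be non-negative")
    if sum(counts.values()) == 0:
        raise ConfigError("at least one record must be requested")
    cfgs = dict(default_class_configs())
    if configs:
        cfgs.update({normalize_label(k): v for k, v in configs.items()})

    records: list[ECGRecord] = []
    index = 0
    for label, count in counts.items():
        cfg = cfgs[label]
        for j in range(count):
            records.append(
                generate_record(
                    cfg,
                    n_samples,
                    fs,
                    seed=seed + index,
                    record_id=f"{label}-{j:03d}",
                )
            )
            index += 1
    return SignalDataset(records)
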