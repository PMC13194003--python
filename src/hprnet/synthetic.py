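"""Synthetic ECG heartbeat generator.

Each beat is a sum of Gaussian bumps on [0, 1) mimicking the P-QRS-T
morphology of a single cardiac cycle, plus sinusoidal baseline wander and
additive white noise.  Class variants follow the textbook morphology of the
AAMI beat families: a normal beat has all five waves; a supraventricular
ectopic beat lacks the P wave and has a narrow QRS; a ventricular ectopic
beat has a wide, high-amplitude QRS with an inverted T wave; a fusion beat
is the average of the normal and ventricular templates.  This is plumbing
for testing the classification pipeline, not a physiologically validated
simulator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import BeatDataset

# (center_fraction, width_fraction, amplitude) per Gaussian bump.
# Amplitudes are normalized so the R wave of a normal beat is 1.0; the R
# bump is centered at fraction 0.5 so its peak falls on sample length//2.
_N_TEMPLATE = [
    (0.30, 0.035, 0.15),   # P
    (0.455, 0.015, -0.12),  # Q
    (0.50, 0.020, 1.00),   # R
    (0.545, 0.015, -0.20),  # S
    (0.70, 0.060, 0.35),   # T
]
_S_TEMPLATE = [             # no P wave, narrow QRS, earlier T
    (0.46, 0.012, -0.10),   # Q
    (0.50, 0.014, 1.00),    # R
    (0.54, 0.012, -0.18),   # S
    (0.66, 0.045, 0.30),    # T
]
_V_TEMPLATE = [             # wide high-amplitude QRS, inverted T, no P
    (0.43, 0.030, -0.15),   # Q
    (0.50, 0.060, 1.15),    # R (3x the width of the N template's R)
    (0.59, 0.035, -0.30),   # S
    (0.78, 0.070, -0.40),   # T
]
_F_TEMPLATE = (             # fusion: mean of N and V morphologies
    [(c, w, a / 2.0) for c, w, a in _N_TEMPLATE]
    + [(c, w, a / 2.0) for c, w, a in _V_TEMPLATE]
)

DEFAULT_WAVE_PARAMS = {
    "N": _N_TEMPLATE,
    "S": _S_TEMPLATE,
    "V": _V_TEMPLATE,
    "F": _F_TEMPLATE,
}


@dataclass
class SynthConfig:
    """Configuration of the synthetic beat generator.

    noise_sd is expressed as a fraction of the R-wave amplitude (1.0);
    wander_amp / wander_freq parameterize a baseline-wander sinusoid with a
    random phase per beat (wander_freq in Hz at sampling rate ``fs``).
    """

    length: int = 128
    fs: float = 360.0
    classes: tuple = ("N", "S", "V", "F")
    n_per_class: int = 250
    wave_params: dict = field(default_factory=lambda: dict(DEFAULT_WAVE_PARAMS))
    noise_sd: float = 0.05
    wander_amp: float = 0.05
    wander_freq: float = 0.33
    seed: int = 0

    def __post_init__(self):
        if self.length < 16:
            raise ValueError("length must be >= 16")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cls in self.classes:
            if cls not in self.wave_params:
                raise ValueError(f"no wave_params for class {cls!r}")
            for _, w, _ in self.wave_params[cls]:
                if w <= 0:
                    raise ValueError("all width_fractions must be > 0")


def class_template(class_name: str, cfg: SynthConfig) -> np.ndarray:
    """Noiseless template waveform for one class (sum of Gaussian bumps)."""
    if class_name not in cfg.classes:
        raise ValueError(
            f"unknown class {class_name!r}; valid classes: {list(cfg.classes)}"
        )
    t = np.arange(cfg.length, dtype=np.float64) / cfg.length
    wave = np.zeros(cfg.length)
    for center, width, amp in cfg.wave_params[class_name]:
        wave += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return wave


def synth_beat(class_name: str, cfg: SynthConfig,
               rng: np.random.Generator) -> np.ndarray:
    """One beat: class template + baseline wander + white noise."""
    wave = class_template(class_name, cfg)
    if cfg.wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        tsec = np.arange(cfg.length) / cfg.fs
        wave = wave + cfg.wander_amp * np.sin(
            2 * np.pi * cfg.wander_freq * tsec + phase)
    if cfg.noise_sd > 0:
        wave = wave + rng.normal(0.0, cfg.noise_sd, size=cfg.length)
    return wave


def synth_dataset(cfg: SynthConfig) -> BeatDataset:
    """Generate ``n_per_class`` beats for every class, in class order."""
    rng = np.random.default_rng(cfg.seed)
    beats, labels, srcs = [], [], []
    for ci, cls in enumerate(cfg.classes):
        for _ in range(cfg.n_per_class):
            beats.append(synth_beat(cls, cfg, rng))
            labels.append(ci)
            srcs.append(f"synth/{cls}")
    ds = BeatDataset(
        np.asarray(beats), np.asarray(labels), list(cfg.classes),
        np.asarray(srcs, dtype=object), fs=cfg.fs, lead="synthetic",
    )
    ds.meta["synth_config"] = {
        "length": cfg.length, "fs": cfg.fs, "classes": list(cfg.classes),
        "n_per_class": cfg.n_per_class, "noise_sd": cfg.noise_sd,
        "wander_amp": cfg.wander_amp, "wander_freq": cfg.wander_freq,
        "seed": cfg.seed,
    }
    return ds


def nearest_template_predict(beats: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Max-correlation nearest-template classifier (testing oracle)."""
    templates = np.stack([class_template(c, cfg) for c in cfg.classes])
    b = beats - beats.mean(axis=1, keepdims=True)
    t = templates - templates.mean(axis=1, keepdims=True)
    b = b / np.maximum(np.linalg.norm(b, axis=1, keepdims=True), 1e-12)
    t = t / np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-12)
    return np.argmax(b @ t.T, axis=1)
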