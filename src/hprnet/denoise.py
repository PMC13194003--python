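"""Wavelet soft-threshold denoising (sym8, 5 levels, universal threshold).

The threshold is the standard wavelet-shrinkage default: the universal
threshold sigma * sqrt(2 ln N) with the noise scale sigma estimated from
the finest-level detail coefficients as median(|d|)/0.6745, applied with
soft shrinkage to every detail level.  Approximation coefficients are left
untouched.  Intended to run per record, before beat segmentation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt


@dataclass
class DenoiseConfig:
    wavelet_name: str = "sym8"
    levels: int = 5
    threshold_rule: str = "universal"
    mode: str = "soft"

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.threshold_rule != "universal":
            raise ValueError("only the universal threshold rule is supported")
        if self.mode != "soft":
            raise ValueError("only soft thresholding is supported")


def wavelet_denoise(x, cfg: DenoiseConfig | None = None) -> np.ndarray:
    """Denoise a 1-D signal; output has exactly the input length."""
    cfg = cfg or DenoiseConfig()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("input must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    wavelet = pywt.Wavelet(cfg.wavelet_name)
    max_lev = int(np.log2(len(x))) if len(x) >= 2 else 0
    if 2 ** cfg.levels > len(x):
        raise ValueError(
            f"signal of length {len(x)} supports at most {max_lev} "
            f"decomposition levels, got {cfg.levels}")
    with warnings.catch_warnings():
        # deliberately allow depths beyond pywt's conservative recommendation
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, level=cfg.levels, mode="symmetric")
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest)) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(len(x)))
    if thr > 0:
        den = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft")
                             for c in coeffs[1:]]
    else:  # zero noise estimate: soft threshold at 0 is the identity
        den = coeffs
    y = pywt.waverec(den, wavelet, mode="symmetric")
    return y[: len(x)] if len(y) >= len(x) else np.pad(y, (0, len(x) - len(y)))
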