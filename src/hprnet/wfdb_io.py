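"""Minimal WFDB (PhysioNet waveform database) reader and writer.

Supports the subset of the format family needed for beat-level arrhythmia
work: single-segment headers (.hea), signal files (.dat) in formats 16
(little-endian int16) and 212 (packed 12-bit pairs, the MIT-BIH format),
and MIT-format beat annotations (.atr).  The writer emits format-16
records and is used to build small test fixtures.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

# MIT annotation type codes -> annotation symbol (ecgcodes subset).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}

# pseudo-annotation codes with special encodings
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalInfo:
    filename: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


@dataclass
class Record:
    name: str
    fs: float
    n_samples: int
    signals: list[SignalInfo]
    data: np.ndarray  # (n_samples, n_sig) physical units


def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    sigs = []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        filename = parts[0]
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(parts) > 2:
            g = parts[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        description = " ".join(parts[8:]) if len(parts) > 8 else f"sig{len(sigs)}"
        sigs.append(SignalInfo(filename, fmt, gain, baseline, units, description))
    return name, n_sig, fs, n_samp, sigs


def _read_dat(path: Path, fmt: int, n_sig: int, n_samp: int) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2")
        adc = adc[: n_samp * n_sig] if n_samp else adc
        return adc.reshape(-1, n_sig)
    if fmt == 212:
        if n_sig != 2:
            raise ValueError("format 212 is only supported for 2-signal records")
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0[s0 > 2047] -= 4096
        s1[s1 > 2047] -= 4096
        adc = np.column_stack([s0, s1])
        return adc[:n_samp] if n_samp else adc
    raise ValueError(f"unsupported WFDB signal format {fmt}")


def read_record(path, lead: str | None = None):
    """Read a WFDB record; return (signal, fs) for one lead plus annotations.

    ``path`` is the record path without extension.  Returns
    ``(signal, fs, annotations)`` where ``signal`` is a 1-D float array in
    physical units and ``annotations`` a list of (sample_index, symbol).
    When ``lead`` is None the first signal is used.
    """
    path = Path(path)
    name, n_sig, fs, n_samp, sigs = _parse_header(path.with_suffix(".hea"))
    adc = _read_dat(path.parent / sigs[0].filename, sigs[0].fmt, n_sig, n_samp)
    leads = [s.description for s in sigs]
    if lead is None:
        col = 0
    else:
        if lead not in leads:
            raise ValueError(f"lead {lead!r} not found; available leads: {leads}")
        col = leads.index(lead)
    info = sigs[col]
    signal = (adc[:, col].astype(np.float64) - info.baseline) / info.gain
    atr = path.with_suffix(".atr")
    annotations = read_annotations(atr, len(signal)) if atr.exists() else []
    return signal, fs, annotations


def read_annotations(path, n_samples: int | None = None):
    """Parse an MIT-format annotation file into (sample_index, symbol) pairs."""
    raw = Path(path).read_bytes()
    out = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        lo, hi = raw[i], raw[i + 1]
        i += 2
        code = hi >> 2
        delta = ((hi & 0x03) << 8) | lo
        if code == 0 and delta == 0:  # EOF
            break
        if code == _SKIP:
            # 4-byte interval in PDP-11 order: high word first, each word
            # little-endian
            jump = int.from_bytes(
                bytes([raw[i + 1], raw[i], raw[i + 3], raw[i + 2]]),
                "big", signed=True)
            t += jump
            i += 4
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += delta + (delta & 1)
            continue
        t += delta
        sym = _CODE_TO_SYMBOL.get(code, "?")
        if n_samples is None or 0 <= t < n_samples:
            out.append((t, sym))
    return out


def write_record(path, signals: np.ndarray, fs: float, leads: list[str],
                 gain: float = 200.0, units: str = "mV") -> None:
    """Write a format-16 WFDB record (used for fixtures and exports)."""
    path = Path(path)
    signals = np.atleast_2d(np.asarray(signals, dtype=np.float64))
    if signals.shape[0] < signals.shape[1]:
        signals = signals.T  # accept (n_sig, n) or (n, n_sig)
    n_samp, n_sig = signals.shape
    if len(leads) != n_sig:
        raise ValueError("one lead name per signal required")
    adc = np.clip(np.round(signals * gain), -32768, 32767).astype("<i2")
    lines = [f"{path.stem} {n_sig} {fs:g} {n_samp}"]
    for lead in leads:
        lines.append(f"{path.stem}.dat 16 {gain:g}/{units} 16 0 0 0 0 {lead}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    path.with_suffix(".dat").write_bytes(adc.reshape(-1).tobytes())


def write_annotations(path, annotations) -> None:
    """Write (sample_index, symbol) pairs as an MIT-format .atr file."""
    buf = bytearray()
    t_prev = 0
    for t, sym in sorted(annotations):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"no MIT annotation code for symbol {sym!r}")
        delta = t - t_prev
        if delta > 1023:  # emit a SKIP word for long gaps
            buf += bytes([0, _SKIP << 2])
            jump = delta - 1023
            high, low = (jump >> 16) & 0xFFFF, jump & 0xFFFF
            buf += bytes([high & 0xFF, high >> 8, low & 0xFF, low >> 8])
            delta = 1023
        buf += bytes([delta & 0xFF, (code << 2) | ((delta >> 8) & 0x03)])
        t_prev = t
    buf += bytes([0, 0])  # EOF
    Path(path).write_bytes(bytes(buf))
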