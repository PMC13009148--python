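"""Minimal EDF (European Data Format) writer plus an MNE-backed reader.

Writing covers exactly what the cohort exporter needs: continuous
multichannel signals in microvolts, 16-bit samples, one-second data records.
Reading goes through :func:`mne.io.read_raw_edf`, so any standards-compliant
EDF produced elsewhere is accepted too.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from eegmark.channels import normalize_label

__all__ = ["write_edf", "read_edf"]


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, signal: np.ndarray, sampling_rate: float,
              channel_names: list[str] | tuple[str, ...],
              patient_id: str = "X") -> None:
    """Write channels x samples (microvolts) to an EDF file.

    Uses one-second data records; a trailing partial second is truncated.
    Sampling rate must be a whole number of samples per second.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2 or signal.shape[0] != len(channel_names):
        raise ValueError("signal must be channels x samples matching channel_names")
    fs = sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_channels, n_samples = signal.shape
    n_records = n_samples // fs
    if n_records < 1:
        raise ValueError("signal shorter than one 1-s data record")
    signal = signal[:, : n_records * fs]

    dig_min, dig_max = -32768, 32767
    phys_max = np.maximum(np.abs(signal).max(axis=1), 1e-6)
    # round up to keep header fields short and quantization symmetric
    phys_max = np.array([float(f"{v:.6g}") * 1.000001 + 1e-9 for v in phys_max])
    phys_min = -phys_max

    header = b"".join([
        _field(0, 8),
        _field(patient_id, 80),
        _field("eegmark synthetic recording", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(256 * (n_channels + 1), 8),
        _field("", 44),
        _field(n_records, 8),
        _field(1, 8),
        _field(n_channels, 4),
    ])

    def per_signal(values, width):
        return b"".join(_field(v, width) for v in values)

    def fmt8(x: float) -> str:
        s = f"{x:.6g}"
        return s if len(s) <= 8 else f"{x:.2e}"

    header += per_signal([str(c)[:16] for c in channel_names], 16)
    header += per_signal(["" for _ in channel_names], 80)
    header += per_signal(["uV" for _ in channel_names], 8)
    header += per_signal([fmt8(v) for v in phys_min], 8)
    header += per_signal([fmt8(v) for v in phys_max], 8)
    header += per_signal([dig_min for _ in channel_names], 8)
    header += per_signal([dig_max for _ in channel_names], 8)
    header += per_signal(["" for _ in channel_names], 80)
    header += per_signal([fs for _ in channel_names], 8)
    header += per_signal(["" for _ in channel_names], 32)

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((signal - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (channels x samples in microvolts, rate, labels).

    Labels are normalized to bare 10-20 names where they match the common
    vendor patterns ('EEG F7-REF' -> 'F7').
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # Volts -> microvolts
    labels = [normalize_label(name) for name in raw.ch_names]
    return data, float(raw.info["sfreq"]), labels


def write_cohort_edf(cohort, out_dir: str | Path) -> list[Path]:
    """Write one EDF per subject; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in cohort:
        p = out_dir / f"{rec.subject_id}.edf"
        write_edf(p, rec.signal, rec.sampling_rate, rec.channel_names,
                  patient_id=rec.subject_id)
        paths.append(p)
    return paths
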