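"""Synthetic multi-site resting-state EEG cohorts.

The clinical recordings behind the analysis are access-restricted, so this
module generates cohorts with the statistical structure the pipeline assumes:
a 1/f^gamma Gaussian background, an amplitude-modulated alpha-band (8-12 Hz)
oscillation whose amplitude carries the class effects (diagnosis at
frontal/parietal channels, treatment response at frontal channels), ocular
transients with a frontal, laterally asymmetric spatial profile, and
band-limited (>30 Hz) muscle bursts.  Site heterogeneity enters through the
per-site sampling rate, recording duration and group sizes of the six-site
cohort the analysis was designed for.

Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from eegmark.channels import CANONICAL_CHANNELS

__all__ = [
    "SiteProfile",
    "EffectSpec",
    "SubjectRecord",
    "generate_subject",
    "generate_cohort",
    "default_sites",
    "write_cohort_metadata",
    "read_cohort_metadata",
]


@dataclass(frozen=True)
class SiteProfile:
    """Recording conditions and group sizes of one site."""

    site_id: str
    sampling_rate: float          # Hz
    duration: float               # seconds, MDD recordings
    n_hc: int
    n_mdd: int
    responder_fraction: float     # of included MDD patients
    assessment_week: int
    duration_hc: float | None = None  # defaults to `duration`

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be within [0, 1]")
        if self.duration < 2.0:
            raise ValueError("duration must be at least one 2-s segment")
        if self.n_hc < 0 or self.n_mdd < 0:
            raise ValueError("group sizes must be non-negative")

    @property
    def hc_duration(self) -> float:
        return self.duration if self.duration_hc is None else self.duration_hc


@dataclass(frozen=True)
class EffectSpec:
    """Parameters of the planted signal structure.

    Amplitudes are in microvolts.  ``diag_amp_ratio`` multiplies the alpha
    envelope on ``diag_channels`` for MDD subjects; ``resp_amp_ratio``
    multiplies it on ``resp_channels`` for responders.  Ratios of 1 produce a
    null cohort with no class information.
    """

    alpha_freq: float = 10.0                     # Hz, within the 8-12 Hz band
    diag_channels: tuple[str, ...] = ("F7", "F4", "F3", "P3")
    resp_channels: tuple[str, ...] = ("F3", "F7", "F4")
    diag_amp_ratio: float = 1.0
    resp_amp_ratio: float = 1.0
    background_exponent: float = 1.0             # 1/f^gamma power slope
    blink_rate: float = 6.0                      # events / minute
    emg_burst_rate: float = 2.0                  # events / minute
    background_rms: float = 10.0                 # uV per channel
    alpha_amp: float = 10.0                      # uV baseline envelope mean
    blink_amp: float = 60.0                      # uV at the dominant electrode
    emg_amp: float = 15.0                        # uV RMS within a burst
    alpha_coherence_time: float = 2.0            # s, envelope correlation time

    def __post_init__(self) -> None:
        if self.diag_amp_ratio <= 0 or self.resp_amp_ratio <= 0:
            raise ValueError("amplitude ratios must be positive")
        if self.blink_rate < 0 or self.emg_burst_rate < 0:
            raise ValueError("event rates must be non-negative")
        if not 8.0 <= self.alpha_freq <= 12.0:
            raise ValueError("alpha_freq must lie within the 8-12 Hz band")
        unknown = [
            c
            for c in tuple(self.diag_channels) + tuple(self.resp_channels)
            if c not in CANONICAL_CHANNELS
        ]
        if unknown:
            raise ValueError(f"unknown effect channels: {unknown}")


@dataclass
class SubjectRecord:
    """One subject's multichannel signal plus metadata.

    ``responder`` is 'NA' for healthy controls and 'R'/'NR' for patients.
    ``signal`` is channels x samples in microvolts.
    """

    subject_id: str
    site_id: str
    group: str                    # 'HC' | 'MDD'
    responder: str                # 'R' | 'NR' | 'NA'
    assessment_week: int
    signal: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.group not in ("HC", "MDD"):
            raise ValueError(f"group must be 'HC' or 'MDD', got {self.group!r}")
        if self.responder not in ("R", "NR", "NA"):
            raise ValueError(f"responder must be 'R'/'NR'/'NA', got {self.responder!r}")
        if (self.responder == "NA") != (self.group == "HC"):
            raise ValueError("responder must be 'NA' exactly for healthy controls")
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channel_names):
            raise ValueError("signal must be channels x samples matching channel_names")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.sampling_rate


# Lateral asymmetry lets the F7-F8 bipolar surrogate see the ocular events;
# amplitudes decay away from the eyes.
_BLINK_WEIGHTS = {
    "F7": 1.0, "F8": 0.55, "F3": 0.75, "F4": 0.45,
    "C3": 0.25, "C4": 0.2, "P3": 0.12, "P4": 0.1, "O1": 0.05, "O2": 0.05,
}
# Muscle bursts favour lateral frontal (temporalis) electrodes.
_EMG_WEIGHTS = {
    "F7": 1.0, "F8": 1.0, "F3": 0.4, "F4": 0.4,
    "C3": 0.3, "C4": 0.3, "P3": 0.2, "P4": 0.2, "O1": 0.3, "O2": 0.3,
}


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      fs: float, exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent."""
    if rms == 0.0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * rms


def _alpha_envelope(rng: np.random.Generator, n_samples: int, fs: float,
                    coherence_time: float) -> np.ndarray:
    """Positive, slowly varying amplitude envelope with mean 1."""
    sigma = max(coherence_time * fs / 2.0, 1.0)
    raw = rng.standard_normal(n_samples)
    # Gaussian smoothing via FFT (circular; edge effects negligible for long records)
    freqs = np.fft.rfftfreq(n_samples)
    kernel = np.exp(-2.0 * (np.pi * freqs * sigma) ** 2)
    smooth = np.fft.irfft(np.fft.rfft(raw) * kernel, n=n_samples)
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    env = np.abs(1.0 + 0.5 * smooth)
    return env / env.mean()


def _alpha_carrier(rng: np.random.Generator, n_samples: int, fs: float,
                   freq: float, bandwidth: float = 1.0) -> np.ndarray:
    """Unit-RMS narrowband stochastic oscillation centred on ``freq``.

    Band-limited Gaussian noise rather than a fixed-phase sinusoid: real
    alpha rhythm has a drifting phase, and a constant phase would hand the
    classifier a spurious subject-identity cue.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    # Gaussian passband around the centre frequency
    shape = np.exp(-0.5 * ((freqs - freq) / (bandwidth / 2.0)) ** 2)
    x = np.fft.irfft(spec * shape, n=n_samples)
    rms = np.sqrt((x ** 2).mean())
    return x / rms if rms > 0 else x


def _blink_template(rng: np.random.Generator, fs: float) -> np.ndarray:
    """Smooth biphasic ocular pulse, 100-400 ms."""
    width_s = rng.uniform(0.1, 0.4)
    n = max(int(round(width_s * fs)), 4)
    t = np.linspace(0.0, 1.0, n)
    return np.sin(2.0 * np.pi * t) * np.hanning(n)


def _add_events(rng: np.random.Generator, signal: np.ndarray, fs: float,
                rate_per_min: float, weights: dict[str, float],
                channels: tuple[str, ...], make_template, amplitude: float) -> None:
    n_samples = signal.shape[1]
    duration_min = n_samples / fs / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    w = np.array([weights.get(c, 0.0) for c in channels])[:, None]
    for _ in range(n_events):
        template = make_template(rng)
        start = rng.integers(0, max(n_samples - len(template), 1))
        stop = min(start + len(template), n_samples)
        signal[:, start:stop] += amplitude * w * template[None, : stop - start]


def generate_subject(site: SiteProfile, effect: EffectSpec, group: str,
                     responder: str, seed: int,
                     subject_id: str | None = None) -> SubjectRecord:
    """Generate one subject's recording; bit-for-bit reproducible given the seed.

    The signal is the sum of a 1/f^gamma background, an amplitude-modulated
    alpha sinusoid on every channel (envelope mean ``alpha_amp``, multiplied
    by ``diag_amp_ratio`` on ``diag_channels`` for MDD and by
    ``resp_amp_ratio`` on ``resp_channels`` for responders), frontal ocular
    transients and band-limited muscle bursts.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    if group == "HC" and responder != "NA":
        raise ValueError("healthy controls must have responder='NA'")
    if group == "MDD" and responder not in ("R", "NR"):
        raise ValueError("patients must have responder 'R' or 'NR'")

    fs = site.sampling_rate
    duration = site.hc_duration if group == "HC" else site.duration
    n_samples = int(round(duration * fs))
    channels = CANONICAL_CHANNELS
    rng = np.random.default_rng(seed)

    signal = _one_over_f_noise(rng, len(channels), n_samples, fs,
                               effect.background_exponent, effect.background_rms)

    # class-dependent alpha oscillation (amplitude-modulated narrowband noise)
    amp = np.full(len(channels), effect.alpha_amp)
    if group == "MDD":
        for c in effect.diag_channels:
            amp[channels.index(c)] *= effect.diag_amp_ratio
    if responder == "R":
        for c in effect.resp_channels:
            amp[channels.index(c)] *= effect.resp_amp_ratio
    for i in range(len(channels)):
        env = _alpha_envelope(rng, n_samples, fs, effect.alpha_coherence_time)
        carrier = _alpha_carrier(rng, n_samples, fs, effect.alpha_freq)
        # carrier is unit-RMS; scale so `amp` is the envelope-mean amplitude
        signal[i] += amp[i] / np.sqrt(2.0) * env * carrier

    if effect.blink_rate > 0:
        _add_events(rng, signal, fs, effect.blink_rate, _BLINK_WEIGHTS, channels,
                    lambda r: _blink_template(r, fs), effect.blink_amp)

    if effect.emg_burst_rate > 0:
        from scipy.signal import butter, sosfiltfilt

        high = min(100.0, 0.45 * fs)
        sos = butter(4, [30.0, high], btype="bandpass", fs=fs, output="sos")

        def emg_template(r: np.random.Generator) -> np.ndarray:
            width = r.uniform(0.2, 0.5)
            n = max(int(round(width * fs)), 32)
            burst = sosfiltfilt(sos, r.standard_normal(n))
            s = burst.std()
            if s > 0:
                burst = burst / s
            return burst * np.hanning(n)

        _add_events(rng, signal, fs, effect.emg_burst_rate, _EMG_WEIGHTS, channels,
                    emg_template, effect.emg_amp)

    if subject_id is None:
        subject_id = f"{site.site_id}-{group}-{seed}"
    return SubjectRecord(
        subject_id=subject_id,
        site_id=site.site_id,
        group=group,
        responder=responder,
        assessment_week=site.assessment_week,
        signal=signal,
        sampling_rate=fs,
        channel_names=channels,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def generate_cohort(sites: list[SiteProfile], effect: EffectSpec,
                    seed: int) -> list[SubjectRecord]:
    """Generate all subjects of a multi-site cohort.

    Per site, ``round(responder_fraction * n_mdd)`` patients (round half up)
    are responders; the assignment of labels to subjects is a seeded shuffle.
    Subject ids are unique across the cohort.
    """
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate site_id in site list")
    root = np.random.SeedSequence(seed)
    site_seqs = root.spawn(len(sites))
    cohort: list[SubjectRecord] = []
    for site, seq in zip(sites, site_seqs):
        label_rng = np.random.default_rng(seq.spawn(1)[0])
        n_resp = _round_half_up(site.responder_fraction * site.n_mdd)
        responder_labels = ["R"] * n_resp + ["NR"] * (site.n_mdd - n_resp)
        label_rng.shuffle(responder_labels)
        subject_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in seq.spawn(site.n_hc + site.n_mdd)
        ]
        for i in range(site.n_hc):
            cohort.append(generate_subject(
                site, effect, "HC", "NA", subject_seeds[i],
                subject_id=f"{site.site_id}-HC{i:03d}"))
        for j in range(site.n_mdd):
            cohort.append(generate_subject(
                site, effect, "MDD", responder_labels[j],
                subject_seeds[site.n_hc + j],
                subject_id=f"{site.site_id}-MDD{j:03d}"))
    return cohort


def default_sites(duration_scale: float = 1.0) -> list[SiteProfile]:
    """The six-site cohort profile the analysis was designed around.

    Group sizes, responder counts, sampling rates and recording durations
    follow the included-subject columns of the source cohorts (146 HC, 203
    MDD, 103 responders overall).  ``duration_scale`` shrinks recording
    durations for quick runs without touching group structure (floor of one
    2-s segment).
    """
    sites = [
        SiteProfile("LeipzigI", 1000, 906, 32, 6, 2 / 6, 4, duration_hc=900),
        SiteProfile("LeipzigII", 1000, 126, 17, 15, 7 / 15, 6, duration_hc=127),
        SiteProfile("PragueI", 250, 72, 0, 21, 13 / 21, 5),
        SiteProfile("PragueII", 1000, 75, 0, 36, 20 / 36, 5),
        SiteProfile("Ottawa", 512, 184, 43, 14, 6 / 14, 12, duration_hc=185),
        SiteProfile("CANBIND", 512, 562, 54, 111, 55 / 111, 8, duration_hc=555),
    ]
    if duration_scale != 1.0:
        sites = [
            replace(
                s,
                duration=max(2.0, s.duration * duration_scale),
                duration_hc=max(2.0, s.hc_duration * duration_scale),
            )
            for s in sites
        ]
    return sites


_META_FIELDS = ("subject_id", "site_id", "group", "responder", "assessment_week")


def write_cohort_metadata(cohort: list[SubjectRecord], path: str | Path) -> None:
    """Write the cohort metadata table (CSV, one row per subject)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_META_FIELDS)
        for rec in cohort:
            writer.writerow([rec.subject_id, rec.site_id, rec.group,
                             rec.responder, rec.assessment_week])


def read_cohort_metadata(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
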