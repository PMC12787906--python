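"""Synthetic ECG and muscle-artifact noise with exact ground truth.

Stand-ins for the MIT-BIH Arrhythmia Database records (360 Hz, half-hour,
single channel, millivolts) and the NSTD 'ma' muscle-artifact record, so the
whole mix → detect → pair → metrics pipeline is testable without any
database download. No clinical fidelity is claimed: the QRS is a narrow
Gaussian bump (optionally followed by a smaller opposite-sign T wave) —
just enough morphology for a bandpass/derivative/square/average feature
chain to behave realistically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .wfdb_io import BeatAnnotations, EcgRecord

__all__ = ["SyntheticEcgSpec", "SyntheticNoiseSpec", "generate_ecg", "generate_ma_noise"]

logger = logging.getLogger(__name__)

#: physiological refractory floor: a second R peak cannot occur within 200 ms
_MIN_RR_S = 0.2


@dataclass(frozen=True)
class SyntheticEcgSpec:
    """Parameters of a synthetic single-channel ECG.

    Either give ``rr_intervals`` explicitly (seconds) or a ``mean_rr_s`` with
    Gaussian ``rr_jitter_sd_s`` around it; every interval must exceed 200 ms.
    """

    fs: float = 360.0
    duration_s: float = 30.0
    rr_intervals: tuple[float, ...] | None = None
    mean_rr_s: float = 0.8
    rr_jitter_sd_s: float = 0.05
    qrs_width_ms: float = 100.0
    qrs_amplitude_mV: float = 1.0
    t_wave_amplitude_mV: float = 0.2
    baseline_wander_amplitude_mV: float = 0.05
    baseline_wander_frequency_Hz: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("qrs_amplitude_mV", "t_wave_amplitude_mV",
                     "baseline_wander_amplitude_mV", "qrs_width_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rr_intervals is not None:
            if any(rr <= _MIN_RR_S for rr in self.rr_intervals):
                raise ValueError("all RR intervals must exceed 0.2 s")
        elif self.mean_rr_s <= _MIN_RR_S:
            raise ValueError("mean RR must exceed 0.2 s")


@dataclass(frozen=True)
class SyntheticNoiseSpec:
    """Band-limited Gaussian noise emulating a muscle-artifact recording.

    The default 15–110 Hz band overlaps the detector's passband, so the
    noise genuinely perturbs the feature signal, as real EMG artifact does.
    """

    fs: float = 360.0
    duration_s: float = 30.0
    band_Hz: tuple[float, float] = (15.0, 110.0)
    rms_mV: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.band_Hz
        if not 0 < low < high < self.fs / 2:
            raise ValueError(f"band {self.band_Hz} must satisfy 0 < low < high < fs/2")
        if self.rms_mV < 0:
            raise ValueError("rms_mV must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def _draw_rr_intervals(spec: SyntheticEcgSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.rr_intervals is not None:
        return np.asarray(spec.rr_intervals, dtype=float)
    n = int(np.ceil(spec.duration_s / spec.mean_rr_s)) + 2
    rr = rng.normal(spec.mean_rr_s, spec.rr_jitter_sd_s, size=n)
    return np.clip(rr, _MIN_RR_S + 0.05, None)


def generate_ecg(spec: SyntheticEcgSpec) -> tuple[EcgRecord, BeatAnnotations]:
    """Generate a synthetic ECG together with its exact R-peak ground truth.

    One QRS template is centred at each cumulative-RR position; the returned
    annotations are precisely those centre sample indices with code 'N'.
    Deterministic for a fixed seed. Beats whose cumulative RR position falls
    beyond ``duration_s`` are truncated (with a logged count).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    ecg = spec.baseline_wander_amplitude_mV * np.sin(
        2 * np.pi * spec.baseline_wander_frequency_Hz * t)

    rr = _draw_rr_intervals(spec, rng)
    beat_times = np.cumsum(rr)
    n_total = beat_times.size
    beat_times = beat_times[beat_times < spec.duration_s]
    if beat_times.size < n_total:
        logger.debug("truncated %d beats beyond duration_s", n_total - beat_times.size)
    centers = np.round(beat_times * spec.fs).astype(np.int64)
    centers = centers[centers < n]

    sd = (spec.qrs_width_ms / 5.0) / 1000.0  # visible complex spans ~qrs_width_ms
    half = int(round(4 * sd * spec.fs)) + 1
    offs = np.arange(-half, half + 1)
    qrs = spec.qrs_amplitude_mV * np.exp(-0.5 * (offs / (sd * spec.fs)) ** 2)
    t_sd = 2.5 * sd
    t_half = int(round(4 * t_sd * spec.fs)) + 1
    t_offs = np.arange(-t_half, t_half + 1)
    t_wave = -spec.t_wave_amplitude_mV * np.exp(-0.5 * (t_offs / (t_sd * spec.fs)) ** 2)
    t_delay = int(round(0.300 * spec.fs))

    for c in centers:
        lo, hi = max(0, c - half), min(n, c + half + 1)
        ecg[lo:hi] += qrs[lo - (c - half): hi - (c - half)]
        tc = c + t_delay
        lo, hi = max(0, tc - t_half), min(n, tc + t_half + 1)
        if lo < hi:
            ecg[lo:hi] += t_wave[lo - (tc - t_half): hi - (tc - t_half)]

    record_id = f"synthetic-ecg-{spec.seed}"
    rec = EcgRecord(record_id=record_id, fs=spec.fs, samples=ecg)
    ann = BeatAnnotations(record_id=record_id,
                          entries=tuple((int(c), "N") for c in centers),
                          beat_only=True)
    return rec, ann


def generate_ma_noise(spec: SyntheticNoiseSpec) -> EcgRecord:
    """Band-limited Gaussian noise rescaled to the requested RMS exactly."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    white = rng.standard_normal(n)
    if spec.rms_mV == 0:
        return EcgRecord(record_id=f"synthetic-ma-{spec.seed}", fs=spec.fs,
                         samples=np.zeros(n))
    sos = sps.butter(4, spec.band_Hz, btype="bandpass", fs=spec.fs, output="sos")
    shaped = sps.sosfilt(sos, white)
    measured = float(np.sqrt(np.mean(shaped**2)))
    shaped *= spec.rms_mV / measured
    return EcgRecord(record_id=f"synthetic-ma-{spec.seed}", fs=spec.fs, samples=shaped)
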