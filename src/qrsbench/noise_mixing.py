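"""Relative-SNR computation and controlled noise mixing.

The test records are built by adding a scaled muscle-artifact trace to a raw
ECG record. Because the raw record already carries intrinsic noise, the SNR
is *relative*: it compares the RMS of the whole raw record against the RMS
of the added, scaled noise,

    SNR = 20 * log10(RMS_s / RMS_n),

and the scaling factor that hits a target SNR is

    m = (RMS_s / RMS_n) * 10 ** (-tSNR / 20),

after which the mixed record is simply ``signal + m * noise``. The standard
mixing grid has 18 levels: a "no noise added" sentinel (m = 0) plus RMS
ratios 10 down to 0.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .wfdb_io import EcgRecord

__all__ = [
    "NO_NOISE",
    "SNR_GRID_DB",
    "SNR_GRID_RATIOS",
    "MixSpec",
    "MixGrid",
    "rms",
    "relative_snr",
    "scaling_factor",
    "mix",
    "snr_label",
]

#: Sentinel for the unmixed condition ("no noise added"); scaling factor 0.
NO_NOISE = None

#: RMS ratios of the standard 18-level mixing grid (None = no noise added).
SNR_GRID_RATIOS: tuple[float | None, ...] = (
    None, 10, 9, 8, 7, 6, 5, 4, 3, 2, 1.8, 1.6, 1.4, 1.2, 1, 0.8, 0.6, 0.4)

#: The same grid expressed in dB: 20*log10(ratio), None = no noise added.
SNR_GRID_DB: tuple[float | None, ...] = tuple(
    None if r is None else 20 * math.log10(r) for r in SNR_GRID_RATIOS)


def snr_label(target_snr_db: float | None, ndigits: int = 2) -> str:
    """Human-readable label for an SNR level ('no noise added' or e.g. '6.02')."""
    if target_snr_db is None:
        return "no noise added"
    return f"{target_snr_db:.{ndigits}f}"


@dataclass(frozen=True)
class MixSpec:
    """One realized mixing condition: target SNR and the computed scale m."""

    target_snr_db: float | None
    scaling_factor_m: float
    source_record_id: str
    noise_record_id: str

    def __post_init__(self) -> None:
        if self.scaling_factor_m < 0:
            raise ValueError("scaling factor must be non-negative")
        if (self.scaling_factor_m == 0) != (self.target_snr_db is None):
            raise ValueError("m == 0 exactly when the no-noise sentinel is used")


@dataclass(frozen=True)
class MixGrid:
    """The full mixing grid: SNR levels crossed with source records."""

    snr_levels: tuple[float | None, ...] = SNR_GRID_DB
    records: tuple[str, ...] = ()

    @property
    def n_outputs(self) -> int:
        return len(self.snr_levels) * len(self.records)


def rms(samples: np.ndarray) -> float:
    """Root mean square, sqrt(mean(x^2)), over the full sequence."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("RMS of an empty sequence is undefined")
    if not np.all(np.isfinite(x)):
        raise ValueError("RMS requires finite samples")
    return float(np.sqrt(np.mean(x**2)))


def relative_snr(signal: EcgRecord, noise: EcgRecord) -> float:
    """Relative SNR in dB: 20*log10(RMS_signal / RMS_noise).

    A zero-RMS noise trace raises: infinite SNR is the "no noise added"
    sentinel, not a number.
    """
    rms_n = rms(noise.samples)
    if rms_n == 0:
        raise ValueError("noise RMS is zero; use the no-noise sentinel instead")
    return 20.0 * math.log10(rms(signal.samples) / rms_n)


def scaling_factor(signal: EcgRecord, noise: EcgRecord,
                   target_snr_db: float | None) -> float:
    """Scale m such that relative_snr(signal, m*noise) == target_snr_db.

    The no-noise sentinel maps to m = 0.
    """
    if target_snr_db is None:
        return 0.0
    rms_n = rms(noise.samples)
    if rms_n == 0:
        raise ValueError("noise RMS is zero; cannot compute a scaling factor")
    return (rms(signal.samples) / rms_n) * 10.0 ** (-target_snr_db / 20.0)


def _fit_noise_length(noise: np.ndarray, n: int) -> np.ndarray:
    # equal-length database records never hit this; synthetic inputs may
    if noise.size >= n:
        return noise[:n]
    reps = int(np.ceil(n / noise.size))
    return np.tile(noise, reps)[:n]


def mix(signal: EcgRecord, noise: EcgRecord,
        target_snr_db: float | None) -> EcgRecord:
    """Mix scaled noise into a record to reach the target relative SNR.

    Returns ``signal + m * noise`` element-wise; the record id encodes the
    source id and the SNR label. A shorter noise trace is tiled end-to-end,
    a longer one truncated. Sampling rates must match.
    """
    if signal.fs != noise.fs:
        raise ValueError(
            f"sampling rate mismatch: signal {signal.fs} Hz vs noise {noise.fs} Hz")
    m = scaling_factor(signal, noise, target_snr_db)
    record_id = f"{signal.record_id}+snr={snr_label(target_snr_db)}"
    if m == 0.0:
        return signal.with_samples(signal.samples.copy(), record_id=record_id)
    noise_fit = _fit_noise_length(noise.samples, signal.n_samples)
    return signal.with_samples(signal.samples + m * noise_fit, record_id=record_id)
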