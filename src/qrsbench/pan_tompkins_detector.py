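"""Traced reimplementation of a Pan-Tompkins-style QRS detector.

The detector under study is the widely used moving-window-integration
variant: a causal bandpass → first difference → squaring → 150 ms causal
moving average produces the feature signal mwa[n]; the decision stage then
scans mwa[n] for *strict* local maxima and accepts a candidate as a beat
label when it exceeds an adaptive threshold and falls more than 300 ms
(0.3*fs samples) after the previous beat label.

Two behaviors of that implementation are deliberately preserved because
they are exactly what this package exists to measure:

* no group-delay compensation anywhere — the reported detection point is
  the mwa-axis candidate index itself, so beat labels lag the annotated
  R peak by roughly the filter delays plus a variable fraction of the
  mwa plateau (tens of samples at 360 Hz);
* the strict-inequality local-maximum test (``mwa[i-1] < mwa[i] and
  mwa[i+1] < mwa[i]``) — on the flat-topped plateaus the 150 ms average
  produces, this fires late or erratically, which is the mechanism behind
  the counter-intuitive cases where *adding* noise reduces detection
  jitter and improves DER.

Every candidate evaluation is recorded in a trace (rising, falling,
above-threshold, outside-refractory booleans) so the decision stage can be
audited sample by sample.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .wfdb_io import EcgRecord

__all__ = [
    "DetectorConfig",
    "FeatureSignal",
    "CandidateTraceRow",
    "DetectionResult",
    "preprocess",
    "detect",
    "detect_record",
    "trace_window",
]


@dataclass(frozen=True)
class DetectorConfig:
    """All detector constants, exposed so the decision stage is auditable.

    Defaults: 5–15 Hz order-1 recursive bandpass run causally, 150 ms moving
    average (54 samples at 360 Hz), 300 ms refractory, classic adaptive
    threshold updates (running peak <- 0.125*peak + 0.875*previous,
    threshold = noise + 0.25*(signal - noise)), searchback at 1.66x the
    running 8-interval RR average with a half threshold.
    """

    fs: float = 360.0
    band_low_Hz: float = 5.0
    band_high_Hz: float = 15.0
    filter_order: int = 1
    mwa_window_ms: float = 150.0
    refractory_ms: float = 300.0
    threshold_signal_update: float = 0.125
    threshold_noise_update: float = 0.125
    threshold_fraction: float = 0.25
    searchback_rr_factor: float = 1.66
    searchback_threshold_fraction: float = 0.5
    searchback_signal_update: float = 0.25
    rr_average_beats: int = 8
    warmup_suppress_ms: float = 300.0
    init_window_s: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low_Hz < self.band_high_Hz < self.fs / 2:
            raise ValueError("passband must satisfy 0 < low < high < fs/2")
        if self.refractory_ms < 200:
            raise ValueError("refractory must be >= 200 ms (physiological floor)")
        if self.mwa_window_ms <= 0:
            raise ValueError("mwa_window_ms must be positive")

    @property
    def mwa_window_samples(self) -> int:
        return int(round(self.mwa_window_ms * self.fs / 1000.0))

    @property
    def refractory_samples(self) -> float:
        # Algorithm condition is (i - last) > 0.3*fs, kept as a float product
        return self.refractory_ms / 1000.0 * self.fs


@dataclass(frozen=True)
class FeatureSignal:
    """mwa[n] plus the intermediate stage outputs, on the input sample axis."""

    mwa: np.ndarray
    bandpassed: np.ndarray
    differentiated: np.ndarray
    squared: np.ndarray
    fs: float


@dataclass(frozen=True)
class CandidateTraceRow:
    """One decision-stage evaluation of a candidate sample.

    ``accepted`` is exactly the conjunction of the four conditions;
    ``searchback`` marks labels emitted retroactively by the searchback
    mechanism (their above_threshold refers to the full threshold, which
    they failed at first pass).
    """

    sample_index: int
    rising: bool
    falling: bool
    above_threshold: bool
    outside_refractory: bool
    accepted: bool
    threshold: float
    mwa_value: float
    searchback: bool = False

    def __post_init__(self) -> None:
        conj = self.rising and self.falling and self.above_threshold and self.outside_refractory
        if self.accepted != conj:
            raise ValueError("accepted must equal rising & falling & above_threshold "
                             "& outside_refractory")


@dataclass(frozen=True)
class DetectionResult:
    """Beat labels plus the full decision trace that produced them."""

    beat_labels: np.ndarray
    trace: tuple[CandidateTraceRow, ...]
    thresholds: np.ndarray  # threshold_I1 at each trace row
    config: DetectorConfig
    feature: FeatureSignal

    def __post_init__(self) -> None:
        labels = np.asarray(self.beat_labels, dtype=np.int64)
        object.__setattr__(self, "beat_labels", labels)
        if labels.size > 1:
            gaps = np.diff(labels)
            if np.any(gaps <= 0):
                raise ValueError("beat labels must be strictly increasing")
            if np.any(gaps <= self.config.refractory_samples):
                raise ValueError("consecutive beat labels violate the refractory period")

    def replay_labels(self) -> np.ndarray:
        """Reconstruct beat_labels from the trace alone (completeness check)."""
        out = sorted(r.sample_index for r in self.trace if r.accepted or r.searchback)
        return np.asarray(out, dtype=np.int64)


def preprocess(rec: EcgRecord, cfg: DetectorConfig) -> FeatureSignal:
    """Causal feature chain: bandpass -> first difference -> square -> MWA.

    All stages run forward only, so group delay is left in; the output is on
    the same sample axis and has the same length as the input. The moving
    average is the trailing mean over ``mwa_window_samples`` with a growing
    window during warm-up.
    """
    if rec.fs != cfg.fs:
        raise ValueError(f"record fs {rec.fs} != detector fs {cfg.fs}")
    window = cfg.mwa_window_samples
    if rec.n_samples <= window:
        raise ValueError(
            f"record of {rec.n_samples} samples is shorter than one "
            f"{window}-sample moving-average window")
    x = rec.samples
    sos = sps.butter(cfg.filter_order, [cfg.band_low_Hz, cfg.band_high_Hz],
                     btype="bandpass", fs=cfg.fs, output="sos")
    bp = sps.sosfilt(sos, x)
    diff = np.diff(bp, prepend=bp[0])
    sq = diff * diff
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    n = sq.size
    idx = np.arange(n)
    start = np.maximum(idx - window + 1, 0)
    mwa = (csum[idx + 1] - csum[start]) / (idx - start + 1)
    return FeatureSignal(mwa=mwa, bandpassed=bp, differentiated=diff, squared=sq,
                         fs=cfg.fs)


def _local_maxima(mwa: np.ndarray) -> np.ndarray:
    """Strict local maxima: mwa[i-1] < mwa[i] and mwa[i+1] < mwa[i].

    Plateau samples satisfy neither strict inequality on at least one side
    and therefore yield no candidate — kept verbatim from the studied
    implementation; this ambiguity is the behavior under test.
    """
    if mwa.size < 3:
        return np.empty(0, dtype=np.int64)
    interior = mwa[1:-1]
    mask = (mwa[:-2] < interior) & (mwa[2:] < interior)
    return np.flatnonzero(mask) + 1


class _Thresholds:
    """Running signal/noise peak estimates and threshold_I1."""

    def __init__(self, cfg: DetectorConfig, mwa: np.ndarray):
        init = mwa[: max(2, int(round(cfg.init_window_s * cfg.fs)))]
        self.spki = float(np.max(init))
        self.npki = float(np.mean(init))
        self.cfg = cfg

    @property
    def threshold(self) -> float:
        return self.npki + self.cfg.threshold_fraction * (self.spki - self.npki)

    def on_signal(self, value: float) -> None:
        a = self.cfg.threshold_signal_update
        self.spki = a * value + (1 - a) * self.spki

    def on_searchback_signal(self, value: float) -> None:
        a = self.cfg.searchback_signal_update
        self.spki = a * value + (1 - a) * self.spki

    def on_noise(self, value: float) -> None:
        a = self.cfg.threshold_noise_update
        self.npki = a * value + (1 - a) * self.npki


def detect(feat: FeatureSignal, cfg: DetectorConfig) -> DetectionResult:
    """Run the decision stage over a feature signal.

    Every strict local maximum of mwa is a candidate; a candidate becomes a
    beat label iff it exceeds threshold_I1 and lies more than 0.3*fs samples
    after the previous label. Rejected candidates update the noise estimate.
    When the gap since the last label exceeds ``searchback_rr_factor`` times
    the running RR average, the gap is re-scanned for the largest rejected
    candidate above half the threshold, which is then emitted retroactively
    (flagged ``searchback`` in the trace). Candidates inside the first
    ``warmup_suppress_ms`` are never accepted.
    """
    mwa = feat.mwa
    thr = _Thresholds(cfg, mwa)
    refractory = cfg.refractory_samples
    warmup = cfg.warmup_suppress_ms / 1000.0 * cfg.fs

    rows: list[CandidateTraceRow] = []
    labels: list[int] = []
    rr_history: deque[float] = deque(maxlen=cfg.rr_average_beats)
    # rejected-but-plausible candidates in the current inter-beat gap
    gap_candidates: list[tuple[int, float, int]] = []  # (index, value, row position)

    def add_label(i: int) -> None:
        if labels:
            rr_history.append(i - labels[-1])
        labels.append(i)

    for i in _local_maxima(mwa):
        v = float(mwa[i])

        # searchback: abnormally long gap -> re-scan rejected candidates
        if labels and rr_history:
            rr_avg = float(np.mean(rr_history))
            if (i - labels[-1]) > cfg.searchback_rr_factor * rr_avg and gap_candidates:
                sb_thr = cfg.searchback_threshold_fraction * thr.threshold
                eligible = [(j, vj, rpos) for j, vj, rpos in gap_candidates
                            if vj > sb_thr and (j - labels[-1]) > refractory
                            and (i - j) > refractory]
                if eligible:
                    j, vj, rpos = max(eligible, key=lambda e: e[1])
                    add_label(j)
                    old = rows[rpos]
                    rows[rpos] = CandidateTraceRow(
                        sample_index=old.sample_index, rising=old.rising,
                        falling=old.falling, above_threshold=old.above_threshold,
                        outside_refractory=old.outside_refractory,
                        accepted=old.accepted, threshold=old.threshold,
                        mwa_value=old.mwa_value, searchback=True)
                    gap_candidates = [(jj, vv, pp) for jj, vv, pp in gap_candidates
                                      if jj > j]

        threshold = thr.threshold
        above = v > threshold
        outside = (i - labels[-1]) > refractory if labels else True
        past_warmup = i > warmup
        accepted = above and outside and past_warmup
        # warm-up suppression folds into the threshold condition so the row
        # invariant (accepted == conjunction of the four booleans) holds
        row_above = above and past_warmup
        rows.append(CandidateTraceRow(
            sample_index=int(i), rising=True, falling=True,
            above_threshold=row_above, outside_refractory=outside,
            accepted=accepted, threshold=threshold, mwa_value=v))
        if accepted:
            add_label(int(i))
            gap_candidates = []
            thr.on_signal(v)
        else:
            thr.on_noise(v)
            if outside and past_warmup:
                gap_candidates.append((int(i), v, len(rows) - 1))

    # searchback may have inserted labels out of order relative to append time
    labels_arr = np.asarray(sorted(labels), dtype=np.int64)
    thresholds = np.asarray([r.threshold for r in rows])
    return DetectionResult(beat_labels=labels_arr, trace=tuple(rows),
                           thresholds=thresholds, config=cfg, feature=feat)


def detect_record(rec: EcgRecord, cfg: DetectorConfig | None = None) -> DetectionResult:
    """Convenience: preprocess + detect with a default config at rec.fs."""
    if cfg is None:
        cfg = DetectorConfig(fs=rec.fs)
    return detect(preprocess(rec, cfg), cfg)


def trace_window(result: DetectionResult, start: int, end: int
                 ) -> tuple[CandidateTraceRow, ...]:
    """Decision-trace rows for a sample window, plus boundary rows.

    Returns the local-peak rows with ``start <= i <= end``, bracketed by
    synthetic rows for the boundary samples themselves (whose rising/falling
    flags are evaluated directly on mwa), matching the truth-table layout
    used to audit individual strips.
    """
    mwa = result.feature.mwa
    if not 0 <= start < end < mwa.size:
        raise ValueError(f"window [{start}, {end}] out of range for {mwa.size} samples")

    inner = [r for r in result.trace if start <= r.sample_index <= end]

    def boundary(i: int) -> CandidateTraceRow:
        rising = bool(mwa[i - 1] < mwa[i]) if i > 0 else False
        falling = bool(mwa[i + 1] < mwa[i]) if i + 1 < mwa.size else False
        thr = _threshold_at(result, i)
        above = bool(mwa[i] > thr)
        labels = result.beat_labels
        prev = labels[labels < i]
        outside = bool((i - prev[-1]) > result.config.refractory_samples) if prev.size else True
        return CandidateTraceRow(
            sample_index=i, rising=rising, falling=falling, above_threshold=above,
            outside_refractory=outside,
            accepted=rising and falling and above and outside,
            threshold=thr, mwa_value=float(mwa[i]))

    out = list(inner)
    if not inner or inner[0].sample_index != start:
        out.insert(0, boundary(start))
    if not inner or inner[-1].sample_index != end:
        out.append(boundary(end))
    return tuple(out)


def _threshold_at(result: DetectionResult, i: int) -> float:
    """threshold_I1 in force at sample i (piecewise constant between candidates)."""
    idx = np.asarray([r.sample_index for r in result.trace])
    pos = int(np.searchsorted(idx, i, side="left"))
    if pos >= len(result.trace):
        return float(result.thresholds[-1]) if result.thresholds.size else 0.0
    return float(result.thresholds[pos])
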