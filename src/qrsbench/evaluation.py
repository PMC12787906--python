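"""Beat pairing and detection statistics.

Two pairing schemes are provided:

* **tolerance pairing** — one-to-one matching of reference and detected
  beat labels whose distance does not exceed the detection time tolerance
  (DTT, inclusive). TP/FP/FN counts then feed the classic statistics

      DER = (FP + FN) / (TP + FN)        (may exceed 100%)
      Se  = TP / (TP + FN)
      PPV = TP / (TP + FP)
      F1  = 2 * PPV * Se / (PPV + Se)

* **proximity pairing** — tolerance-free mutual-nearest-neighbor matching
  used by the JF benchmark: the F1 computed from the proximity counts is
  discounted by f(jitter) = 1 / (1 + jitter / 12 ms), where jitter is the
  mean absolute reference-to-detection distance over matched pairs, so a
  detector with perfect counts but 12 ms average jitter scores JF = 50%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .wfdb_io import BeatAnnotations

__all__ = [
    "DttPairing",
    "MetricSet",
    "JfResult",
    "UndefinedMetricError",
    "pair_with_tolerance",
    "metrics",
    "metrics_from_counts",
    "pair_by_proximity",
    "jitter_to_score",
    "jf_score",
    "jitter_histogram",
    "dtt_to_ms",
    "JITTER_HALF_SCORE_MS",
]

#: mean absolute jitter at which the JF discount reaches 0.5
JITTER_HALF_SCORE_MS = 12.0


class UndefinedMetricError(ZeroDivisionError):
    """A statistic's denominator is zero (e.g. Se with no reference beats)."""


def _as_sample_array(labels: "BeatAnnotations | Sequence[int] | np.ndarray",
                     what: str) -> np.ndarray:
    if isinstance(labels, BeatAnnotations):
        arr = labels.sample_indices
    else:
        arr = np.asarray(labels, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional")
    if arr.size > 1 and np.any(np.diff(arr) < 0):
        raise ValueError(f"{what} must be sorted by sample index")
    return arr


@dataclass(frozen=True)
class DttPairing:
    """One-to-one matching under a tolerance, with signed jitter per pair."""

    dtt_samples: int
    pairs: tuple[tuple[int, int, int], ...]  # (ref, det, jitter = det - ref)
    fp_indices: tuple[int, ...]  # unmatched detections
    fn_indices: tuple[int, ...]  # unmatched references

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_indices)

    @property
    def fn(self) -> int:
        return len(self.fn_indices)

    @property
    def jitters(self) -> np.ndarray:
        return np.asarray([j for _, _, j in self.pairs], dtype=np.int64)


@dataclass(frozen=True)
class MetricSet:
    """TP/FP/FN counts and the derived percentages (full precision)."""

    TB: int
    TP: int
    FN: int
    FP: int
    DER: float
    Se: float
    PPV: float
    F1: float

    def round2(self) -> dict:
        """Display form: percentages at two decimals, as in the report tables."""
        return {"TB": self.TB, "TP": self.TP, "FN": self.FN, "FP": self.FP,
                "Se": round(self.Se, 2), "PPV": round(self.PPV, 2),
                "F1": round(self.F1, 2), "DER": round(self.DER, 2)}


@dataclass(frozen=True)
class JfResult:
    """JF benchmark outcome: proximity counts, jitter, discount, JF percent."""

    TP_JF: int
    FP_JF: int
    FN_JF: int
    mean_abs_jitter_ms: float
    jitter_score: float
    F1_JF: float  # percent
    JF: float     # percent


def pair_with_tolerance(refs, dets, dtt_samples: int) -> DttPairing:
    """Pair references and detections one-to-one within ±dtt_samples.

    Greedy by ascending absolute distance, ties broken toward the earlier
    reference then the earlier detection; the comparison is inclusive
    (|det - ref| <= DTT). Equal to the maximum-cardinality matching whenever
    events are separated by more than 2*DTT, which holds at all standard DTT
    values against a >108-sample refractory.
    """
    if dtt_samples < 0:
        raise ValueError("dtt_samples must be non-negative")
    ref = _as_sample_array(refs, "references")
    det = _as_sample_array(dets, "detections")
    candidates: list[tuple[int, int, int]] = []  # (|delta|, ref_pos, det_pos)
    lo = np.searchsorted(det, ref - dtt_samples, side="left")
    hi = np.searchsorted(det, ref + dtt_samples, side="right")
    for rpos in range(ref.size):
        for dpos in range(int(lo[rpos]), int(hi[rpos])):
            candidates.append((abs(int(det[dpos]) - int(ref[rpos])), rpos, dpos))
    candidates.sort()
    ref_used = np.zeros(ref.size, dtype=bool)
    det_used = np.zeros(det.size, dtype=bool)
    pairs: list[tuple[int, int, int]] = []
    for _, rpos, dpos in candidates:
        if not ref_used[rpos] and not det_used[dpos]:
            ref_used[rpos] = det_used[dpos] = True
            pairs.append((int(ref[rpos]), int(det[dpos]),
                          int(det[dpos]) - int(ref[rpos])))
    pairs.sort()
    return DttPairing(
        dtt_samples=int(dtt_samples),
        pairs=tuple(pairs),
        fp_indices=tuple(int(x) for x in det[~det_used]),
        fn_indices=tuple(int(x) for x in ref[~ref_used]),
    )


def metrics_from_counts(tp: int, fn: int, fp: int) -> MetricSet:
    """DER/Se/PPV/F1 from raw counts; full internal precision, percentages."""
    if tp + fn == 0:
        raise UndefinedMetricError("Se and DER are undefined with no reference beats")
    se = 100.0 * tp / (tp + fn)
    der = 100.0 * (fp + fn) / (tp + fn)
    if tp + fp == 0:
        raise UndefinedMetricError("PPV is undefined with no detections")
    ppv = 100.0 * tp / (tp + fp)
    f1 = 2 * ppv * se / (ppv + se) if (ppv + se) > 0 else 0.0
    return MetricSet(TB=tp + fn, TP=tp, FN=fn, FP=fp, DER=der, Se=se, PPV=ppv, F1=f1)


def metrics(pairing: DttPairing) -> MetricSet:
    """Detection statistics of a tolerance pairing."""
    return metrics_from_counts(pairing.tp, pairing.fn, pairing.fp)


def pair_by_proximity(refs, dets) -> tuple[int, int, int, tuple[tuple[int, int], ...]]:
    """Tolerance-free mutual-nearest-neighbor pairing.

    Each reference is matched to its nearest detection and vice versa; a
    pair forms only where the choice is mutual. Equidistant candidates
    resolve toward the earlier label. Returns (TP_JF, FP_JF, FN_JF, pairs);
    every unpaired detection counts as FP_JF and every unpaired reference
    as FN_JF.
    """
    ref = _as_sample_array(refs, "references")
    det = _as_sample_array(dets, "detections")
    if ref.size == 0 or det.size == 0:
        return 0, int(det.size), int(ref.size), ()

    def nearest(sources: np.ndarray, targets: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(targets, sources)
        left = np.clip(pos - 1, 0, targets.size - 1)
        right = np.clip(pos, 0, targets.size - 1)
        d_left = np.abs(sources - targets[left])
        d_right = np.abs(sources - targets[right])
        return np.where(d_left <= d_right, left, right)  # tie -> earlier label

    ref_to_det = nearest(ref, det)
    det_to_ref = nearest(det, ref)
    pairs = tuple(
        (int(ref[r]), int(det[ref_to_det[r]]))
        for r in range(ref.size)
        if det_to_ref[ref_to_det[r]] == r
    )
    matched_dets = {d for _, d in pairs}
    fp = int(det.size - len(matched_dets))
    fn = int(ref.size - len(pairs))
    return len(pairs), fp, fn, pairs


def jitter_to_score(mean_abs_jitter_ms: float) -> float:
    """JF jitter discount: 1 / (1 + jitter / 12 ms); 0 ms -> 1, 12 ms -> 0.5."""
    if mean_abs_jitter_ms < 0:
        raise ValueError("jitter must be non-negative")
    return 1.0 / (1.0 + mean_abs_jitter_ms / JITTER_HALF_SCORE_MS)


def jf_score(refs, dets, fs: float) -> JfResult:
    """JF benchmark: proximity-paired F1 discounted by the jitter score.

    JF = F1_JF * f(mean |jitter| in ms), both expressed in percent.
    """
    tp, fp, fn, pairs = pair_by_proximity(refs, dets)
    if tp == 0:
        raise UndefinedMetricError("mean jitter is undefined with no proximity pairs")
    jit_ms = float(np.mean([abs(d - r) for r, d in pairs])) * 1000.0 / fs
    score = jitter_to_score(jit_ms)
    f1_jf = 100.0 * 2 * tp / (2 * tp + fp + fn)
    return JfResult(TP_JF=tp, FP_JF=fp, FN_JF=fn, mean_abs_jitter_ms=jit_ms,
                    jitter_score=score, F1_JF=f1_jf, JF=f1_jf * score)


def jitter_histogram(pairings: Sequence[DttPairing], bin_width_samples: int = 1
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of signed jitters pooled over pairings, bins aligned at 0.

    Returns (bin_edges, counts); the edge grid is k*bin_width for integer k.
    """
    if bin_width_samples <= 0:
        raise ValueError("bin width must be positive")
    jit = np.concatenate([p.jitters for p in pairings]) if pairings else np.empty(0)
    if jit.size == 0:
        return np.array([0, bin_width_samples]), np.array([0])
    lo = int(np.floor(jit.min() / bin_width_samples)) * bin_width_samples
    hi = (int(np.floor(jit.max() / bin_width_samples)) + 1) * bin_width_samples
    edges = np.arange(lo, hi + bin_width_samples, bin_width_samples)
    counts, _ = np.histogram(jit, bins=edges)
    return edges, counts


def dtt_to_ms(dtt_samples: int, fs: float) -> float:
    """Tolerance in ms at a sampling rate, rounded to the displayed 2 decimals."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    return round(dtt_samples * 1000.0 / fs, 2)
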