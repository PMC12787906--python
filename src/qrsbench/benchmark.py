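"""Orchestration of the DTT x SNR benchmarking sweep.

For every (record, SNR) cell the detector runs once on the mixed record;
the cached detections are then paired against the reference beats at every
DTT level. Per-record statistics are kept, and the pooled statistics for
each (DTT, SNR) cell are recomputed from *summed* TP/FN/FP counts — never
averaged from per-record percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import dtt_to_ms, metrics_from_counts, pair_with_tolerance
from .noise_mixing import SNR_GRID_DB, mix, snr_label
from .pan_tompkins_detector import DetectorConfig, detect_record
from .wfdb_io import BeatAnnotations, EcgRecord, filter_beat_annotations

__all__ = ["DTT_GRID", "SweepConfig", "SweepResult", "run_sweep",
           "per_record_der_diff", "report"]

#: Standard tolerance grid: odd sample counts 3..59 (8.33..163.89 ms at 360 Hz).
DTT_GRID: tuple[int, ...] = tuple(range(3, 60, 4))

_COLUMNS = ["record", "dtt_samples", "dtt_ms", "snr_db", "TB", "TP", "FN", "FP",
            "Se", "PPV", "F1", "DER", "TP_TB"]


@dataclass(frozen=True)
class SweepConfig:
    """Declarative description of a sweep: grids, detector constants, pooling."""

    dtt_grid: tuple[int, ...] = DTT_GRID
    snr_grid: tuple[float | None, ...] = SNR_GRID_DB
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    pooling_rule: str = "summed-counts"

    def __post_init__(self) -> None:
        if not self.dtt_grid or not self.snr_grid:
            raise ValueError("dtt_grid and snr_grid must be non-empty")
        if any(d % 2 == 0 or d <= 0 for d in self.dtt_grid):
            raise ValueError("DTT values are positive odd sample counts")
        if self.pooling_rule != "summed-counts":
            raise ValueError(f"unknown pooling rule {self.pooling_rule!r}")


@dataclass(frozen=True)
class SweepResult:
    """Per-record and pooled statistics over the grid, as tidy DataFrames."""

    per_record: pd.DataFrame
    pooled: pd.DataFrame
    config: SweepConfig

    def cell(self, dtt: int, snr_db: float | None, pooled: bool = True) -> pd.Series:
        df = self.pooled if pooled else self.per_record
        sel = df[(df["dtt_samples"] == dtt) & (df["snr_db"] == snr_label(snr_db))]
        if sel.empty:
            raise KeyError(f"no sweep cell for DTT={dtt}, SNR={snr_label(snr_db)}")
        return sel.iloc[0] if pooled else sel


def run_sweep(records: Sequence[tuple[EcgRecord, BeatAnnotations]],
              noise: EcgRecord | None,
              cfg: SweepConfig | None = None) -> SweepResult:
    """Mix, detect and score every (record, DTT, SNR) combination.

    ``noise`` may be None only if the SNR grid is just the no-noise sentinel.
    Reference annotations are reduced to beat codes before pairing, so TB
    counts beats only.
    """
    cfg = cfg or SweepConfig()
    if noise is None and any(s is not None for s in cfg.snr_grid):
        raise ValueError("a noise record is required for noise-added SNR levels")
    rows = []
    for rec, ann in records:
        refs = ann if ann.beat_only else filter_beat_annotations(ann)
        for snr_db in cfg.snr_grid:
            mixed = rec if snr_db is None else mix(rec, noise, snr_db)
            detection = detect_record(mixed, cfg.detector)  # once per (record, snr)
            for dtt in cfg.dtt_grid:
                pairing = pair_with_tolerance(refs, detection.beat_labels, dtt)
                m = metrics_from_counts(pairing.tp, pairing.fn, pairing.fp)
                rows.append({
                    "record": rec.record_id, "dtt_samples": dtt,
                    "dtt_ms": dtt_to_ms(dtt, rec.fs), "snr_db": snr_label(snr_db),
                    "TB": m.TB, "TP": m.TP, "FN": m.FN, "FP": m.FP,
                    "Se": m.Se, "PPV": m.PPV, "F1": m.F1, "DER": m.DER,
                    "TP_TB": 100.0 * m.TP / m.TB,
                })
    per_record = pd.DataFrame(rows, columns=_COLUMNS)
    pooled = _pool(per_record)
    return SweepResult(per_record=per_record, pooled=pooled, config=cfg)


def _pool(per_record: pd.DataFrame) -> pd.DataFrame:
    """Pooled statistics: sum TP/FN/FP over records first, then the formulas."""
    rows = []
    for (dtt, dtt_ms, snr), grp in per_record.groupby(
            ["dtt_samples", "dtt_ms", "snr_db"], sort=True):
        tp, fn, fp = int(grp["TP"].sum()), int(grp["FN"].sum()), int(grp["FP"].sum())
        m = metrics_from_counts(tp, fn, fp)
        rows.append({
            "record": "TOTAL", "dtt_samples": dtt, "dtt_ms": dtt_ms, "snr_db": snr,
            "TB": m.TB, "TP": m.TP, "FN": m.FN, "FP": m.FP,
            "Se": m.Se, "PPV": m.PPV, "F1": m.F1, "DER": m.DER,
            "TP_TB": 100.0 * m.TP / m.TB,
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def per_record_der_diff(result: SweepResult, mode: str,
                        dtt: int | None = None,
                        snr_pair: tuple[float | None, float | None] = (None, 6.02),
                        dtt_pair: tuple[int, int] = (35, 31),
                        snr_db: float | None = None) -> pd.DataFrame:
    """Per-record signed DER differences between two sweep cells.

    mode="noise": at fixed ``dtt``, DER(no noise) - DER(with noise), i.e.
    positive means the record *improved* when noise was added.
    mode="dtt": at fixed ``snr_db``, DER(dtt_pair[1]) - DER(dtt_pair[0]);
    positive means DER rose when the tolerance tightened.
    Rows are sorted by decreasing |difference|.
    """
    df = result.per_record
    if mode == "noise":
        if dtt is None:
            raise ValueError("mode='noise' needs a fixed dtt")
        a = df[(df.dtt_samples == dtt) & (df.snr_db == snr_label(snr_pair[0]))]
        b = df[(df.dtt_samples == dtt) & (df.snr_db == snr_label(snr_pair[1]))]
        label = (f"DER(DTT={dtt}, {snr_label(snr_pair[0])}) - "
                 f"DER(DTT={dtt}, {snr_label(snr_pair[1])} dB)")
    elif mode == "dtt":
        key = snr_label(snr_db)
        a = df[(df.dtt_samples == dtt_pair[1]) & (df.snr_db == key)]
        b = df[(df.dtt_samples == dtt_pair[0]) & (df.snr_db == key)]
        label = f"DER(DTT={dtt_pair[1]}) - DER(DTT={dtt_pair[0]}) at SNR={key}"
    else:
        raise ValueError("mode must be 'noise' or 'dtt'")
    if a.empty or b.empty:
        raise KeyError(f"sweep is missing a compared cell for {label}")
    merged = a.set_index("record")[["DER"]].join(
        b.set_index("record")[["DER"]], lsuffix="_a", rsuffix="_b", how="inner")
    out = pd.DataFrame({
        "record": merged.index,
        "der_difference": merged["DER_a"].to_numpy() - merged["DER_b"].to_numpy(),
    })
    out["comparison"] = label
    return out.sort_values("der_difference", key=np.abs, ascending=False,
                           kind="mergesort").reset_index(drop=True)


def report(result: SweepResult, out_dir: str | Path,
           make_plots: bool = True) -> list[Path]:
    """Write pooled/per-record CSVs, DER plots and a reproducibility manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _dump(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.round(2).to_csv(path, index=False)
        written.append(path)

    if not result.pooled.empty:
        _dump(result.pooled, "pooled.csv")
        _dump(result.per_record, "per_record.csv")
        for mode, name in (("noise", "der_diff_noise.csv"), ("dtt", "der_diff_dtt.csv")):
            try:
                if mode == "noise":
                    diff = per_record_der_diff(result, "noise",
                                               dtt=result.config.dtt_grid[0])
                else:
                    diff = per_record_der_diff(result, "dtt",
                                               snr_db=result.config.snr_grid[0],
                                               dtt_pair=(max(result.config.dtt_grid),
                                                         min(result.config.dtt_grid)))
                _dump(diff, name)
            except (KeyError, ValueError):
                pass  # grid too small for this comparison
        if make_plots:
            written.extend(_plots(result, out_dir))

    manifest = {
        "tool": "qrsbench", "version": __version__,
        "dtt_grid": list(result.config.dtt_grid),
        "snr_grid": [snr_label(s) for s in result.config.snr_grid],
        "detector": {k: getattr(result.config.detector, k)
                     for k in DetectorConfig.__dataclass_fields__},
        "pooling_rule": result.config.pooling_rule,
        "n_records": int(result.per_record["record"].nunique()) if not
                     result.per_record.empty else 0,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written


def _plots(result: SweepResult, out_dir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for column, fname in (("DER", "der_vs_dtt.png"), ("TP_TB", "tp_tb_vs_dtt.png")):
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for snr, grp in result.pooled.groupby("snr_db", sort=False):
            grp = grp.sort_values("dtt_samples")
            ax.plot(grp["dtt_samples"], grp[column], marker="o", label=str(snr))
        ax.set_xlabel("detection time tolerance [samples]")
        ax.set_ylabel(f"pooled {column.replace('_', '/')} [%]")
        ax.legend(title="SNR [dB]", fontsize=7)
        fig.tight_layout()
        path = out_dir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
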