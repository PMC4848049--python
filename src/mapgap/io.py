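"""On-disk formats.

* Trace CSV: header ``time_s,map_mv,ecg_mv,sensor_nm`` (plus ``force_g``
  once calibrated) with a JSON sidecar carrying the sample rate, fiber id
  and — for synthetic traces — the generator ground truth.
* Survey directory: ``sites.csv`` (``site_id,phase,in_pattern,trace_file``),
  one trace CSV per site and phase, ``bench.csv`` for the fiber, and a
  ``ground_truth.json`` used only by tests.
* Detection output: per-beat CSV plus a DetectionResult JSON.
* Classification output: ``classification.csv`` plus ``report.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import CalibrationPoint
from .classify import SiteClassification, SurveyReport
from .detection import BeatAssessment, DetectionResult
from .synth import SurveyRecording
from .trace import Trace, TraceTruth


# -------------------------------------------------------------------- traces

def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    cols = {
        "time_s": trace.time,
        "map_mv": trace.map_mv,
        "ecg_mv": trace.ecg_mv,
        "sensor_nm": np.full(len(trace), np.nan) if trace.sensor_nm is None else trace.sensor_nm,
    }
    if trace.force_g is not None:
        cols["force_g"] = trace.force_g
    # %.17g guarantees bit-exact float64 round trips through the CSV
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "sample_rate": trace.sample_rate,
        "fiber_id": trace.fiber_id,
        "quality_uniform": None if trace.quality is None else int(trace.quality[0])
        if len(np.unique(trace.quality)) == 1
        else None,
        "truth": None if trace.truth is None else trace.truth.to_dict(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    side = {}
    if path.with_suffix(".json").exists():
        side = json.loads(path.with_suffix(".json").read_text())
    sample_rate = side.get("sample_rate")
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy())))
    n = len(df)
    quality = None
    if side.get("quality_uniform") is not None:
        quality = np.full(n, side["quality_uniform"], dtype=np.uint8)
    truth = None
    if side.get("truth"):
        truth = TraceTruth.from_dict(side["truth"])
    sensor = df["sensor_nm"].to_numpy() if "sensor_nm" in df else None
    if sensor is not None and np.all(np.isnan(sensor)):
        sensor = None
    return Trace(
        sample_rate=float(sample_rate),
        time=df["time_s"].to_numpy(),
        map_mv=df["map_mv"].to_numpy(),
        ecg_mv=df["ecg_mv"].to_numpy(),
        sensor_nm=sensor,
        force_g=df["force_g"].to_numpy() if "force_g" in df else None,
        fiber_id=side.get("fiber_id"),
        quality=quality,
        truth=truth,
    )


# ------------------------------------------------------------------- surveys

@dataclass
class SurveySiteFile:
    site_id: str
    phase: str
    in_pattern: bool
    trace_file: str


def write_survey(survey: SurveyRecording, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {}
    for rec in survey.sites:
        for phase, trace in (("pre_ablation", rec.pre), ("post_ablation", rec.post)):
            fname = f"{rec.site_id}_{phase}.csv"
            write_trace(trace, outdir / fname)
            rows.append(
                {
                    "site_id": rec.site_id,
                    "phase": phase,
                    "in_pattern": rec.in_pattern,
                    "trace_file": fname,
                }
            )
        truth[rec.site_id] = {
            "in_pattern": rec.in_pattern,
            "is_gap": rec.in_pattern and rec.physiology_post.viable,
            "viable_post": rec.physiology_post.viable,
            "cf_threshold": rec.physiology_pre.cf_threshold,
        }
    pd.DataFrame(rows).to_csv(outdir / "sites.csv", index=False)
    pd.DataFrame(
        [{"force_g": p.applied_force, "shift_nm": p.measured_shift} for p in survey.bench_points]
    ).to_csv(outdir / "bench.csv", index=False)
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return outdir


@dataclass
class SurveyOnDisk:
    sites: list[SurveySiteFile]
    root: Path
    bench_points: list

    def load_trace(self, entry: SurveySiteFile) -> Trace:
        return read_trace(self.root / entry.trace_file)


def read_survey(path: str | Path) -> SurveyOnDisk:
    root = Path(path)
    df = pd.read_csv(root / "sites.csv")
    sites = [
        SurveySiteFile(
            site_id=str(r.site_id),
            phase=str(r.phase),
            in_pattern=bool(r.in_pattern),
            trace_file=str(r.trace_file),
        )
        for r in df.itertuples()
    ]
    bench = []
    if (root / "bench.csv").exists():
        bdf = pd.read_csv(root / "bench.csv")
        bench = [CalibrationPoint(float(f), float(s)) for f, s in zip(bdf.force_g, bdf.shift_nm)]
    return SurveyOnDisk(sites=sites, root=root, bench_points=bench)


# ----------------------------------------------------------------- detection

def _beat_row(b: BeatAssessment) -> dict:
    return {
        "beat_index": b.beat_index,
        "qrs_time_s": b.qrs_time,
        "map_present": b.map_present,
        "amplitude_mv": b.amplitude,
        "at_ms": b.activation_time_at,
        "eor_ms": b.end_of_repolarization_eor,
        "mapdur_ms": b.map_duration_mapdur,
        "cf_g": b.cf_at_beat,
    }


def write_detection(result: DetectionResult, outdir: str | Path, stem: str = "detection") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([_beat_row(b) for b in result.beats]).to_csv(
        outdir / f"{stem}_beats.csv", index=False
    )
    summary = {
        "first_consistent_run_start": result.first_consistent_run_start,
        "cf_at_detection": result.cf_at_detection,
        "max_cf_applied": result.max_cf_applied,
        "n_beats": len(result.beats),
        "n_map_present": sum(1 for b in result.beats if b.map_present),
    }
    (outdir / f"{stem}.json").write_text(json.dumps(summary, indent=2))


# ------------------------------------------------------------ classification

def write_classification(report: SurveyReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "site_id": c.site_id,
                "label": c.label.value,
                "cf_reference_g": c.cf_reference_used,
                "cf_evidence_g": c.cf_evidence,
                "rationale": c.rationale,
            }
            for c in report.classifications
        ]
    ).to_csv(outdir / "classification.csv", index=False)
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
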