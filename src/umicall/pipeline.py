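"""End-to-end pipeline: tag -> group -> consensus -> call -> monitor.

One :class:`PipelineConfig` carries every tunable; all randomness flows from
its single seed, so a run is byte-reproducible.  Outputs per sample: VCF and
TSV report; per patient: time-series and events TSV; plus a QC summary whose
conservation identities (reads in = assigned + rejected; families =
consensus + sub-threshold) always hold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date, datetime
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .calling import DEFAULT_SECONDARY_AF, SampleCall, call_sample
from .consensus import (DEFAULT_MAJORITY_THRESHOLD, DEFAULT_MIN_FAMILY_SIZE,
                        build_all_consensus, group_families)
from .monitor import PatientTimeSeries, build_time_series
from .panel import PanelDefinition, load_panel
from .reads import process_fastq
from .vcfio import write_vcf

log = logging.getLogger("umicall")


class PipelineConfig(BaseModel):
    """All pipeline tunables; serializable round-trip stable (YAML)."""

    umi_length: int = Field(default=12, ge=6)
    min_family_size: int = Field(default=DEFAULT_MIN_FAMILY_SIZE, ge=1)
    majority_threshold: float = Field(default=DEFAULT_MAJORITY_THRESHOLD,
                                      gt=0.5, le=1.0)
    collapse_mode: Literal["exact", "hamming1"] = "exact"
    max_primer_mismatches: int = Field(default=2, ge=0)
    secondary_af_threshold: float = Field(default=DEFAULT_SECONDARY_AF,
                                          gt=0.0, le=1.0)
    positivity_mode: Literal["paper", "confirmed"] = "confirmed"
    confirm_window: int = Field(default=1, ge=1)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


@dataclass
class SampleSheetRow:
    patient_id: str
    sample_id: str
    collection_date: Date
    tracked_hotspot: str
    fastq: Optional[str] = None


def read_sample_sheet(path: str | Path) -> list[SampleSheetRow]:
    """TSV with columns patient_id, sample_id, collection_date (ISO 8601),
    tracked_hotspot and optionally fastq."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "sample_id", "collection_date", "tracked_hotspot"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        rows.append(SampleSheetRow(
            patient_id=r["patient_id"],
            sample_id=r["sample_id"],
            collection_date=datetime.strptime(
                r["collection_date"], "%Y-%m-%d").date(),
            tracked_hotspot=r["tracked_hotspot"],
            fastq=r.get("fastq") if "fastq" in df.columns else None,
        ))
    return rows


@dataclass
class SampleRunResult:
    call: SampleCall
    qc: dict[str, int]


@dataclass
class ReportBundle:
    out_dir: Path
    sample_results: dict[str, SampleRunResult]
    time_series: dict[str, PatientTimeSeries] = field(default_factory=dict)


def process_sample(fastq_path: str | Path, panel: PanelDefinition,
                   config: PipelineConfig, sample_id: str,
                   tracked_hotspots: list[str]) -> SampleRunResult:
    """Run one sample through tag -> consensus -> call."""
    tagged, tally = process_fastq(fastq_path, panel, config.umi_length,
                                  config.max_primer_mismatches)
    families = group_families(tagged, config.collapse_mode)
    target_lengths = {a.assay_id: a.target_length for a in panel.assays}
    cons, n_small = build_all_consensus(
        families, config.min_family_size, config.majority_threshold,
        target_lengths)
    call = call_sample(cons, panel, tracked_hotspots, sample_id,
                       config.secondary_af_threshold)
    qc = tally.as_dict()
    qc.update({
        "umi_families": len(families),
        "consensus_reads": len(cons),
        "families_below_min_size": n_small,
    })
    assert qc["umi_families"] == qc["consensus_reads"] + qc["families_below_min_size"]
    log.info("sample %s: %d reads -> %d families -> %d consensus",
             sample_id, tally.total_reads, len(families), len(cons))
    return SampleRunResult(call=call, qc=qc)


def _sample_report_frame(call: SampleCall) -> pd.DataFrame:
    rows = []
    for r in call.hotspot_results:
        rows.append({
            "sample_id": r.sample_id,
            "hotspot_id": r.hotspot_id,
            "mutant_consensus_count": r.mutant_consensus_count,
            "total_consensus_depth": r.total_consensus_depth,
            "vaf_percent": (round(100.0 * r.vaf, 4)
                            if r.vaf is not None else None),
            "lod_percent": r.lod_percent,
            "is_positive": r.is_positive,
            "evaluable": r.evaluable,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig,
                 fastq_by_sample: dict[str, str | Path],
                 panel_path: str | Path,
                 sample_sheet_path: str | Path,
                 out_dir: str | Path) -> ReportBundle:
    """Full pipeline over a cohort.

    ``fastq_by_sample`` maps sample_id -> FASTQ path (overrides any ``fastq``
    column in the sheet).  Raises with stage and sample context on error;
    outputs land under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = load_panel(panel_path)
    sheet = read_sample_sheet(sample_sheet_path)

    bundle = ReportBundle(out_dir=out_dir, sample_results={})
    for row in sheet:
        fq = fastq_by_sample.get(row.sample_id, row.fastq)
        if fq is None:
            raise FileNotFoundError(
                f"sample {row.sample_id}: no FASTQ given in sheet or mapping")
        try:
            res = process_sample(fq, panel, config, row.sample_id,
                                 [row.tracked_hotspot])
        except Exception as exc:
            raise RuntimeError(
                f"stage=call sample={row.sample_id}: {exc}") from exc
        bundle.sample_results[row.sample_id] = res
        write_vcf(res.call, panel, out_dir / f"{row.sample_id}.vcf")
        _sample_report_frame(res.call).to_csv(
            out_dir / f"{row.sample_id}.tsv", sep="\t", index=False)

    # per-patient monitoring
    by_patient: dict[str, list[SampleSheetRow]] = {}
    for row in sheet:
        by_patient.setdefault(row.patient_id, []).append(row)
    strict = config.positivity_mode == "paper"
    ts_rows, ev_rows = [], []
    for pid, rows in by_patient.items():
        hid = rows[0].tracked_hotspot
        dated = []
        for row in rows:
            call = bundle.sample_results[row.sample_id].call
            result = next(r for r in call.hotspot_results
                          if r.hotspot_id == row.tracked_hotspot)
            dated.append((row.collection_date, result))
        series = build_time_series(pid, hid, dated, strict,
                                   config.confirm_window)
        bundle.time_series[pid] = series
        for s in series.samples:
            ts_rows.append({
                "patient_id": pid, "sample_id": s.sample_id,
                "date": s.date.isoformat(), "status": s.status.value,
                "mutant_count": s.mutant_count,
                "vaf": s.vaf if s.vaf is not None else "",
            })
        for e in series.events:
            ev_rows.append({
                "patient_id": pid, "event": e.type.value,
                "date": e.date.isoformat(),
                "supporting_samples": ",".join(e.supporting_samples),
            })
    pd.DataFrame(ts_rows).to_csv(out_dir / "time_series.tsv", sep="\t",
                                 index=False)
    pd.DataFrame(ev_rows, columns=["patient_id", "event", "date",
                                   "supporting_samples"]).to_csv(
        out_dir / "events.tsv", sep="\t", index=False)

    qc = pd.DataFrame(
        [{"sample_id": sid, **res.qc}
         for sid, res in bundle.sample_results.items()])
    qc.to_csv(out_dir / "qc_summary.tsv", sep="\t", index=False)
    return bundle
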