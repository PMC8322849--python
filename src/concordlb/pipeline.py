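"""End-to-end orchestration: config, fixed stage order, reports.

Stage order: assemble cohort → QC gate (WGA CTCs only) → germline
subtraction → compartment VAF thresholds → concordance retention → metrics
(shared-mutation tables, occurrence classes, resemblance, temporal classes,
CNV burden) → report files.  Every stage logs its input/output counts;
identical config and inputs give byte-identical TSV outputs.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import cnv as cnv_mod
from . import filtering, heterogeneity, qc as qc_mod, temporal
from .io import assemble_cohort, subtract_germline
from .model import Compartment, PatientBundle, Stage
from .qc import QC_PRESETS, read_qc_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_report"]


class RunConfig(BaseModel):
    """Validated pipeline configuration; defaults are the published
    pipeline parameters (CTC VAF >= 10%, ctDNA/tumor VAF >= 1%, 5-of-10
    Ct < 35 CTC quality gate, time points pooled for sharing)."""

    manifest: str
    vcf_dir: str
    cnv_table: Optional[str] = None
    qc_table: Optional[str] = None
    out_dir: str = "results"

    thresholds: dict[str, float] = Field(
        default_factory=lambda: {
            "ctc": 0.10,
            "ctdna": 0.01,
            "tumor_primary": 0.01,
            "tumor_met": 0.01,
        }
    )
    vaf_inclusive: bool = True
    qc_preset: Optional[str] = "lung_ct_5of10"
    missing_panel: str = "fail"
    retention_mode: str = "circulating_guard"
    stage_group_low: list[str] = Field(default_factory=lambda: ["II", "III"])
    stage_group_high: list[str] = Field(default_factory=lambda: ["IV"])
    alpha: float = 0.05
    seed: int = 0

    @field_validator("thresholds")
    @classmethod
    def _known_compartments(cls, v: dict[str, float]) -> dict[str, float]:
        for name, cutoff in v.items():
            Compartment(name)  # raises on unknown compartment
            if not 0.0 <= cutoff <= 1.0:
                raise ValueError(f"threshold for {name} must be in [0,1]")
        return v

    @field_validator("qc_preset")
    @classmethod
    def _known_preset(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in QC_PRESETS:
            raise ValueError(f"unknown QC preset {v!r}; choose from {sorted(QC_PRESETS)}")
        return v

    @field_validator("retention_mode")
    @classmethod
    def _known_mode(cls, v: str) -> str:
        filtering.RetentionMode(v)
        return v

    @model_validator(mode="after")
    def _stages_valid(self) -> "RunConfig":
        for group in (self.stage_group_low, self.stage_group_high):
            for s in group:
                Stage(s)
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def _stage_log(stage: str, message: str) -> None:
    logger.info("[%s] %s", stage, message)


def _nan_to_none(x: float) -> Optional[float]:
    return None if isinstance(x, float) and math.isnan(x) else x


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write result tables under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        cohort = assemble_cohort(config.manifest, config.vcf_dir, config.cnv_table)
    except Exception as exc:
        raise RuntimeError(f"stage 'assemble' failed: {exc}") from exc
    n_samples = sum(len(b.samples) for b in cohort)
    _stage_log("assemble", f"{len(cohort)} patients, {n_samples} non-germline samples")

    qc_report = None
    if config.qc_preset is not None and config.qc_table is not None:
        try:
            panels = read_qc_table(config.qc_table)
            cohort, qc_report = qc_mod.apply_qc(
                cohort, panels, QC_PRESETS[config.qc_preset], config.missing_panel
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'qc_gate' failed: {exc}") from exc
        _stage_log(
            "qc_gate",
            f"passed {sum(qc_report.passed.values())}/{sum(qc_report.isolated.values())} samples",
        )

    cohort = [subtract_germline(b) for b in cohort]
    _stage_log("germline", f"subtracted germline for {len(cohort)} patients")

    try:
        thresholds = {Compartment(k): v for k, v in config.thresholds.items()}
        cohort = [
            filtering.apply_vaf_thresholds(b, thresholds, config.vaf_inclusive)
            for b in cohort
        ]
    except Exception as exc:
        raise RuntimeError(f"stage 'vaf_thresholds' failed: {exc}") from exc
    _stage_log(
        "vaf_thresholds",
        f"{sum(len(s.variants) for b in cohort for s in b.samples)} calls survive",
    )

    retained_by_patient = {
        b.patient_id: filtering.retain_concordant(b, config.retention_mode)
        for b in cohort
    }
    _stage_log(
        "retention",
        f"{sum(len(v) for v in retained_by_patient.values())} retained keys",
    )

    # --- outputs ---------------------------------------------------------
    retained_rows = []
    provenance: dict[str, list[dict]] = {}
    for bundle in cohort:
        for rv in retained_by_patient[bundle.patient_id]:
            retained_rows.append(
                {
                    "patient_id": bundle.patient_id,
                    "chrom": rv.key.chrom,
                    "pos": rv.key.pos,
                    "ref": rv.key.ref,
                    "alt": rv.key.alt,
                    "gene": rv.gene,
                    "carriers": ";".join(f"{sid}:{vaf:.6g}" for sid, vaf in rv.carriers),
                    "evidence": ",".join(sorted(e.value for e in rv.evidence)),
                }
            )
            provenance.setdefault(bundle.patient_id, []).append(
                {
                    "key": str(rv.key),
                    "gene": rv.gene,
                    "carriers": {sid: vaf for sid, vaf in rv.carriers},
                    "evidence": sorted(e.value for e in rv.evidence),
                }
            )
    pd.DataFrame(
        retained_rows,
        columns=["patient_id", "chrom", "pos", "ref", "alt", "gene", "carriers", "evidence"],
    ).to_csv(out_dir / "retained_variants.tsv", sep="\t", index=False)
    with open(out_dir / "retained_variants.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)

    table_rows = []
    for bundle in cohort:
        snv = heterogeneity.shared_mutation_table(bundle, retained_by_patient[bundle.patient_id])
        cnv_tab = heterogeneity.shared_cnv_table(bundle)
        table_rows.append(
            {
                "patient_id": bundle.patient_id,
                "tumor_available": snv.tumor_available,
                "n_tumor_ctc": snv.n_tumor_ctc,
                "n_multi_ctc": snv.n_multi_ctc,
                "n_tumor_ctdna": snv.n_tumor_ctdna,
                "n_ctc_ctdna": snv.n_ctc_ctdna,
                "cnv_tumor_ctc": cnv_tab.n_tumor_ctc,
                "cnv_multi_ctc": cnv_tab.n_multi_ctc,
                "cnv_tumor_ctdna": cnv_tab.n_tumor_ctdna,
                "cnv_ctc_ctdna": cnv_tab.n_ctc_ctdna,
            }
        )
    pd.DataFrame(table_rows).to_csv(out_dir / "concordance_table.tsv", sep="\t", index=False)

    occ_rows = []
    for bundle in cohort:
        classes = heterogeneity.classify_occurrence(
            bundle, retained_by_patient[bundle.patient_id]
        )
        for key, occ in sorted(classes.items(), key=lambda kv: str(kv[0])):
            occ_rows.append(
                {"patient_id": bundle.patient_id, "key": str(key), "occurrence": occ.value}
            )
    pd.DataFrame(occ_rows, columns=["patient_id", "key", "occurrence"]).to_csv(
        out_dir / "occurrence_classes.tsv", sep="\t", index=False
    )

    fraction, per_ctc = heterogeneity.ctc_concordance_fraction(cohort, retained_by_patient)
    resemblance: dict[str, dict] = {}
    summaries: dict[str, dict] = {}
    for bundle in cohort:
        scores = heterogeneity.resemblance_scores(bundle, retained_by_patient[bundle.patient_id])
        resemblance[bundle.patient_id] = {
            sc.compartment.value: {
                "f_primary_only": _nan_to_none(sc.f_primary_only),
                "f_met_only": _nan_to_none(sc.f_met_only),
                "f_both": _nan_to_none(sc.f_both),
                "n_keys": sc.n_keys,
            }
            for sc in scores
        }
        summaries[bundle.patient_id] = {
            k: _nan_to_none(v)
            for k, v in heterogeneity.heterogeneity_summary(
                bundle, retained_by_patient[bundle.patient_id]
            ).items()
        }
    with open(out_dir / "heterogeneity.json", "w") as fh:
        json.dump(
            {
                "ctc_tumor_concordance_fraction": _nan_to_none(fraction),
                "per_ctc": per_ctc,
                "resemblance": resemblance,
                "summary": summaries,
            },
            fh,
            indent=1,
            sort_keys=True,
        )

    temporal_rows = []
    for bundle in cohort:
        if len(bundle.timepoints) < 2:
            continue
        matrix = temporal.presence_matrix(bundle, retained_by_patient[bundle.patient_id])
        for compartment in matrix.compartments:
            if len(matrix.observed.get(compartment, [])) < 2:
                continue
            for key, cls in classify_sorted(matrix, compartment):
                temporal_rows.append(
                    {
                        "patient_id": bundle.patient_id,
                        "compartment": compartment.value,
                        "key": _row_key_str(key),
                        "class": cls.kind.value,
                        "transition_t": cls.t if cls.t is not None else "",
                    }
                )
    pd.DataFrame(
        temporal_rows,
        columns=["patient_id", "compartment", "key", "class", "transition_t"],
    ).to_csv(out_dir / "temporal_classes.tsv", sep="\t", index=False)

    burden_rows = [
        {
            "patient_id": b.patient_id,
            "sample_id": s.sample_id,
            "compartment": s.compartment.value,
            "stage": s.stage.value,
            "cnv_count": cnv_mod.cnv_count(s),
        }
        for b in cohort
        for s in b.samples
    ]
    pd.DataFrame(
        burden_rows,
        columns=["patient_id", "sample_id", "compartment", "stage", "cnv_count"],
    ).to_csv(out_dir / "cnv_burden.tsv", sep="\t", index=False)

    grouping = (
        frozenset(Stage(s) for s in config.stage_group_low),
        frozenset(Stage(s) for s in config.stage_group_high),
    )
    comparisons = {}
    for compartment in (Compartment.TUMOR_PRIMARY, Compartment.TUMOR_MET, Compartment.CTC, Compartment.CTDNA):
        try:
            comparison = cnv_mod.compare_burden_by_stage(
                cohort, compartment, grouping, config.alpha
            )
        except ValueError as exc:
            comparisons[compartment.value] = {"error": str(exc)}
            continue
        comparisons[compartment.value] = comparison.as_dict()
    with open(out_dir / "burden_comparison.json", "w") as fh:
        json.dump(comparisons, fh, indent=1, sort_keys=True)

    if qc_report is not None:
        with open(out_dir / "qc_retention.json", "w") as fh:
            json.dump(qc_report.as_dict(), fh, indent=1, sort_keys=True)

    config.to_yaml(out_dir / "config_used.yaml")
    _stage_log("report", f"results written to {out_dir}")
    return out_dir


def _row_key_str(key) -> str:
    if isinstance(key, tuple) and len(key) == 3 and key[0] == "CNV":
        return f"CNV:{key[1]}:{key[2]}"
    return str(key)


def classify_sorted(matrix, compartment):
    classes = temporal.classify_temporal(matrix, compartment)
    return sorted(classes.items(), key=lambda kv: _row_key_str(kv[0]))


def render_report(results_dir: Union[str, Path]) -> Path:
    """Render a Markdown summary and a gene x sample alteration matrix.

    Cell codes: SNV, INDEL, AMP, DEL, joined with '+' when a sample carries
    several alteration types in one gene.
    """
    results_dir = Path(results_dir)
    retained_path = results_dir / "retained_variants.tsv"
    if not retained_path.exists():
        raise FileNotFoundError(f"no pipeline results at {results_dir}")
    retained = pd.read_csv(retained_path, sep="\t", dtype={"chrom": str})
    burden = pd.read_csv(results_dir / "cnv_burden.tsv", sep="\t")
    cnv_calls = None
    concordance = pd.read_csv(results_dir / "concordance_table.tsv", sep="\t")

    # gene x sample alteration codes
    codes: dict[tuple[str, str], set[str]] = {}
    for row in retained.itertuples(index=False):
        gene = row.gene if isinstance(row.gene, str) and row.gene else f"{row.chrom}:{row.pos}"
        kind = "SNV" if len(str(row.ref)) == 1 and len(str(row.alt)) == 1 else "INDEL"
        for carrier in str(row.carriers).split(";"):
            sample_id = carrier.rsplit(":", 1)[0]
            codes.setdefault((gene, sample_id), set()).add(kind)
    with open(results_dir / "config_used.yaml") as fh:
        cfg = yaml.safe_load(fh)
    cnv_path = cfg.get("cnv_table")
    if cnv_path and Path(cnv_path).exists():
        cnv_calls = pd.read_csv(cnv_path, sep="\t")
        sample_ids = set(burden["sample_id"])
        for row in cnv_calls.itertuples(index=False):
            if row.sample_id not in sample_ids:
                continue
            direction = "AMP" if float(row.copy_ratio) > 1.0 else "DEL"
            codes.setdefault((str(row.gene), str(row.sample_id)), set()).add(direction)

    genes = sorted({g for g, _ in codes})
    samples = sorted({s for _, s in codes})
    matrix = pd.DataFrame(
        [
            [("+".join(sorted(codes.get((g, s), ())))) for s in samples]
            for g in genes
        ],
        index=genes,
        columns=samples,
    )
    matrix.index.name = "gene"
    matrix.to_csv(results_dir / "alteration_matrix.tsv", sep="\t")

    lines = ["# Cohort alteration summary", ""]
    n_retained = len(retained)
    if n_retained == 0:
        lines.append("Zero retained alterations after filtering.")
    else:
        lines.append(
            f"{n_retained} retained variant calls across "
            f"{retained['patient_id'].nunique()} patients; alteration matrix spans "
            f"{len(genes)} genes x {len(samples)} samples."
        )
    lines += ["", "## Shared-mutation counts per patient", ""]
    lines.append(concordance.to_markdown(index=False))
    report_path = results_dir / "report.md"
    report_path.write_text("\n".join(lines) + "\n")
    return report_path
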