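"""Readers and writers for cohort inputs: VCF, CNV table, manifest.

Variant calls are consumed at the VCF level (one file per sample).  The
allele fraction is read from the per-sample FORMAT field ``AF`` with a
fallback to the INFO field ``AF``; depth from FORMAT/INFO ``DP`` (missing
depth is stored as 0 — all downstream filters operate on VAF).  Gene symbols
come from the INFO field ``GENE`` when present and are never computed.

The manifest is a TSV with header columns ``sample_id``, ``patient_id``,
``compartment`` (tumor_primary|tumor_met|ctc|ctdna|germline), ``timepoint``
(integer, 0 = pre-study tumor), ``stage`` (I|II|III|IV|NA) and ``wga`` (0|1).
The CNV table is a TSV with columns ``sample_id``, ``gene``, ``copy_ratio``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from .model import (
    CnvEvent,
    Compartment,
    PatientBundle,
    SampleProfile,
    Stage,
    Variant,
    VariantKey,
    chrom_sort_key,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["sample_id", "patient_id", "compartment", "timepoint", "stage", "wga"]

PathLike = Union[str, Path]


def _scalar(value) -> Optional[float]:
    """Collapse pysam's tuple-or-scalar field values to a single float."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
    if value is None:
        return None
    return float(value)


def _per_alt(value, n_alts: int, what: str, where: str) -> list[float]:
    """Expand a Number=A field to one value per alt allele."""
    if value is None:
        raise ValueError(f"missing {what} at {where}")
    if not isinstance(value, (tuple, list)):
        value = (value,)
    vals = [v for v in value if v is not None]
    if len(vals) == n_alts:
        return [float(v) for v in vals]
    if len(vals) == 1:
        return [float(vals[0])] * n_alts
    raise ValueError(
        f"{what} has {len(vals)} values for {n_alts} alt alleles at {where}"
    )


def read_sample_vcf(path: PathLike, sample_meta: Mapping) -> SampleProfile:
    """Read one sample's VCF into a :class:`SampleProfile`.

    ``sample_meta`` is a manifest row (mapping with the manifest columns).
    Multi-allelic records are split into one variant per alt allele; alleles
    are uppercased; positions are taken as-is (1-based).  A record without an
    allele-fraction field is a hard error naming the record.
    """
    profile = SampleProfile(
        sample_id=str(sample_meta["sample_id"]),
        patient_id=str(sample_meta["patient_id"]),
        compartment=Compartment(str(sample_meta["compartment"])),
        timepoint=int(sample_meta["timepoint"]),
        stage=Stage(str(sample_meta["stage"])),
        wga=bool(int(sample_meta["wga"])),
    )
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed or unreadable VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            where = f"{path.name}:{rec.chrom}:{rec.pos}"
            alts = rec.alts or ()
            n_alts = len(alts)
            if n_alts == 0:
                continue
            af = None
            dp = None
            if rec.samples:
                fmt = rec.samples[0]
                if "AF" in fmt and fmt.get("AF") is not None:
                    af = _per_alt(fmt.get("AF"), n_alts, "FORMAT/AF", where)
                if "DP" in fmt:
                    dp = _scalar(fmt.get("DP"))
            if af is None and "AF" in rec.info:
                af = _per_alt(rec.info.get("AF"), n_alts, "INFO/AF", where)
            if af is None:
                raise ValueError(f"no allele-fraction (AF) field at record {where}")
            if dp is None:
                dp = _scalar(rec.info.get("DP")) if "DP" in rec.info else None
            gene = rec.info.get("GENE", "") if "GENE" in rec.info else ""
            if isinstance(gene, tuple):
                gene = gene[0] if gene else ""
            for alt, vaf in zip(alts, af):
                profile.add_variant(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=str(alt).upper(),
                        vaf=vaf,
                        depth=int(dp) if dp is not None else 0,
                        gene=str(gene),
                    )
                )
    return profile


def write_sample_vcf(profile: SampleProfile, path: PathLike) -> None:
    """Write a profile's variants as an uncompressed single-sample VCF."""
    header = pysam.VariantHeader()
    contigs = sorted({v.chrom for v in profile.variants.values()}, key=chrom_sort_key)
    for contig in contigs:
        header.contigs.add(contig)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AF", "A", "Float", "Allele fraction of the alternate allele")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(profile.sample_id)
    ordered = sorted(
        profile.variants.values(), key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.ref, v.alt)
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), filter="PASS"
            )
            if v.gene:
                rec.info["GENE"] = v.gene
            rec.samples[profile.sample_id]["AF"] = (v.vaf,)
            rec.samples[profile.sample_id]["DP"] = v.depth
            out.write(rec)


def read_manifest(path: PathLike) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    return manifest


def read_cnv_table(path: PathLike) -> dict[str, frozenset[CnvEvent]]:
    """Read the per-sample CNV TSV into sample_id -> set of events."""
    table = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "gene", "copy_ratio"):
        if col not in table.columns:
            raise ValueError(f"CNV table {path} missing column {col}")
    events: dict[str, set[CnvEvent]] = {}
    for row in table.itertuples(index=False):
        events.setdefault(str(row.sample_id), set()).add(
            CnvEvent(gene=str(row.gene), copy_ratio=float(row.copy_ratio))
        )
    return {sid: frozenset(evts) for sid, evts in events.items()}


def assemble_cohort(
    manifest_path: PathLike,
    vcf_dir: PathLike,
    cnv_path: Optional[PathLike] = None,
) -> list[PatientBundle]:
    """Load the cohort: manifest rows joined to per-sample VCFs and CNV calls.

    Bundles are ordered by patient_id, samples by sample_id.  A manifest
    sample without a VCF is a hard error; a VCF without a manifest row is
    skipped with a warning.
    """
    manifest = read_manifest(manifest_path)
    vcf_dir = Path(vcf_dir)
    if manifest["sample_id"].duplicated().any():
        dupes = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in manifest: {dupes}")
    cnv_by_sample = read_cnv_table(cnv_path) if cnv_path is not None else {}

    listed = set(manifest["sample_id"])
    for vcf_path in sorted(vcf_dir.glob("*.vcf")):
        if vcf_path.stem not in listed:
            logger.warning("VCF %s has no manifest row; skipped", vcf_path.name)

    profiles: list[SampleProfile] = []
    for row in manifest.to_dict("records"):
        vcf_path = vcf_dir / f"{row['sample_id']}.vcf"
        if not vcf_path.exists():
            raise FileNotFoundError(
                f"manifest sample {row['sample_id']} has no VCF at {vcf_path}"
            )
        profile = read_sample_vcf(vcf_path, row)
        if profile.sample_id in cnv_by_sample:
            profile.cnvs = cnv_by_sample[profile.sample_id]
        profiles.append(profile)

    bundles: list[PatientBundle] = []
    for patient_id in sorted({p.patient_id for p in profiles}):
        patient_profiles = sorted(
            (p for p in profiles if p.patient_id == patient_id),
            key=lambda p: p.sample_id,
        )
        germline = [p for p in patient_profiles if p.compartment is Compartment.GERMLINE]
        if len(germline) > 1:
            raise ValueError(
                f"patient {patient_id} has {len(germline)} germline samples; at most one allowed"
            )
        bundles.append(
            PatientBundle(
                patient_id=patient_id,
                samples=[p for p in patient_profiles if p.compartment is not Compartment.GERMLINE],
                germline=germline[0] if germline else None,
            )
        )
    return bundles


def subtract_germline(bundle: PatientBundle) -> PatientBundle:
    """Remove every variant key present in the germline control from all samples.

    The buffy-coat control is treated as pure germline: a key is subtracted
    on any germline call regardless of its germline VAF.  Without a germline
    sample the bundle is returned unchanged (warning logged).
    """
    if bundle.germline is None:
        logger.warning(
            "patient %s has no germline sample; germline subtraction skipped",
            bundle.patient_id,
        )
        return bundle
    germline_keys = bundle.germline.keys
    samples = [
        s.copy_with_variants({k: v for k, v in s.variants.items() if k not in germline_keys})
        for s in bundle.samples
    ]
    return bundle.copy_with_samples(samples)
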