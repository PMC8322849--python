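"""Clonal-shedding cohort simulator.

Generates synthetic patients with a known clonal structure and emits exactly
the inputs the readers consume (per-sample VCFs, manifest, CNV and QC
tables) plus the ground truth, so every downstream stage can be tested
against labels.

The generative model, per patient:

* A clone tree: trunk mutations carried by every clone; primary-tumor clones
  each with private mutations; metastatic clones descending from the
  dominant primary clone with additional met-private mutations.
* Bulk tumors: for each mutation, expected VAF = purity x (sum of carrying
  clone fractions) / 2 under an all-heterozygous model, observed through
  binomial read sampling at the given depth.
* Single CTCs: one clone's genotype at VAF 0.5, degraded by allelic dropout
  (each true variant lost independently with probability ``ado_rate``) and
  contaminated with WGA false-positive artifacts — Poisson-many calls at
  reserved decoy positions with VAF uniform below 10%, mirroring the
  amplification-error spectrum that motivates the 10% CTC VAF cutoff.
* ctDNA: a shedding-weighted clone mixture concentrated on the dominant
  clone, plus a sub-1% VAF sequencing-error background.
* QC panels: each region of a k-of-n integrity panel reads positive with
  probability equal to the cell's genome integrity (Ct ~ 25 + noise when
  positive, >= 40 otherwise).

Artifact and background calls are drawn from a decoy key space disjoint
from all true somatic and germline keys, so truth labels are unambiguous.
Every operation is a pure function of its arguments and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .io import write_sample_vcf
from .model import (
    CnvEvent,
    Compartment,
    PatientBundle,
    SampleProfile,
    Stage,
    Variant,
    VariantKey,
)
from .qc import QcMode, QcPanelResult, write_qc_table

__all__ = [
    "NoiseModel",
    "Clone",
    "ClonalTruth",
    "simulate_clonal_structure",
    "sample_bulk_tumor",
    "sample_single_ctc",
    "sample_ctdna",
    "simulate_qc_panel",
    "simulate_patient",
    "simulate_cohort",
    "write_cohort",
    "read_truth",
    "CNV_STAGE_MEANS",
]

#: Targeted-panel gene set (symbol, chromosome) used for simulated mutations.
GENE_PANEL: tuple[tuple[str, str], ...] = (
    ("EGFR", "chr7"), ("TP53", "chr17"), ("KRAS", "chr12"), ("PIK3CA", "chr3"),
    ("ALK", "chr2"), ("BRAF", "chr7"), ("JAK2", "chr9"), ("ATM", "chr11"),
    ("BRCA1", "chr17"), ("BRCA2", "chr13"), ("ERBB2", "chr17"), ("MET", "chr7"),
    ("RB1", "chr13"), ("PTEN", "chr10"), ("NOTCH1", "chr9"), ("FGFR1", "chr8"),
    ("KIT", "chr4"), ("SMAD4", "chr18"), ("STK11", "chr19"), ("CDKN2A", "chr9"),
    ("APC", "chr5"), ("NF1", "chr17"), ("ESR1", "chr6"), ("GATA3", "chr10"),
    ("AKT1", "chr14"), ("CDH1", "chr16"), ("MAP2K1", "chr15"), ("NRAS", "chr1"),
    ("ROS1", "chr6"), ("RET", "chr10"),
)

_BASES = "ACGT"

# Disjoint position ranges keep somatic, germline and decoy keys unambiguous.
_SOMATIC_POS = (10_000, 1_000_000)
_GERMLINE_POS = (5_000_000, 5_100_000)
_DECOY_POS = (10_000_000, 10_100_000)

#: Mean per-sample CNV event count by disease stage (Poisson); higher stage,
#: heavier burden, so stage-comparison tests have signal to recover.
CNV_STAGE_MEANS: dict[Stage, float] = {
    Stage.I: 2.0,
    Stage.II: 3.0,
    Stage.III: 6.0,
    Stage.IV: 10.0,
    Stage.UNKNOWN: 4.0,
}


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise parameters for amplified cells and plasma DNA.

    ``ado_rate``: per-variant allelic dropout probability in a single cell.
    ``wga_fp_count_mean``: mean number of WGA artifact calls per cell
    (Poisson).  Artifact VAFs are uniform on
    (``wga_fp_vaf_low``, ``wga_fp_vaf_high``), below the 10% cutoff by
    default.  ``ctdna_error_rate``: per-decoy-site background call
    probability in plasma; background VAFs are at most
    ``ctdna_error_vaf_high`` (1% by default).  ``depth_mean`` is the nominal
    read depth recorded for single-cell calls.
    """

    ado_rate: float = 0.2
    wga_fp_count_mean: float = 5.0
    wga_fp_vaf_low: float = 0.01
    wga_fp_vaf_high: float = 0.09
    ctdna_error_rate: float = 0.01
    ctdna_error_vaf_high: float = 0.01
    depth_mean: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.ado_rate <= 1.0:
            raise ValueError(f"ado_rate must be in [0,1], got {self.ado_rate}")
        if self.wga_fp_count_mean < 0 or self.ctdna_error_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.wga_fp_vaf_low <= self.wga_fp_vaf_high <= 1.0:
            raise ValueError("need 0 <= wga_fp_vaf_low <= wga_fp_vaf_high <= 1")
        if not 0.0 < self.ctdna_error_vaf_high <= 1.0:
            raise ValueError("ctdna_error_vaf_high must be in (0,1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


@dataclass(frozen=True)
class Clone:
    clone_id: str
    parent_id: Optional[str]
    site: str  # "primary" or "met"
    mutations: frozenset[VariantKey]


@dataclass
class ClonalTruth:
    """Ground-truth clonal structure of one simulated patient."""

    clones: list[Clone]
    site_fractions: dict[str, dict[str, float]]
    shedding_weights: dict[str, dict[str, float]]
    trunk: frozenset[VariantKey]
    gene_map: dict[VariantKey, str] = field(default_factory=dict)
    decoy_panel: tuple[VariantKey, ...] = ()

    def __post_init__(self) -> None:
        by_id = {c.clone_id: c for c in self.clones}
        if len(by_id) != len(self.clones):
            raise ValueError("duplicate clone ids")
        for clone in self.clones:
            if not self.trunk <= clone.mutations:
                raise ValueError(f"clone {clone.clone_id} missing trunk mutations")
            if clone.parent_id is not None:
                parent = by_id.get(clone.parent_id)
                if parent is None:
                    raise ValueError(f"clone {clone.clone_id} has unknown parent")
                if not parent.mutations <= clone.mutations:
                    raise ValueError(
                        f"clone {clone.clone_id} does not inherit parent mutations"
                    )
        for site, fracs in self.site_fractions.items():
            if any(f < 0 for f in fracs.values()):
                raise ValueError(f"negative clone fraction at site {site}")
            if sum(fracs.values()) > 1.0 + 1e-9:
                raise ValueError(f"clone fractions at site {site} sum above 1")
            for cid in fracs:
                if cid not in by_id:
                    raise ValueError(f"fraction for unknown clone {cid}")
        for comp, weights in self.shedding_weights.items():
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"negative shedding weight for {comp}")

    def clone(self, clone_id: str) -> Clone:
        for c in self.clones:
            if c.clone_id == clone_id:
                return c
        raise KeyError(f"unknown clone {clone_id}")

    @property
    def all_mutations(self) -> frozenset[VariantKey]:
        out: set[VariantKey] = set()
        for c in self.clones:
            out |= c.mutations
        return frozenset(out)

    def private_mutations(self, clone_id: str) -> frozenset[VariantKey]:
        """Mutations carried by this clone and no other clone."""
        others: set[VariantKey] = set()
        for c in self.clones:
            if c.clone_id != clone_id:
                others |= c.mutations
        return self.clone(clone_id).mutations - others

    def carrying_fraction(self, site: str, key: VariantKey) -> float:
        fracs = self.site_fractions.get(site, {})
        by_id = {c.clone_id: c for c in self.clones}
        return sum(f for cid, f in fracs.items() if key in by_id[cid].mutations)


def _draw_keys(
    rng: np.random.Generator,
    n: int,
    pos_range: tuple[int, int],
    used_positions: set[int],
) -> tuple[list[VariantKey], dict[VariantKey, str]]:
    """Draw n novel SNV keys on panel genes with globally unique positions."""
    keys: list[VariantKey] = []
    genes: dict[VariantKey, str] = {}
    lo, hi = pos_range
    while len(keys) < n:
        pos = int(rng.integers(lo, hi))
        if pos in used_positions:
            continue
        used_positions.add(pos)
        gene, chrom = GENE_PANEL[int(rng.integers(0, len(GENE_PANEL)))]
        ref = _BASES[int(rng.integers(0, 4))]
        alt = _BASES[int(rng.integers(0, 4))]
        while alt == ref:
            alt = _BASES[int(rng.integers(0, 4))]
        key = VariantKey(chrom, pos, ref, alt)
        keys.append(key)
        genes[key] = gene
    return keys, genes


def simulate_clonal_structure(
    n_trunk: int,
    n_private_per_clone: int,
    n_clones_primary: int,
    n_clones_met: int,
    seed: int,
    n_decoy: int = 200,
) -> ClonalTruth:
    """Build a clone tree with trunk, primary-private and met-private mutations.

    Primary clones are siblings carrying trunk plus their own private
    mutations; metastatic clones descend from the dominant primary clone and
    add met-private mutations absent from every primary clone.  Site
    fractions are Dirichlet-distributed with the first clone dominant;
    default shedding weights put CTCs and ctDNA on the metastatic clones
    (ctDNA concentrated 90% on the dominant one).  Deterministic per seed.
    """
    if n_trunk < 0 or n_private_per_clone < 0 or n_clones_primary < 0 or n_clones_met < 0:
        raise ValueError("counts must be >= 0")
    if n_clones_primary + n_clones_met == 0:
        raise ValueError("at least one clone required")
    rng = np.random.default_rng(seed)
    used: set[int] = set()
    trunk_keys, gene_map = _draw_keys(rng, n_trunk, _SOMATIC_POS, used)
    trunk = frozenset(trunk_keys)

    clones: list[Clone] = []
    for i in range(n_clones_primary):
        priv, genes = _draw_keys(rng, n_private_per_clone, _SOMATIC_POS, used)
        gene_map.update(genes)
        clones.append(
            Clone(f"P{i + 1}", parent_id=None, site="primary", mutations=trunk | set(priv))
        )
    met_parent = clones[0] if clones else None
    base = met_parent.mutations if met_parent is not None else trunk
    for i in range(n_clones_met):
        priv, genes = _draw_keys(rng, n_private_per_clone, _SOMATIC_POS, used)
        gene_map.update(genes)
        clones.append(
            Clone(
                f"M{i + 1}",
                parent_id=met_parent.clone_id if met_parent else None,
                site="met",
                mutations=base | set(priv),
            )
        )

    def _fractions(ids: Sequence[str]) -> dict[str, float]:
        if not ids:
            return {}
        raw = np.sort(rng.dirichlet(np.full(len(ids), 2.0)))[::-1]
        return {cid: float(f) for cid, f in zip(ids, raw)}

    primary_ids = [c.clone_id for c in clones if c.site == "primary"]
    met_ids = [c.clone_id for c in clones if c.site == "met"]
    site_fractions = {"primary": _fractions(primary_ids), "met": _fractions(met_ids)}

    shed_ids = met_ids if met_ids else primary_ids
    ctc_weights = {cid: 1.0 / len(shed_ids) for cid in shed_ids}
    dominant = shed_ids[0]
    if len(shed_ids) == 1:
        ctdna_weights = {dominant: 1.0}
    else:
        rest = 0.1 / (len(shed_ids) - 1)
        ctdna_weights = {cid: (0.9 if cid == dominant else rest) for cid in shed_ids}

    decoys, decoy_genes = _draw_keys(rng, n_decoy, _DECOY_POS, used)
    gene_map.update(decoy_genes)
    return ClonalTruth(
        clones=clones,
        site_fractions=site_fractions,
        shedding_weights={"ctc": ctc_weights, "ctdna": ctdna_weights},
        trunk=trunk,
        gene_map=gene_map,
        decoy_panel=tuple(decoys),
    )


def sample_bulk_tumor(
    truth: ClonalTruth,
    site: str,
    purity: float,
    depth: int,
    seed: int,
    *,
    sample_id: str = "TUMOR",
    patient_id: str = "P0",
    timepoint: int = 0,
    stage: Stage = Stage.UNKNOWN,
) -> SampleProfile:
    """Draw a bulk tumor profile: binomial reads around purity-scaled clone VAFs.

    Expected VAF of a mutation is purity x (sum of carrying-clone fractions)
    / 2 under the all-heterozygous model; calls with zero observed alternate
    reads are dropped.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0,1], got {purity}")
    fracs = truth.site_fractions.get(site) or {}
    if not fracs:
        raise ValueError(f"site {site!r} has no clone fractions")
    rng = np.random.default_rng(seed)
    compartment = Compartment.TUMOR_PRIMARY if site == "primary" else Compartment.TUMOR_MET
    profile = SampleProfile(
        sample_id=sample_id,
        patient_id=patient_id,
        compartment=compartment,
        timepoint=timepoint,
        stage=stage,
    )
    by_id = {c.clone_id: c for c in truth.clones}
    keys = sorted(
        {k for cid in fracs for k in by_id[cid].mutations}, key=lambda k: (k.chrom, k.pos)
    )
    for key in keys:
        expected = purity * truth.carrying_fraction(site, key) / 2.0
        reads = int(rng.binomial(depth, expected))
        if reads == 0:
            continue
        profile.add_variant(
            Variant(
                chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                vaf=reads / depth, depth=depth, gene=truth.gene_map.get(key, ""),
            )
        )
    return profile


def sample_single_ctc(
    truth: ClonalTruth,
    clone_id: str,
    noise: NoiseModel,
    seed: int,
    *,
    sample_id: str = "CTC",
    patient_id: str = "P0",
    timepoint: int = 1,
    stage: Stage = Stage.UNKNOWN,
) -> SampleProfile:
    """Draw one WGA-amplified single CTC from the given clone.

    True heterozygous variants appear at VAF 0.5 and drop out independently
    with probability ``ado_rate``; Poisson-many WGA artifacts are added at
    decoy keys with VAF uniform on (wga_fp_vaf_low, wga_fp_vaf_high).
    """
    clone = truth.clone(clone_id)
    rng = np.random.default_rng(seed)
    profile = SampleProfile(
        sample_id=sample_id,
        patient_id=patient_id,
        compartment=Compartment.CTC,
        timepoint=timepoint,
        stage=stage,
        wga=True,
    )
    for key in sorted(clone.mutations, key=lambda k: (k.chrom, k.pos)):
        if rng.random() < noise.ado_rate:
            continue
        profile.add_variant(
            Variant(
                chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                vaf=0.5, depth=noise.depth_mean, gene=truth.gene_map.get(key, ""),
            )
        )
    n_fp = int(rng.poisson(noise.wga_fp_count_mean))
    n_fp = min(n_fp, len(truth.decoy_panel))
    if n_fp:
        picks = rng.choice(len(truth.decoy_panel), size=n_fp, replace=False)
        for idx in sorted(int(i) for i in picks):
            key = truth.decoy_panel[idx]
            vaf = float(rng.uniform(noise.wga_fp_vaf_low, noise.wga_fp_vaf_high))
            profile.add_variant(
                Variant(
                    chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                    vaf=vaf, depth=noise.depth_mean, gene=truth.gene_map.get(key, ""),
                )
            )
    return profile


def sample_ctdna(
    truth: ClonalTruth,
    tumor_fraction: float,
    noise: NoiseModel,
    depth: int,
    seed: int,
    *,
    sample_id: str = "CTDNA",
    patient_id: str = "P0",
    timepoint: int = 1,
    stage: Stage = Stage.UNKNOWN,
    weights: Optional[Mapping[str, float]] = None,
) -> SampleProfile:
    """Draw a plasma ctDNA profile from the shedding-weighted clone mixture.

    Expected VAF of a mutation is tumor_fraction x (weight-renormalized
    carrying fraction) / 2; a sub-1% VAF background of Poisson-many
    sequencing-error calls is added at decoy keys.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError(f"tumor_fraction must be in [0,1], got {tumor_fraction}")
    raw = dict(weights) if weights is not None else truth.shedding_weights.get("ctdna", {})
    total = sum(raw.values())
    if not raw or total <= 0:
        raise ValueError("ctDNA shedding weights are empty")
    norm = {cid: w / total for cid, w in raw.items()}
    rng = np.random.default_rng(seed)
    profile = SampleProfile(
        sample_id=sample_id,
        patient_id=patient_id,
        compartment=Compartment.CTDNA,
        timepoint=timepoint,
        stage=stage,
    )
    by_id = {c.clone_id: c for c in truth.clones}
    keys = sorted(
        {k for cid in norm for k in by_id[cid].mutations}, key=lambda k: (k.chrom, k.pos)
    )
    for key in keys:
        carrying = sum(w for cid, w in norm.items() if key in by_id[cid].mutations)
        expected = tumor_fraction * carrying / 2.0
        reads = int(rng.binomial(depth, expected))
        if reads == 0:
            continue
        profile.add_variant(
            Variant(
                chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                vaf=reads / depth, depth=depth, gene=truth.gene_map.get(key, ""),
            )
        )
    n_bg = int(rng.poisson(noise.ctdna_error_rate * len(truth.decoy_panel)))
    n_bg = min(n_bg, len(truth.decoy_panel))
    if n_bg:
        picks = rng.choice(len(truth.decoy_panel), size=n_bg, replace=False)
        for idx in sorted(int(i) for i in picks):
            key = truth.decoy_panel[idx]
            if key in profile.variants:
                continue
            vaf = float(rng.uniform(1e-4, noise.ctdna_error_vaf_high))
            profile.add_variant(
                Variant(
                    chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                    vaf=vaf, depth=depth, gene=truth.gene_map.get(key, ""),
                )
            )
    return profile


def simulate_qc_panel(
    sample_id: str,
    integrity: float,
    n_regions: int,
    mode: Union[QcMode, str],
    seed: int,
) -> QcPanelResult:
    """Simulate a k-of-n integrity panel for one amplified cell.

    Each region reads positive independently with probability ``integrity``;
    in CT mode a positive region gets Ct around 25 (always < 35) and a
    negative one Ct >= 40.
    """
    if not 0.0 <= integrity <= 1.0:
        raise ValueError(f"integrity must be in [0,1], got {integrity}")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    mode = QcMode(mode)
    rng = np.random.default_rng(seed)
    values: list[tuple[str, float]] = []
    for i in range(n_regions):
        positive = rng.random() < integrity
        if mode is QcMode.CT:
            value = (
                float(np.clip(25.0 + rng.normal(0.0, 2.0), 15.0, 34.5))
                if positive
                else float(40.0 + rng.uniform(0.0, 5.0))
            )
        else:
            value = 1.0 if positive else 0.0
        values.append((f"R{i + 1}", value))
    return QcPanelResult(sample_id=sample_id, mode=mode, values=tuple(values))


def _simulate_cnvs(
    rng: np.random.Generator, stage: Stage, cnv_stage_means: Mapping[Stage, float]
) -> frozenset[CnvEvent]:
    n = int(rng.poisson(cnv_stage_means[stage]))
    n = min(n, len(GENE_PANEL))
    if n == 0:
        return frozenset()
    picks = rng.choice(len(GENE_PANEL), size=n, replace=False)
    events = set()
    for idx in sorted(int(i) for i in picks):
        gene, _ = GENE_PANEL[idx]
        if rng.random() < 0.5:
            ratio = float(rng.uniform(1.5, 4.0))
        else:
            ratio = float(rng.uniform(0.25, 0.7))
        events.add(CnvEvent(gene=gene, copy_ratio=ratio))
    return frozenset(events)


def simulate_patient(
    patient_id: str,
    seed: int,
    *,
    preset: str = "met_shedding",
    n_trunk: int = 8,
    n_private_per_clone: int = 4,
    n_clones_primary: int = 2,
    n_clones_met: int = 2,
    n_ctc_per_timepoint: int = 3,
    n_ctdna_per_timepoint: int = 1,
    n_timepoints: int = 2,
    stage: Stage = Stage.III,
    noise: Optional[NoiseModel] = None,
    tumor_purity: float = 0.7,
    tumor_depth: int = 800,
    ctdna_tumor_fraction: float = 0.2,
    ctdna_depth: int = 5000,
    n_germline_variants: int = 5,
    emergent_clone_timepoint: Optional[int] = None,
    qc_mode: Union[QcMode, str] = QcMode.CT,
    qc_n_regions: int = 10,
    qc_integrity_range: tuple[float, float] = (0.3, 1.0),
    cnv_stage_means: Mapping[Stage, float] = CNV_STAGE_MEANS,
) -> tuple[PatientBundle, ClonalTruth, dict[str, QcPanelResult]]:
    """Simulate one patient: germline + T0 tumors + serial CTCs and ctDNA.

    Presets: ``met_shedding`` (default) sheds CTCs/ctDNA from the metastatic
    clones; ``homogeneous`` makes the metastatic site a copy of the primary
    clone mixture and sheds from the primary clones.  With
    ``emergent_clone_timepoint`` = t, the last metastatic clone is absent
    from both tumor sites and from circulation before t, and from t onward
    is shed by at least two CTCs per time point and by ctDNA — a clone that
    newly appears in the blood mid-study.
    """
    if preset not in ("met_shedding", "homogeneous"):
        raise ValueError(f"unknown preset {preset!r}")
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)

    def subseed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    truth = simulate_clonal_structure(
        n_trunk, n_private_per_clone, n_clones_primary, n_clones_met, subseed()
    )
    met_ids = [c.clone_id for c in truth.clones if c.site == "met"]
    primary_ids = [c.clone_id for c in truth.clones if c.site == "primary"]

    if preset == "homogeneous" and primary_ids:
        truth.site_fractions["met"] = dict(truth.site_fractions["primary"])
        truth.shedding_weights["ctc"] = {
            cid: 1.0 / len(primary_ids) for cid in primary_ids
        }
        dominant = primary_ids[0]
        if len(primary_ids) == 1:
            truth.shedding_weights["ctdna"] = {dominant: 1.0}
        else:
            rest = 0.1 / (len(primary_ids) - 1)
            truth.shedding_weights["ctdna"] = {
                cid: (0.9 if cid == dominant else rest) for cid in primary_ids
            }

    emergent_id: Optional[str] = None
    if emergent_clone_timepoint is not None:
        if not met_ids:
            raise ValueError("emergent clone requires at least one metastatic clone")
        if not 1 <= emergent_clone_timepoint <= n_timepoints:
            raise ValueError("emergent_clone_timepoint must lie within 1..n_timepoints")
        emergent_id = met_ids[-1]
        # The emergent clone is invisible to both tumor sites and to the
        # baseline shedding mixture; it only enters circulation at t.
        for site in ("primary", "met"):
            truth.site_fractions[site].pop(emergent_id, None)
        for comp in ("ctc", "ctdna"):
            truth.shedding_weights[comp].pop(emergent_id, None)

    samples: list[SampleProfile] = []

    germline = SampleProfile(
        sample_id=f"{patient_id}_GL",
        patient_id=patient_id,
        compartment=Compartment.GERMLINE,
        timepoint=0,
        stage=stage,
    )
    germ_rng = np.random.default_rng(subseed())
    used_positions = {k.pos for k in truth.all_mutations} | {
        k.pos for k in truth.decoy_panel
    }
    germ_keys, germ_genes = _draw_keys(
        germ_rng, n_germline_variants, _GERMLINE_POS, used_positions
    )
    truth.gene_map.update(germ_genes)
    for key in germ_keys:
        germline.add_variant(
            Variant(
                chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                vaf=float(np.clip(germ_rng.normal(0.5, 0.02), 0.3, 0.7)),
                depth=tumor_depth, gene=truth.gene_map.get(key, ""),
            )
        )

    def add_germline_leakage(profile: SampleProfile, leak_rng: np.random.Generator) -> None:
        # Germline heterozygous SNPs appear in every compartment near VAF 0.5;
        # they survive the VAF filters and must be removed by subtraction.
        for key in germ_keys:
            if key in profile.variants:
                continue
            profile.add_variant(
                Variant(
                    chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                    vaf=float(np.clip(leak_rng.normal(0.5, 0.03), 0.3, 0.7)),
                    depth=profile.variants and next(iter(profile.variants.values())).depth or tumor_depth,
                    gene=truth.gene_map.get(key, ""),
                )
            )

    tumor_primary = sample_bulk_tumor(
        truth, "primary", tumor_purity, tumor_depth, subseed(),
        sample_id=f"{patient_id}_TP0", patient_id=patient_id, timepoint=0, stage=stage,
    )
    add_germline_leakage(tumor_primary, np.random.default_rng(subseed()))
    tumor_primary.cnvs = _simulate_cnvs(np.random.default_rng(subseed()), stage, cnv_stage_means)
    samples.append(tumor_primary)

    if truth.site_fractions.get("met"):
        tumor_met = sample_bulk_tumor(
            truth, "met", tumor_purity, tumor_depth, subseed(),
            sample_id=f"{patient_id}_TM0", patient_id=patient_id, timepoint=0, stage=stage,
        )
        add_germline_leakage(tumor_met, np.random.default_rng(subseed()))
        tumor_met.cnvs = _simulate_cnvs(np.random.default_rng(subseed()), stage, cnv_stage_means)
        samples.append(tumor_met)

    panels: dict[str, QcPanelResult] = {}
    for t in range(1, n_timepoints + 1):
        ctc_weights = dict(truth.shedding_weights["ctc"])
        ctdna_weights = dict(truth.shedding_weights["ctdna"])
        forced_emergent = 0
        if emergent_id is not None and t >= emergent_clone_timepoint:
            forced_emergent = min(2, n_ctc_per_timepoint)
            ctdna_weights[emergent_id] = 0.5 * (sum(ctdna_weights.values()) or 1.0)
        clone_ids = sorted(ctc_weights)
        probs = np.array([ctc_weights[c] for c in clone_ids], dtype=float)
        probs = probs / probs.sum()
        for i in range(n_ctc_per_timepoint):
            if i < forced_emergent:
                clone_id = emergent_id
            else:
                clone_id = clone_ids[
                    int(np.random.default_rng(subseed()).choice(len(clone_ids), p=probs))
                ]
            ctc = sample_single_ctc(
                truth, clone_id, noise, subseed(),
                sample_id=f"{patient_id}_CTC_T{t}_{i + 1}", patient_id=patient_id,
                timepoint=t, stage=stage,
            )
            add_germline_leakage(ctc, np.random.default_rng(subseed()))
            ctc.cnvs = _simulate_cnvs(np.random.default_rng(subseed()), stage, cnv_stage_means)
            samples.append(ctc)
            integrity = float(
                np.random.default_rng(subseed()).uniform(*qc_integrity_range)
            )
            panels[ctc.sample_id] = simulate_qc_panel(
                ctc.sample_id, integrity, qc_n_regions, qc_mode, subseed()
            )
        for i in range(n_ctdna_per_timepoint):
            ctdna = sample_ctdna(
                truth, ctdna_tumor_fraction, noise, ctdna_depth, subseed(),
                sample_id=f"{patient_id}_DNA_T{t}_{i + 1}", patient_id=patient_id,
                timepoint=t, stage=stage, weights=ctdna_weights,
            )
            add_germline_leakage(ctdna, np.random.default_rng(subseed()))
            ctdna.cnvs = _simulate_cnvs(np.random.default_rng(subseed()), stage, cnv_stage_means)
            samples.append(ctdna)

    bundle = PatientBundle(patient_id=patient_id, samples=samples, germline=germline)
    return bundle, truth, panels


def simulate_cohort(
    n_patients: int,
    seed: int,
    *,
    stages: Optional[Sequence[Stage]] = None,
    **patient_kwargs,
) -> tuple[list[PatientBundle], dict[str, ClonalTruth], dict[str, QcPanelResult]]:
    """Simulate a cohort of patients cycling through the given disease stages."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    stages = list(stages) if stages else [Stage.II, Stage.III, Stage.IV]
    rng = np.random.default_rng(seed)
    bundles: list[PatientBundle] = []
    truths: dict[str, ClonalTruth] = {}
    panels: dict[str, QcPanelResult] = {}
    for i in range(n_patients):
        patient_id = f"SIM{i + 1:03d}"
        bundle, truth, patient_panels = simulate_patient(
            patient_id,
            int(rng.integers(0, 2**31 - 1)),
            stage=stages[i % len(stages)],
            **patient_kwargs,
        )
        bundles.append(bundle)
        truths[patient_id] = truth
        panels.update(patient_panels)
    return bundles, truths, panels


def _truth_to_json(truth: ClonalTruth) -> dict:
    return {
        "clones": [
            {
                "clone_id": c.clone_id,
                "parent_id": c.parent_id,
                "site": c.site,
                "mutations": sorted(str(k) for k in c.mutations),
            }
            for c in truth.clones
        ],
        "site_fractions": truth.site_fractions,
        "shedding_weights": truth.shedding_weights,
        "trunk": sorted(str(k) for k in truth.trunk),
        "gene_map": {str(k): g for k, g in sorted(truth.gene_map.items())},
        "decoy_panel": [str(k) for k in truth.decoy_panel],
    }


def _truth_from_json(data: dict) -> ClonalTruth:
    return ClonalTruth(
        clones=[
            Clone(
                clone_id=c["clone_id"],
                parent_id=c.get("parent_id"),
                site=c["site"],
                mutations=frozenset(VariantKey.parse(k) for k in c["mutations"]),
            )
            for c in data["clones"]
        ],
        site_fractions={s: dict(f) for s, f in data["site_fractions"].items()},
        shedding_weights={s: dict(w) for s, w in data["shedding_weights"].items()},
        trunk=frozenset(VariantKey.parse(k) for k in data["trunk"]),
        gene_map={VariantKey.parse(k): g for k, g in data["gene_map"].items()},
        decoy_panel=tuple(VariantKey.parse(k) for k in data["decoy_panel"]),
    )


def write_cohort(
    bundles: Sequence[PatientBundle],
    truths: Mapping[str, ClonalTruth],
    qc_panels: Mapping[str, QcPanelResult],
    outdir: Union[str, Path],
    overwrite: bool = False,
) -> list[Path]:
    """Write the cohort to disk in the formats the readers consume.

    Emits one VCF per sample (germline included), ``manifest.tsv``,
    ``cnv.tsv``, ``qc.tsv`` and ``truth.json``.  Existing files are an error
    unless ``overwrite`` is set.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_samples: list[SampleProfile] = []
    for bundle in bundles:
        all_samples.extend(bundle.samples)
        if bundle.germline is not None:
            all_samples.append(bundle.germline)
    all_samples.sort(key=lambda s: s.sample_id)

    planned = [outdir / f"{s.sample_id}.vcf" for s in all_samples] + [
        outdir / name for name in ("manifest.tsv", "cnv.tsv", "qc.tsv", "truth.json")
    ]
    if not overwrite:
        existing = [p for p in planned if p.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite {existing[0]} (pass overwrite=True)"
            )

    written: list[Path] = []
    for sample in all_samples:
        path = outdir / f"{sample.sample_id}.vcf"
        write_sample_vcf(sample, path)
        written.append(path)

    manifest = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "compartment": s.compartment.value,
                "timepoint": s.timepoint,
                "stage": s.stage.value,
                "wga": int(s.wga),
            }
            for s in all_samples
        ]
    )
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    written.append(manifest_path)

    cnv_rows = [
        {"sample_id": s.sample_id, "gene": e.gene, "copy_ratio": e.copy_ratio}
        for s in all_samples
        for e in sorted(s.cnvs, key=lambda e: e.gene)
    ]
    cnv_path = outdir / "cnv.tsv"
    pd.DataFrame(cnv_rows, columns=["sample_id", "gene", "copy_ratio"]).to_csv(
        cnv_path, sep="\t", index=False
    )
    written.append(cnv_path)

    qc_path = outdir / "qc.tsv"
    write_qc_table(qc_panels, qc_path)
    written.append(qc_path)

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {pid: _truth_to_json(t) for pid, t in sorted(truths.items())},
            fh,
            indent=1,
        )
    written.append(truth_path)
    return written


def read_truth(path: Union[str, Path]) -> dict[str, ClonalTruth]:
    with open(path) as fh:
        data = json.load(fh)
    return {pid: _truth_from_json(t) for pid, t in data.items()}
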