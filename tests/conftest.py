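"""Shared builders for hand-constructed and randomized patient bundles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from concordlb.model import (
    CnvEvent,
    Compartment,
    PatientBundle,
    SampleProfile,
    Stage,
    Variant,
    VariantKey,
)

# compact key pool for hand-built fixtures: letters a..z at distinct positions
KEY_POOL = {
    letter: VariantKey("chr1", 1000 + i * 10, "A", "T")
    for i, letter in enumerate("abcdefghijklmnopqrstuvwxyz")
}


def make_variant(key: VariantKey, vaf: float = 0.5, depth: int = 100, gene: str = "") -> Variant:
    return Variant(
        chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
        vaf=vaf, depth=depth, gene=gene,
    )


def make_sample(
    sample_id: str,
    compartment: Compartment,
    keys,
    patient_id: str = "PT1",
    vaf: float = 0.5,
    timepoint: int = 0,
    stage: Stage = Stage.UNKNOWN,
    cnvs=(),
) -> SampleProfile:
    """Build a sample carrying the named KEY_POOL letters (or VariantKeys)."""
    if timepoint == 0 and compartment in (Compartment.CTC, Compartment.CTDNA):
        timepoint = 1
    profile = SampleProfile(
        sample_id=sample_id,
        patient_id=patient_id,
        compartment=compartment,
        timepoint=timepoint,
        stage=stage,
        wga=compartment is Compartment.CTC,
        cnvs=frozenset(cnvs),
    )
    for item in keys:
        if isinstance(item, tuple) and not isinstance(item, VariantKey):
            key, v = item
        else:
            key, v = item, vaf
        if isinstance(key, str):
            key = KEY_POOL[key]
        profile.add_variant(make_variant(key, vaf=v))
    return profile


def make_bundle(samples, germline=None, patient_id: str = "PT1") -> PatientBundle:
    return PatientBundle(patient_id=patient_id, samples=list(samples), germline=germline)


def random_bundle(rng: np.random.Generator, max_samples: int = 6, max_keys: int = 30) -> PatientBundle:
    """Random patient bundle for oracle/property tests."""
    n_keys = int(rng.integers(1, max_keys + 1))
    pool = [VariantKey("chr1", 1000 + i * 7, "A", "G") for i in range(n_keys)]
    n_samples = int(rng.integers(1, max_samples + 1))
    compartments = [
        Compartment.TUMOR_PRIMARY,
        Compartment.TUMOR_MET,
        Compartment.CTC,
        Compartment.CTDNA,
    ]
    samples = []
    for i in range(n_samples):
        comp = compartments[int(rng.integers(0, len(compartments)))]
        carried = [k for k in pool if rng.random() < 0.4]
        samples.append(
            make_sample(
                f"S{i}",
                comp,
                [(k, float(rng.uniform(0.01, 1.0))) for k in carried],
                timepoint=int(rng.integers(0, 3)) if comp not in (Compartment.CTC, Compartment.CTDNA) else int(rng.integers(1, 4)),
            )
        )
    return make_bundle(samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)
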