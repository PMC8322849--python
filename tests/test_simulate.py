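"""Clonal-shedding simulator: construction, expectations, determinism."""

from __future__ import annotations

import math

import numpy as np
import pytest

from concordlb.heterogeneity import jaccard
from concordlb.io import assemble_cohort
from concordlb.model import Compartment, VariantKey
from concordlb.qc import QcMode
from concordlb.simulate import (
    Clone,
    ClonalTruth,
    NoiseModel,
    read_truth,
    sample_bulk_tumor,
    sample_ctdna,
    sample_single_ctc,
    simulate_clonal_structure,
    simulate_cohort,
    simulate_patient,
    simulate_qc_panel,
    write_cohort,
)


def two_clone_truth(fracs={"A": 0.6, "B": 0.4}, weights={"A": 0.9, "B": 0.1}):
    """Hand-built truth: trunk key t0, A-private pa, B-private pb."""
    trunk = frozenset({VariantKey("chr1", 100, "A", "T")})
    pa = VariantKey("chr1", 200, "C", "G")
    pb = VariantKey("chr1", 300, "G", "A")
    decoys = tuple(VariantKey("chr2", 10_000_000 + i * 10, "A", "C") for i in range(50))
    return ClonalTruth(
        clones=[
            Clone("A", None, "primary", trunk | {pa}),
            Clone("B", None, "primary", trunk | {pb}),
        ],
        site_fractions={"primary": dict(fracs)},
        shedding_weights={"ctc": {"A": 0.5, "B": 0.5}, "ctdna": dict(weights)},
        trunk=trunk,
        decoy_panel=decoys,
    )


class TestClonalStructure:
    def test_trunk_in_every_clone(self):
        truth = simulate_clonal_structure(10, 5, 2, 1, seed=1)
        assert len(truth.trunk) == 10
        for clone in truth.clones:
            assert truth.trunk <= clone.mutations

    def test_private_sets_pairwise_disjoint(self):
        truth = simulate_clonal_structure(0, 5, 2, 1, seed=1)
        privates = [truth.private_mutations(c.clone_id) for c in truth.clones]
        for i, a in enumerate(privates):
            for b in privates[i + 1 :]:
                assert not (a & b)

    def test_met_private_absent_from_primary_clones(self):
        truth = simulate_clonal_structure(5, 4, 2, 2, seed=3)
        primary_union = frozenset().union(
            *(c.mutations for c in truth.clones if c.site == "primary")
        )
        for clone in truth.clones:
            if clone.site == "met":
                assert clone.mutations - primary_union

    def test_deterministic_under_seed(self):
        a = simulate_clonal_structure(8, 4, 2, 2, seed=11)
        b = simulate_clonal_structure(8, 4, 2, 2, seed=11)
        assert a.clones == b.clones
        assert a.site_fractions == b.site_fractions
        assert a.decoy_panel == b.decoy_panel

    def test_zero_clones_rejected(self):
        with pytest.raises(ValueError):
            simulate_clonal_structure(5, 5, 0, 0, seed=1)


class TestBulkTumor:
    def test_heterozygous_limit_pure_single_clone(self):
        truth = two_clone_truth(fracs={"A": 1.0, "B": 0.0})
        profile = sample_bulk_tumor(truth, "primary", purity=1.0, depth=10**6, seed=5)
        trunk_key = next(iter(truth.trunk))
        assert profile.variants[trunk_key].vaf == pytest.approx(0.5, abs=0.01)

    def test_zero_purity_empty(self):
        truth = two_clone_truth()
        profile = sample_bulk_tumor(truth, "primary", purity=0.0, depth=1000, seed=5)
        assert profile.variants == {}

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            sample_bulk_tumor(two_clone_truth(), "primary", 0.5, 0, seed=1)

    def test_subclonal_binomial_expectation(self):
        """Mean observed VAF of an A-private key (fractions 0.6/0.4,
        purity 0.8) over 1000 replicates within 3 SE of 0.24."""
        truth = two_clone_truth()
        pa = VariantKey("chr1", 200, "C", "G")
        depth = 500
        expected = 0.8 * 0.6 / 2  # 0.24
        vafs = []
        for i in range(1000):
            profile = sample_bulk_tumor(truth, "primary", 0.8, depth, seed=10_000 + i)
            if pa in profile.variants:
                vafs.append(profile.variants[pa].vaf)
        se = math.sqrt(expected * (1 - expected) / depth / len(vafs))
        assert np.mean(vafs) == pytest.approx(expected, abs=3 * se)


class TestSingleCtc:
    def test_noiseless_cell_equals_clone_genotype(self):
        truth = two_clone_truth()
        noise = NoiseModel(ado_rate=0.0, wga_fp_count_mean=0.0)
        profile = sample_single_ctc(truth, "A", noise, seed=2)
        assert profile.keys == truth.clone("A").mutations
        assert all(v.vaf == 0.5 for v in profile.variants.values())
        assert profile.wga is True

    def test_total_dropout_empty(self):
        truth = two_clone_truth()
        noise = NoiseModel(ado_rate=1.0, wga_fp_count_mean=0.0)
        profile = sample_single_ctc(truth, "A", noise, seed=2)
        assert profile.variants == {}

    def test_artifact_vaf_support_below_cutoff(self):
        """With bounds (0.01, 0.09), no artifact over 100 cells reaches 0.10."""
        truth = two_clone_truth()
        noise = NoiseModel(ado_rate=0.0, wga_fp_count_mean=5.0)
        decoys = set(truth.decoy_panel)
        for i in range(100):
            profile = sample_single_ctc(truth, "A", noise, seed=i)
            for key, v in profile.variants.items():
                if key in decoys:
                    assert 0.01 <= v.vaf < 0.10

    def test_unknown_clone_rejected(self):
        with pytest.raises(KeyError):
            sample_single_ctc(two_clone_truth(), "Z", NoiseModel(), seed=1)

    def test_ado_monotonicity(self):
        """Mean retained true-variant count decreases with ado_rate."""
        truth = simulate_clonal_structure(10, 5, 1, 0, seed=4)
        means = []
        for ado in (0.0, 0.3, 0.6, 0.9):
            noise = NoiseModel(ado_rate=ado, wga_fp_count_mean=0.0)
            counts = [
                len(sample_single_ctc(truth, "P1", noise, seed=s).variants)
                for s in range(50)
            ]
            means.append(np.mean(counts))
        assert means == sorted(means, reverse=True)
        assert means[0] > means[-1]


class TestCtdna:
    def test_single_source_subset_of_dominant_clone(self):
        truth = two_clone_truth(weights={"A": 1.0})
        noise = NoiseModel(ctdna_error_rate=0.0)
        profile = sample_ctdna(truth, 0.3, noise, depth=5000, seed=7)
        assert profile.keys <= truth.clone("A").mutations

    def test_zero_tumor_fraction_only_background(self):
        truth = two_clone_truth()
        noise = NoiseModel(ctdna_error_rate=0.2)
        profile = sample_ctdna(truth, 0.0, noise, depth=5000, seed=7)
        assert profile.keys <= set(truth.decoy_panel)
        assert all(v.vaf <= 0.01 for v in profile.variants.values())

    def test_mixture_expectation(self):
        """Mean VAF of an A-private key under weights {A:0.9,B:0.1},
        tumor fraction 0.2, over 500 replicates within 3 SE of 0.09."""
        truth = two_clone_truth(weights={"A": 0.9, "B": 0.1})
        pa = VariantKey("chr1", 200, "C", "G")
        noise = NoiseModel(ctdna_error_rate=0.0)
        depth = 10**4
        expected = 0.2 * 0.9 / 2  # 0.09
        vafs = []
        for i in range(500):
            profile = sample_ctdna(truth, 0.2, noise, depth, seed=50_000 + i)
            if pa in profile.variants:
                vafs.append(profile.variants[pa].vaf)
        se = math.sqrt(expected * (1 - expected) / depth / len(vafs))
        assert np.mean(vafs) == pytest.approx(expected, abs=3 * se)

    def test_ctdna_less_heterogeneous_than_ctcs(self):
        """Dominant-clone shedding: two ctDNA draws overlap more than two
        CTCs from distinct clones in >= 95% of 100 replicates."""
        wins = 0
        for rep in range(100):
            truth = simulate_clonal_structure(6, 4, 2, 2, seed=rep)
            noise = NoiseModel(ado_rate=0.1, wga_fp_count_mean=2.0, ctdna_error_rate=0.01)
            d1 = sample_ctdna(truth, 0.2, noise, 5000, seed=rep * 10 + 1)
            d2 = sample_ctdna(truth, 0.2, noise, 5000, seed=rep * 10 + 2)
            c1 = sample_single_ctc(truth, "M1", noise, seed=rep * 10 + 3)
            c2 = sample_single_ctc(truth, "M2", noise, seed=rep * 10 + 4)
            if jaccard(d1.keys, d2.keys) > jaccard(c1.keys, c2.keys):
                wins += 1
        assert wins >= 95


class TestQcPanelSim:
    def test_full_integrity_all_positive(self):
        panel = simulate_qc_panel("S", 1.0, 10, QcMode.CT, seed=1)
        assert all(ct < 35 for _, ct in panel.values)

    def test_zero_integrity_all_negative(self):
        panel = simulate_qc_panel("S", 0.0, 10, QcMode.CT, seed=1)
        assert all(ct >= 40 for _, ct in panel.values)

    def test_binomial_positive_count(self):
        """integrity 0.5, 10 regions, 2000 panels: mean positives ~ 5."""
        totals = [
            sum(v for _, v in simulate_qc_panel("S", 0.5, 10, QcMode.BINARY, seed=i).values)
            for i in range(2000)
        ]
        se = math.sqrt(10 * 0.25 / 2000)
        assert np.mean(totals) == pytest.approx(5.0, abs=3 * se)


class TestPatientAndCohort:
    def test_patient_determinism(self):
        a, ta, pa = simulate_patient("PT1", 99)
        b, tb, pb = simulate_patient("PT1", 99)
        assert {s.sample_id: s.keys for s in a.samples} == {
            s.sample_id: s.keys for s in b.samples
        }
        assert ta.clones == tb.clones
        assert {k: p.values for k, p in pa.items()} == {k: p.values for k, p in pb.items()}

    def test_patient_has_all_compartments(self):
        bundle, truth, panels = simulate_patient("PT1", 5)
        comps = {s.compartment for s in bundle.samples}
        assert comps == {
            Compartment.TUMOR_PRIMARY,
            Compartment.TUMOR_MET,
            Compartment.CTC,
            Compartment.CTDNA,
        }
        assert bundle.germline is not None
        assert len(panels) == len(bundle.ctc_samples)

    def test_germline_keys_leak_into_all_samples(self):
        bundle, _, _ = simulate_patient("PT1", 5)
        germ_keys = bundle.germline.keys
        assert germ_keys
        for sample in bundle.samples:
            assert germ_keys <= sample.keys

    def test_emergent_clone_absent_before_activation(self):
        bundle, truth, _ = simulate_patient(
            "PT1", 21, emergent_clone_timepoint=2, n_timepoints=2,
            noise=NoiseModel(ado_rate=0.0, wga_fp_count_mean=0.0, ctdna_error_rate=0.0),
        )
        emergent = truth.private_mutations("M2")
        assert emergent
        for sample in bundle.samples:
            if sample.timepoint < 2:
                assert not (sample.keys & emergent), sample.sample_id

    def test_write_cohort_round_trip(self, tmp_path):
        bundles, truths, panels = simulate_cohort(2, 17)
        write_cohort(bundles, truths, panels, tmp_path / "cohort")
        back = assemble_cohort(
            tmp_path / "cohort" / "manifest.tsv",
            tmp_path / "cohort",
            tmp_path / "cohort" / "cnv.tsv",
        )
        orig = {s.sample_id: s for b in bundles for s in b.samples + [b.germline]}
        re = {
            s.sample_id: s
            for b in back
            for s in b.samples + ([b.germline] if b.germline else [])
        }
        assert set(orig) == set(re)
        for sid, a in orig.items():
            b = re[sid]
            assert a.keys == b.keys
            for key in a.keys:
                assert b.variants[key].vaf == pytest.approx(a.variants[key].vaf, abs=1e-6)
            assert {e.key for e in a.cnvs} == {e.key for e in b.cnvs}
        truths_back = read_truth(tmp_path / "cohort" / "truth.json")
        for pid, truth in truths.items():
            assert truths_back[pid].clones == truth.clones
            assert truths_back[pid].trunk == truth.trunk

    def test_write_cohort_refuses_overwrite(self, tmp_path):
        bundles, truths, panels = simulate_cohort(1, 3)
        write_cohort(bundles, truths, panels, tmp_path / "c")
        with pytest.raises(FileExistsError):
            write_cohort(bundles, truths, panels, tmp_path / "c")
        write_cohort(bundles, truths, panels, tmp_path / "c", overwrite=True)
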