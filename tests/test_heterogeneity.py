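"""Shared-mutation tables, occurrence partition, resemblance, Jaccard summaries."""

from __future__ import annotations

import math

import numpy as np
import pytest

from concordlb.filtering import apply_vaf_thresholds, retain_concordant, DEFAULT_THRESHOLDS
from concordlb.heterogeneity import (
    OccurrenceClass,
    classify_occurrence,
    ctc_concordance_fraction,
    heterogeneity_summary,
    jaccard,
    resemblance_scores,
    shared_mutation_table,
)
from concordlb.io import subtract_germline
from concordlb.model import Compartment
from concordlb.simulate import NoiseModel, simulate_patient

from conftest import KEY_POOL, make_bundle, make_sample, random_bundle


def guard_retained(bundle):
    return retain_concordant(bundle, "circulating_guard")


class TestSharedMutationTable:
    def test_disjoint_profiles_all_zero(self):
        bundle = make_bundle(
            [
                make_sample("T", Compartment.TUMOR_PRIMARY, ["a"]),
                make_sample("C1", Compartment.CTC, ["b"]),
                make_sample("D", Compartment.CTDNA, ["c"]),
            ]
        )
        table = shared_mutation_table(bundle, guard_retained(bundle))
        assert (table.n_tumor_ctc, table.n_tumor_ctdna, table.n_multi_ctc, table.n_ctc_ctdna) == (0, 0, 0, 0)

    def test_constructed_bundle_counts(self):
        """tumor {a,b,c}, CTC1 {a,b,d}, CTC2 {b,d}, ctDNA {a}:
        tumor∩CTC={a,b}, tumor∩ctDNA={a}, >=2 CTCs={b,d}, CTC∩ctDNA={a}."""
        bundle = make_bundle(
            [
                make_sample("T", Compartment.TUMOR_PRIMARY, ["a", "b", "c"]),
                make_sample("C1", Compartment.CTC, ["a", "b", "d"]),
                make_sample("C2", Compartment.CTC, ["b", "d"]),
                make_sample("D", Compartment.CTDNA, ["a"]),
            ]
        )
        table = shared_mutation_table(bundle, guard_retained(bundle))
        assert table.n_tumor_ctc == 2
        assert table.n_tumor_ctdna == 1
        assert table.n_multi_ctc == 2
        assert table.n_ctc_ctdna == 1

    def test_no_tumor_patient_flagged(self):
        bundle = make_bundle(
            [
                make_sample("C1", Compartment.CTC, ["a"]),
                make_sample("C2", Compartment.CTC, ["a"]),
            ]
        )
        table = shared_mutation_table(bundle, guard_retained(bundle))
        assert table.tumor_available is False
        assert table.n_tumor_ctc == 0 and table.n_tumor_ctdna == 0

    def test_order_invariant(self, rng):
        for _ in range(20):
            bundle = random_bundle(rng)
            retained = guard_retained(bundle)
            forward = shared_mutation_table(bundle, retained)
            flipped = make_bundle(list(reversed(bundle.samples)))
            assert shared_mutation_table(flipped, guard_retained(flipped)) == forward


class TestClassifyOccurrence:
    def test_pattern_table(self):
        bundle = make_bundle(
            [
                make_sample("T", Compartment.TUMOR_PRIMARY, ["a"]),
                make_sample("C1", Compartment.CTC, ["b"]),
                make_sample("C2", Compartment.CTC, ["b", "c"]),
                make_sample("D", Compartment.CTDNA, ["c", "d"]),
            ]
        )
        classes = classify_occurrence(bundle, guard_retained(bundle))
        assert classes[KEY_POOL["a"]] is OccurrenceClass.TISSUE_ONLY
        assert classes[KEY_POOL["b"]] is OccurrenceClass.CTC_ONLY
        assert classes[KEY_POOL["c"]] is OccurrenceClass.CTC_CTDNA
        assert classes[KEY_POOL["d"]] is OccurrenceClass.CTDNA_ONLY

    def test_all_three(self):
        bundle = make_bundle(
            [
                make_sample("T", Compartment.TUMOR_MET, ["a"]),
                make_sample("C1", Compartment.CTC, ["a"]),
                make_sample("D", Compartment.CTDNA, ["a"]),
            ]
        )
        classes = classify_occurrence(bundle, guard_retained(bundle))
        assert classes[KEY_POOL["a"]] is OccurrenceClass.ALL_THREE

    def test_partition_over_random_bundles(self, rng):
        """Class sizes always sum to the retained count (true partition)."""
        for _ in range(50):
            bundle = random_bundle(rng)
            retained = guard_retained(bundle)
            classes = classify_occurrence(bundle, retained)
            assert len(classes) == len(retained)
            assert set(classes) == {rv.key for rv in retained}


class TestCtcConcordance:
    def _cohort(self):
        b1 = make_bundle(
            [
                make_sample("T1", Compartment.TUMOR_PRIMARY, ["a", "b"], patient_id="P1"),
                make_sample("C11", Compartment.CTC, ["a"], patient_id="P1"),
                make_sample("C12", Compartment.CTC, ["a"], patient_id="P1"),
                make_sample("C13", Compartment.CTC, ["b", "c"], patient_id="P1"),
                make_sample("C14", Compartment.CTC, ["c"], patient_id="P1"),
            ],
            patient_id="P1",
        )
        return [b1]

    def test_three_of_four_sharing(self):
        # C11, C12, C13 share a key with the tumor; C14 carries only 'c'
        # (multi-CTC retained but absent from tumor) -> 3/4
        cohort = self._cohort()
        retained = {"P1": guard_retained(cohort[0])}
        fraction, rows = ctc_concordance_fraction(cohort, retained)
        assert fraction == pytest.approx(0.75)
        assert len(rows) == 4

    def test_all_sharing_trunk(self):
        bundle = make_bundle(
            [
                make_sample("T", Compartment.TUMOR_PRIMARY, ["a"]),
                make_sample("C1", Compartment.CTC, ["a"]),
                make_sample("C2", Compartment.CTC, ["a"]),
            ]
        )
        fraction, _ = ctc_concordance_fraction([bundle], {"PT1": guard_retained(bundle)})
        assert fraction == 1.0

    def test_no_tumor_patients_excluded(self):
        bundle = make_bundle([make_sample("C1", Compartment.CTC, ["a"])])
        fraction, rows = ctc_concordance_fraction([bundle], {"PT1": []})
        assert math.isnan(fraction)
        assert rows == []

    def test_filtered_away_ctcs_score_zero(self):
        bundle = make_bundle(
            [
                make_sample("T", Compartment.TUMOR_PRIMARY, ["a"]),
                make_sample("C1", Compartment.CTC, ["b"]),
            ]
        )
        fraction, _ = ctc_concordance_fraction([bundle], {"PT1": guard_retained(bundle)})
        assert fraction == 0.0


class TestResemblance:
    def test_identical_tumors_all_both(self):
        bundle = make_bundle(
            [
                make_sample("TP", Compartment.TUMOR_PRIMARY, ["a", "b"]),
                make_sample("TM", Compartment.TUMOR_MET, ["a", "b"]),
                make_sample("C1", Compartment.CTC, ["a", "b"]),
                make_sample("C2", Compartment.CTC, ["a", "b"]),
            ]
        )
        ctc_score = resemblance_scores(bundle, guard_retained(bundle))[0]
        assert ctc_score.f_both == 1.0
        assert ctc_score.f_primary_only == 0.0 and ctc_score.f_met_only == 0.0

    def test_fraction_arithmetic(self):
        """CTC keys {m1,m2,p1}: met-only {m1,m2}, primary-only {p1} -> (1/3, 2/3, 0)."""
        bundle = make_bundle(
            [
                make_sample("TP", Compartment.TUMOR_PRIMARY, ["p"]),
                make_sample("TM", Compartment.TUMOR_MET, ["m", "n"]),
                make_sample("C1", Compartment.CTC, ["m", "n", "p"]),
                make_sample("C2", Compartment.CTC, ["m", "n", "p"]),
            ]
        )
        score = resemblance_scores(bundle, guard_retained(bundle))[0]
        assert score.compartment is Compartment.CTC
        assert score.f_primary_only == pytest.approx(1 / 3)
        assert score.f_met_only == pytest.approx(2 / 3)
        assert score.f_both == 0.0
        assert score.f_primary_only + score.f_met_only + score.f_both == pytest.approx(1.0)

    def test_missing_met_tumor_gives_nan(self, caplog):
        bundle = make_bundle(
            [
                make_sample("TP", Compartment.TUMOR_PRIMARY, ["a"]),
                make_sample("C1", Compartment.CTC, ["a"]),
            ]
        )
        with caplog.at_level("WARNING"):
            scores = resemblance_scores(bundle, guard_retained(bundle))
        assert all(math.isnan(s.f_both) for s in scores)

    def test_no_overlap_gives_nan(self):
        bundle = make_bundle(
            [
                make_sample("TP", Compartment.TUMOR_PRIMARY, ["a"]),
                make_sample("TM", Compartment.TUMOR_MET, ["a"]),
                make_sample("C1", Compartment.CTC, ["b"]),
                make_sample("C2", Compartment.CTC, ["b"]),
            ]
        )
        score = resemblance_scores(bundle, guard_retained(bundle))[0]
        assert math.isnan(score.f_both)
        assert score.n_keys == 0

    def test_met_shedding_recovered_over_seeds(self):
        """CTCs and ctDNA shed from metastatic clones resemble the metastatic
        tumor: f_met_only > f_primary_only in >= 95% of 100 seeds."""
        noise = NoiseModel(ado_rate=0.1)
        wins = 0
        for seed in range(100):
            bundle, _, _ = simulate_patient(
                f"PT{seed}", seed, preset="met_shedding", noise=noise,
                n_ctc_per_timepoint=3, n_timepoints=2,
            )
            bundle = apply_vaf_thresholds(subtract_germline(bundle), DEFAULT_THRESHOLDS)
            retained = guard_retained(bundle)
            ctc, ctdna = resemblance_scores(bundle, retained)
            if (
                ctc.f_met_only > ctc.f_primary_only
                and ctdna.f_met_only > ctdna.f_primary_only
            ):
                wins += 1
        assert wins >= 95


class TestHeterogeneitySummary:
    def test_identical_ctcs_jaccard_one(self):
        bundle = make_bundle(
            [
                make_sample("C1", Compartment.CTC, ["a", "b"]),
                make_sample("C2", Compartment.CTC, ["a", "b"]),
            ]
        )
        summary = heterogeneity_summary(bundle, guard_retained(bundle))
        assert summary["mean_ctc_jaccard"] == 1.0

    def test_handbuilt_jaccard(self):
        # retained CTC pools {a,b,d} and {b,d} -> |∩|/|∪| = 2/3
        bundle = make_bundle(
            [
                make_sample("T", Compartment.TUMOR_PRIMARY, ["a", "b", "d"]),
                make_sample("C1", Compartment.CTC, ["a", "b", "d"]),
                make_sample("C2", Compartment.CTC, ["b", "d"]),
            ]
        )
        summary = heterogeneity_summary(bundle, guard_retained(bundle))
        assert summary["mean_ctc_jaccard"] == pytest.approx(2 / 3)

    def test_disjoint_ctcs_jaccard_zero(self):
        bundle = make_bundle(
            [
                make_sample("T", Compartment.TUMOR_PRIMARY, ["a", "b"]),
                make_sample("C1", Compartment.CTC, ["a"]),
                make_sample("C2", Compartment.CTC, ["b"]),
            ]
        )
        summary = heterogeneity_summary(bundle, guard_retained(bundle))
        assert summary["mean_ctc_jaccard"] == 0.0

    def test_single_ctc_gives_nan(self):
        bundle = make_bundle(
            [
                make_sample("T", Compartment.TUMOR_PRIMARY, ["a"]),
                make_sample("C1", Compartment.CTC, ["a"]),
            ]
        )
        summary = heterogeneity_summary(bundle, guard_retained(bundle))
        assert math.isnan(summary["mean_ctc_jaccard"])

    def test_ctc_more_heterogeneous_than_ctdna_over_seeds(self):
        """Dominant-clone ctDNA shedding: mean CTC Jaccard < mean ctDNA
        Jaccard in >= 95% of 100 seeds."""
        noise = NoiseModel(ado_rate=0.2)
        wins = 0
        for seed in range(100):
            bundle, _, _ = simulate_patient(
                f"PT{seed}", 10_000 + seed, preset="met_shedding", noise=noise,
                n_ctc_per_timepoint=3, n_ctdna_per_timepoint=2, n_timepoints=2,
            )
            bundle = apply_vaf_thresholds(subtract_germline(bundle), DEFAULT_THRESHOLDS)
            summary = heterogeneity_summary(bundle, guard_retained(bundle))
            if summary["mean_ctc_jaccard"] < summary["mean_ctdna_jaccard"]:
                wins += 1
        assert wins >= 95
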