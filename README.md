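# concordlb

Concordance-based somatic variant filtering for concurrent liquid-biopsy
compartments: bulk tumor tissue, individual whole-genome-amplified (WGA)
circulating tumor cells (CTCs), and plasma cell-free tumor DNA (ctDNA).

## The problem

Single CTCs must be whole-genome amplified before sequencing, and WGA
introduces two artifacts that corrupt naive variant calling: allelic dropout
(true heterozygous variants vanish) and amplification-error false positives,
which appear as spurious calls at low variant allele frequency (VAF).
ctDNA adds its own sub-1% sequencing-error background. A pipeline that
analyses tumor, CTCs and ctDNA from the same patient can exploit the
redundancy between compartments to separate real tumor mutations from these
artifacts. `concordlb` implements that pipeline as a reusable library + CLI:

1. **Single-cell quality gate** — a WGA CTC enters analysis only if at least
   *k* of *n* genome-integrity regions amplify (presets: Ct < 35 in ≥ 5 of
   10 qPCR regions, or ≥ 2 of 4 positive amplicons; both a 50% positive rate).
2. **Germline subtraction** — every variant key present in the matched
   buffy-coat control is removed from all samples.
3. **Compartment VAF thresholds** — a call is kept iff VAF ≥ 10% in a WGA
   CTC, or VAF ≥ 1% in ctDNA and tumor tissue. The 10% cutoff sits above the
   VAF support of WGA amplification errors.
4. **Concordance retention** — a CTC variant is believed only when
   corroborated: shared with any tumor sample, shared with ctDNA, or present
   in ≥ 2 distinct CTCs of the same patient (time points pooled per
   compartment). Two modes: `circulating_guard` (default; tumor/ctDNA calls
   always kept, labelled `TUMOR_ONLY`/`CTDNA_ONLY` when private) and
   `literal` (only cross-compartment-shared calls survive, in every
   compartment).
5. **Metrics** — per-patient shared-mutation tables; a seven-class occurrence
   partition (tissue/CTC/ctDNA private and shared patterns); fraction of
   CTCs concordant with the matched tumor; resemblance of circulating
   compartments to primary vs metastatic tumor; within-compartment Jaccard
   heterogeneity; variant × time-point presence matrices with
   persistent / emergent / lost / transient labels; and per-sample CNV burden
   compared between disease-stage groups with Welch's *t*-test.

Variant identity everywhere is the exact key `(chrom, pos, ref, alt)`
(1-based, VCF-native); inputs must be pre-normalized (split multi-allelics
are handled, but no left-alignment is performed).

Because real patient-level call sets of this design are rarely shareable,
the package ships a **clonal-shedding simulator**: clone trees with trunk,
primary-private and metastatic-private mutations; binomial bulk-tumor
sampling (`E[VAF] = purity × Σ carrying-clone fractions / 2`); single CTCs
with allelic dropout and sub-10%-VAF WGA artifacts at reserved decoy sites;
ctDNA as a shedding-weighted mixture concentrated on the dominant clone plus
a sub-1% error background; k-of-n QC panels; and stage-dependent CNV counts.
It emits exactly the files the readers consume, plus ground-truth labels.

## Worked example

```sh
concord-lb simulate --out demo --seed 7 --n-patients 2
concord-lb run --config demo/config.yaml
concord-lb report --results demo/results
```

The run log prints each stage's counts:

```
[assemble] 2 patients, 20 non-germline samples
[qc_gate] passed 17/20 samples
[germline] subtracted germline for 2 patients
[vaf_thresholds] 253 calls survive
[retention] 48 retained keys
[report] results written to demo/results
```

Here 3 of 12 simulated CTCs failed the 5-of-10 integrity gate (CTC retention
0.75 in `qc_retention.json`; tumor and ctDNA are never gated). After
germline subtraction and thresholds, concordance retention kept 48 variant
keys across the two patients. `concordance_table.tsv` then mirrors the
per-patient shared-mutation tabulation:

```
patient_id  tumor_available  n_tumor_ctc  n_multi_ctc  n_tumor_ctdna  n_ctc_ctdna
SIM001      True             16           14           18             16
SIM002      True             16           16           18             16
```

and `heterogeneity.json` holds the compartment comparisons for SIM001:
every CTC shares ≥ 1 retained mutation with the matched tumor
(concordance fraction 1.0); the mean pairwise Jaccard index is 0.67 between
CTCs but 1.0 between ctDNA draws — ctDNA, fed by the dominant clone, is the
less heterogeneous compartment; and of the CTC-pool mutations found in
either tumor, 25% are metastasis-only and none are primary-only
(`f_met_only = 0.25 > f_primary_only = 0.0`), reflecting the simulator's
metastatic shedding. `temporal_classes.tsv` labels each retained key per
compartment over time, and `alteration_matrix.tsv` is a gene × sample
matrix with `SNV`/`INDEL`/`AMP`/`DEL` cell codes.

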