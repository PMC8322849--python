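# Methods

## Filtering model

The pipeline treats a variant call as evidence about a genomic key
`(chrom, pos, ref, alt)`. All reasoning about sharing is set algebra on
keys; VAF and depth are per-sample observations and never part of identity.
Inputs are required pre-normalized (uppercase alleles, split multi-allelics,
left-aligned upstream of this package): re-normalizing here would risk
silent key mismatches between compartments, which is worse for a
concordance method than rejecting malformed input. INDELs are matched by
key equality exactly like SNVs; interval-overlap matching is deliberately
not attempted.

Filtering runs in a fixed order: QC gate → germline subtraction →
compartment VAF thresholds → concordance retention. The order matters only
for bookkeeping (retention fractions are reported against isolated cells;
germline keys must leave before thresholds so a germline SNP's high VAF
cannot "rescue" it into the retained set).

**QC gate.** A WGA single cell passes iff at least `min_positive` of
`n_regions` integrity regions are positive. In Ct mode a region is positive
iff its Ct is *strictly* below the threshold (a region at exactly 35.0
counts negative); the boundary is unit-tested both ways. Tumor, ctDNA and
germline samples are never gated — how they might have been QC'd upstream
is outside this package's model. A WGA cell without a panel result fails by
default (configurable to pass), since an unmeasured amplification is
indistinguishable from a failed one.

**Germline subtraction.** The buffy-coat control is treated as pure
germline: any key called in it is removed from every sample regardless of
its germline VAF. Subtraction is idempotent and never adds keys.

**VAF thresholds.** Defaults: 0.10 for WGA CTCs, 0.01 for ctDNA and both
tumor sites. Boundaries are inclusive (`vaf >= cutoff` kept): a call at
exactly the printed cutoff is kept, and the strict variant is available via
`inclusive=False`. CNV events carry no VAF and bypass thresholds.

**Concordance retention.** Sharing pools all time points within a
compartment; "tumor" means any tumor sample, primary or metastatic. The
default `circulating_guard` mode demands corroboration only where the noise
is (single WGA cells): a CTC-only singleton is dropped, while tumor- and
ctDNA-private calls are retained with explicit `TUMOR_ONLY`/`CTDNA_ONLY`
labels, because compartment-private tissue and plasma mutations are real,
reportable observations in this design. `literal` mode applies the
three sharing criteria to every compartment and drops all private calls;
it exists because the two readings genuinely differ and users should be
able to choose. Evidence labels are cumulative, never prioritized.

"Shared between CTC1 and CTC2" generalizes to "present in ≥ 2 distinct CTC
samples", each key counted once — patients routinely contribute more than
two cells, and any pairwise definition would double-count.

## Metrics

Shared-mutation tables count keys, not calls, over compartment pools;
SNV/INDEL only, with a parallel CNV table keyed by `(gene, direction)`
since copy-ratio magnitudes are not comparable across callers. The
occurrence partition is the seven-cell presence pattern over
tissue/CTC/ctDNA pools and provably partitions the retained set. Resemblance
fractions condition on keys found in at least one tumor site; NaN (never 0)
is returned when a tumor site is missing or the denominator is empty, so
"no evidence" cannot masquerade as "no resemblance". Jaccard heterogeneity
uses retained keys only and reports NaN below two samples per compartment.

Temporal classification operates per compartment by default: presence is
pooled across samples within a (time point, compartment) cell — one
carrying CTC marks presence — and each key's boolean trajectory over that
compartment's *observed* time points is labelled PERSISTENT / EMERGENT(t) /
LOST(t) / TRANSIENT. Restricting to observed time points keeps a tumor-only
baseline (T0) from forcing spurious LOST calls in circulating compartments;
a pooled scope is available when a single axis is wanted.

CNV burden uses Welch's unequal-variance t-test (two-sided) rather than the
pooled-variance form: group sizes and variances differ strongly between
stage groups, and Welch is the safer default. Degenerate inputs are handled
explicitly: groups under two samples are an error; two constant equal
groups give t = 0, p = 1; constant unequal groups give an infinite
statistic with p = 0. The default stage grouping is {II, III} vs {IV},
configurable because any pooling of stages is a study choice.

## Simulator

The generator is the package's study population, not a tuning knob. Its
default parameters state the assumed data-generating conditions:

| parameter | default | meaning |
|---|---|---|
| `n_trunk` / `n_private_per_clone` | 8 / 4 | truncal and clone-private mutation counts per patient |
| `n_clones_primary` / `n_clones_met` | 2 / 2 | clone tree width per site |
| `ado_rate` | 0.20 | per-variant allelic dropout in a WGA cell |
| `wga_fp_count_mean` | 5.0 | mean WGA artifact calls per cell (Poisson) |
| `wga_fp_vaf_low/high` | 0.01 / 0.09 | artifact VAF support, below the 10% cutoff |
| `ctdna_error_rate` | 0.01 | per-decoy-site background call rate in plasma |
| `ctdna_error_vaf_high` | 0.01 | background VAF ceiling (the 1% threshold boundary) |
| decoy panel size | 200 | mutation capacity of the simulated target panel |
| `tumor_purity` / `tumor_depth` | 0.7 / 800 | bulk tissue sampling |
| `ctdna_tumor_fraction` / `ctdna_depth` | 0.2 / 5000 | plasma sampling |
| QC integrity | U(0.3, 1.0) per cell | genome integrity driving the k-of-n panel |
| CNV means by stage | I:2 II:3 III:6 IV:10 | Poisson per-sample event counts |

No quantitative ADO or WGA false-positive rate is established for this
design, so these are stated assumptions at values typical for
degenerate-oligonucleotide WGA chemistry, fixed once and exposed in
`NoiseModel` rather than revisited per experiment. All somatic variants are
modelled heterozygous (VAF 0.5 in a pure cell) with no CNV–VAF coupling,
because every filter in the pipeline operates on VAF alone. Artifact and
plasma-background keys are drawn from a reserved decoy key space disjoint
from true somatic and germline keys purely so truth labels are unambiguous
in tests; nothing downstream can see the distinction.

Clone trees are deliberately simple: primary clones are siblings on a
shared trunk; metastatic clones descend from the dominant primary clone and
add met-private mutations. Site fractions are Dirichlet(2) draws sorted so
the first clone dominates. Default shedding places CTCs uniformly on the
metastatic clones and concentrates ctDNA 90% on the dominant one — the
`met_shedding` preset; `homogeneous` copies the primary mixture into the
metastatic site and sheds from primary clones. The emergent-clone option
removes one metastatic clone from both tumor sites and from circulation
before its activation time point, then forces two CTCs per subsequent time
point plus ctDNA weight onto it, modelling a subclone newly entering the
blood mid-study.

What the simulator does *not* emulate: read-level errors and mapping noise,
locus-specific WGA bias, copy-number-driven VAF shifts, contamination
between compartments, and panel design. Tests passing on this generator
therefore demonstrate that the pipeline's logic recovers planted structure
under idealized binomial/Poisson noise — not that the printed thresholds
are optimal for any particular chemistry.

## Numerical and I/O choices

Sample depth in a VCF lacking `DP` is stored as 0 (filters use VAF only).
The allele fraction is read from FORMAT `AF` with INFO `AF` fallback; a
record with neither is a hard error naming the record. Multi-allelic
records are split one key per alt, broadcasting a scalar AF when only one
value is present. VCF `AF` is a 32-bit float on disk, so round-trip VAF
equality is asserted to 1e-6; CNV copy ratios pass through TSV at full
repr precision but are compared by `(gene, direction)` identity.
Chromosomes order 1–22, X, Y, MT, then lexically. All simulator draws
derive from `numpy.random.default_rng` child seeds below 2^31, making every
operation a pure function of (arguments, seed); pipeline outputs are
byte-identical across reruns of the same config.

Problem sizes in the test and acceptance suites (100 cells for artifact
suppression, 100 seeds per recovery experiment, 20 simulated patients for
cohort concordance, 10^4 permutations for the t-test cross-check) were
chosen to give stable pass/fail behaviour at interactive runtimes.

## Known limitations

- Key-equality matching means upstream normalization differences silently
  break sharing; the CLI documents the pre-normalization requirement but
  cannot detect violations.
- `circulating_guard` vs `literal` retention differ for compartment-private
  calls; neither is asserted as the uniquely correct reading of the
  three sharing criteria, and both are first-class.
- Shared-mutation counts depend on the ≥2-distinct-CTCs convention; other
  tabulation conventions (pairwise max/sum) would give different numbers on
  the same data.
- The burden comparison treats samples, not patients, as the unit of
  analysis; repeated cells per patient are not modelled as clustered.
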