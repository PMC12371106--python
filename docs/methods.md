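# Methods

This note documents the models implemented in `neomerkit`, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the design decisions taken
where more than one reasonable reading existed.

## Nullomers, resurfacing, and neomers

A *nullomer* is a k-mer (k ≤ 17 here) absent from a reference genome.
Presence is strand-symmetric: a k-mer is present iff it or its reverse
complement occurs as an N-free window of some contig, so the presence
set — a dense bitmap over all 4^k two-bit codes — is closed under
reverse complement, and so is its complement, the nullomer set.  When
nullomers are *counted*, a k-mer and its RC are tallied as two separate
entries unless palindromic; when they are used as a *recurrence or
detection unit*, the pair is collapsed to its lexicographic minimum
("canonical" form).  Both conventions appear in the literature; the
package stores canonical units and re-expands counts where a separate-RC
tally is wanted.  Soft-masked (lowercase) bases are uppercased and used:
masking marks repeats, not absence.  Windows containing any non-ACGT
symbol are skipped silently.

Applying a variant to the reference can create k-mers that were absent:
*resurfacing*.  All novel k-mers lie inside a window of (k−1) reference
bases flanking the replaced region, so `resurfaced_nullomers` scans only
that window, keeps the k-mers that overlap the edit (for a pure
deletion: those spanning the junction) and are absent from the presence
set, and reports each (variant, k-mer) pair once, whatever the number of
window offsets it occurs at.  Variants of one patient are applied
independently against the unmutated reference — no phasing or joint
windows; this matches per-mutation accounting and keeps each variant's
output independent of the rest of the cohort.  Indels are limited to a
100 bp length change.

A *neomer* is a nullomer resurfacing in at least r_i distinct patients
of one cancer type.  `choose_threshold` scans r = 2, 3, … and returns
the r whose catalog size is closest to a target (default 10,000; ties go
to the smaller r); if r = 2 already yields a catalog at or under the
target it is used directly — the minimum recurrence is always 2.  The
cfDNA detection path uses r = 2 catalogs, trading purity for
sensitivity, as is appropriate when the sample gives so few tumor
fragments.

The *order* of a nullomer is the minimum number of single-base edits to
the genome needed to create it; order ≥ 1 means no single substitution,
insertion or deletion suffices.  Creatability by one genome edit is
tested through the equivalent neighbor formulation (a Hamming-1 neighbor
of the k-mer present in the genome ⇔ creatable by one substitution; a
single-base deletion of the k-mer occurring ⇔ one insertion; a
single-base insertion ⇔ one deletion), which bounds the candidate set at
O(k) strings instead of enumerating genome edits; the equivalence is
verified against exhaustive single-edit enumeration in the test suite.

## Supervised selection and enrichment

* **MSI**: microsatellite-instable tumors mutate mononucleotide tracts,
  so MSI samples are scored by the number of their neomers containing
  `AAAAAAAA` or `TTTTTTTT` (length fixed at 8, exactly these two
  motifs).  The MSI/MSS decision cut is the harmonic mean
  t = 2ab/(a+b) of a = max(MSS counts) and b = min(MSI counts); a count
  ≥ t classifies positive, so the boundary sample is called positive.
* **POLE deficiency**: neomers created by TCT>TAT or TCG>TTG
  substitutions, with contexts read on the reference strand.  Because
  mutational signatures are conventionally strand-symmetric, the
  reverse-complement presentations (AGA>ATA, CGA>CAA) also qualify by
  default; a flag restricts to the literal contexts.
* **Germline exclusion**: any neomer creatable by a common germline
  variant (allele frequency > 1% by default) is removed from a
  catalog, since it could arise in healthy carriers.
* **Hypergeometric enrichment**: an observed overlap of n_draws items
  against white "successes" among white+black total is scored by
  expectation n·w/(w+b), fold observed/expectation, and upper-tail
  P(X ≥ observed).  With the validated-neoantigen urn (1700 draws,
  188,659 neomers, 186,067,892 sub-recurrent nullomers) the expectation
  is 1.72, so 13 observed ≈ 7.5-fold enrichment.
* **Driver enrichment**: the fraction of driver variants creating ≥ 1
  nullomer is compared with equal-sized sets of uniform random
  substitutions at random N-free positions (the minimal permutation
  null; trinucleotide-context matching is a documented stricter
  alternative), with the add-one permutation p-value.

## Tissue-of-origin classification

Each patient is a vector of per-cancer-type catalog intersection counts
(raw counts, not burden-normalized).  The classifier is a linear-kernel
SVM with default regularization (one-vs-one multiclass, fixed seed).
Cross-validation is stratified; the catalogs (recurrence filter and
threshold choice) are rebuilt inside every fold from the training
patients only, and held-out profiles are computed against those
training-derived catalogs — a neomer recurrent only because of a
held-out patient can never enter that fold's catalog.  When a class has
fewer members than folds (including leave-one-out) the split falls back
to unstratified K-fold with a warning.  Reported metrics: micro
accuracy, mean per-class recall, per-class F1 and macro F1 (the single
summary F1 is the macro value, labeled as such), and the confusion
matrix.

## cfDNA scanning and detection

Reads are scanned for exact matches by rolling 2-bit codes over each
read and testing canonical codes against a sorted query array —
O(read length) per read, independent of query-list size.  Because query
neomers are absent from the reference by construction, windows present
in the reference presence set are excluded first by an O(1) bit test,
which removes the overwhelming majority of windows before the query
lookup.  A read matches a neomer if it contains it on either strand
(fragments are double-stranded; RC pairs are one detection unit at scan
level).  Base qualities are ignored — matching is exact.

Filtering rules, in order:

1. **Both mates**: a neomer counts for a read pair only if found in both
   mates.  With ~167 bp fragments and 150 bp mates the mates overlap by
   ~133 bp, so this keeps genuine fragment-center k-mers while making a
   sequencing-error match require the same error twice independently.
2. **Genome anchor**: a hit pair must show evidence of genomic origin —
   at least one N-free k-mer of a mate *outside* the neomer window
   present in the reference.  This is the desk-scale stand-in for
   "the read aligns to the genome"; the module documents the extension
   point for a real aligner.  Reads too short to contain any outside
   window are retained with a warning.  Note the test's power depends on
   the presence-set density: it discriminates sharply when 4^k vastly
   exceeds the genome size (the regime used here), and saturates as the
   presence fraction grows.
3. **Support**: neomers backed by fewer than 2 read pairs (identical
   pairs optionally deduplicated; UMI dedup is assumed upstream) are
   dropped.

Per-sample counts divided by mean coverage C_j (scanned bases over
genome length) give densities d_ij = n_ij/C_j, assembled into the
samples × neomers neomer density matrix.  Downsampling to a target
coverage c keeps each read pair independently with probability c/C_i
(without replacement), re-applies the support filter, and repeats 100
times by default.

**Feature hashing.** NDM columns are hashed into m = 8192 buckets with a
keyed 64-bit BLAKE2b hash (deterministic across runs given the seed).
The default is *unsigned* bucket sums.  The usual ±1 signed variant is
available behind a flag, but it cancels the aggregate neomer-abundance
signal in expectation, and in sparse cohorts where each case's detected
neomer columns are largely private (see the geometry below, which makes
any single neomer's detection in many samples improbable at low tumor
fraction), that aggregate abundance *is* the dominant discriminative
signal.

**Classifiers.** The default detector is logistic regression with L2
penalty, class-balanced, with C grid-searched over 7 log-spaced points
(10⁻³…10³) on a 10-fold inner CV maximizing balanced accuracy, inside a
10-fold outer CV; L1 logistic regression, linear and RBF SVMs, and a
random forest are selectable.  Outer-fold decision scores are pooled
into a single ROC/AUC; per-fold AUC and balanced accuracy,
sensitivity/specificity at the default operating point and at fixed
specificities (85%, 95%), and stage-stratified metrics are also
reported.  The count-threshold detector implements t = max(training
control counts) − 1 with "count ≥ t ⇒ cancer" verbatim — including its
known quirk that the maximal training control itself flags positive; a
strict-inequality switch is provided.  Class balancing by random removal
precedes each of the 100 random splits of the repeated-F1 evaluation.

## The synthetic-data generator

The generator emulates the three data tiers the pipeline consumes:

* **Genome**: i.i.d. bases at GC 0.41 (the human genome-wide value).
  No repeats, no chromatin-informed fragmentation — so mapping
  ambiguity and repeat-driven artifacts are *not* represented, and
  passing tests say nothing about those failure modes on real data.
* **Somatic cohorts**: per cancer type, a pool of signature
  substitutions chosen by rejection sampling to create ≥ 1 nullomer
  each, every one shared by `recurrence_depth` (default 3) patients;
  private background substitutions and 1–`indel_size_max` bp indels per
  patient carry no resurfacing requirement.  A truth table lists every
  planted neomer with its type; signature sets can be forced pairwise
  disjoint across types.
* **Germline**: a panel of SNPs with allele frequencies (20% common,
  AF ∈ (0.01, 0.5]; the rest log-uniform on [10⁻⁴, 0.01]), plus a
  per-individual genotype: panel SNPs carried at the Hardy-Weinberg
  heterozygote rate ~2·AF, and ~30 private rare heterozygous SNPs per
  sample — the order of the rare-variant density a real megabase of one
  genome carries.  Rare personal variants are what give healthy controls
  their realistic nonzero neomer noise floor, since the common-variant
  filter cannot remove them.
* **cfDNA reads**: fragment lengths truncated-Normal(167, 10) on
  [120, 220]; a pair derives from the tumor haplotype (somatic +
  germline variants, one clonal haplotype, no subclonal structure) with
  probability `tumor_fraction`, else from one of two parental
  haplotypes (germline variants heterozygous on one); mates are the
  first and RC'd last 150 bp of the fragment with i.i.d. substitution
  errors (default 10⁻³) — no indel errors, no quality correlation, no
  adapter read-through.

### Problem sizes and the coverage geometry

A mutation site is confirmed by a read pair only when its k-mer falls in
the mate-overlap region, so the per-site both-mate hit rate is

    λ = coverage × tumor_fraction × E[overlap − k + 1] / (2 × read_length),

independent of genome length (λ ≈ 0.10 at 5× coverage and 5% tumor
fraction, k = 12).  The ≥ 2-pair support rule then passes a site with
probability ≈ λ²/2 ≈ 0.5%.  Detection therefore depends on the
*absolute* number of mutation sites a patient carries, not on mutation
density; the cfDNA cohort generator accordingly plants the order of 10⁴
substitutions per patient on its 1 Mb genome — matching the per-patient
resurfacing-site count of real whole-genome cohorts rather than their
per-megabase density.  With 5,000 recurrent sites per case this yields
~25 detected sites (a few hundred neomers) per case against a control
noise floor of a handful, which is the regime the detectors are
evaluated in.  The evaluated problem sizes are: tissue-of-origin — 5
types × 20 patients on 300 kb at k = 10; cfDNA detection — 50 cases /
50 controls on 1 Mb at k = 12, 5×, tumor fraction 0.05; downsampling —
30/30 on 300 kb at k = 12, 10× downsampled to 3×, tumor fraction 0.2
(the strong-signal condition under which coverage robustness is the
claim being checked).

## Numerical and interface conventions

* Coordinates are 1-based inclusive in files and CLI output, 0-based
  half-open internally.  FASTA/FASTQ (gzip allowed) via Biopython; VCF
  via pysam; tables via pandas.
* The presence set serializes as magic + k + genome id + raw bitmap;
  catalogs as TSV plus a JSON threshold sidecar; NDMs as sparse triplet
  TSV plus metadata.
* All randomness flows through `numpy.random.default_rng` seeds passed
  explicitly; derived seeds stay below 2³¹.  Repeated runs with one seed
  are byte-identical.
* Degenerate inputs: empty unions in Jaccard return 0 with a warning;
  all-zero training controls make the threshold rule flag everything
  (warned); a = b = 0 makes the harmonic threshold undefined (error);
  variants mismatching the reference are skipped and counted.

## Known limitations

* The anchor filter is a heuristic, not an aligner; on references where
  a large fraction of k-mer space is present (e.g. short k on large
  genomes) it loses discriminative power against non-genomic reads.
* The generator's i.i.d. genome overstates nullomer abundance relative
  to a repeat-rich genome of equal size, and its error model cannot
  produce the correlated-error artifacts real both-mate false positives
  come from (e.g. index hopping), so absolute control noise levels on
  real data must be measured, not taken from simulation.
* The dense 4^k bitmap is the only membership backend; at k = 17 it
  costs 2 GiB.  A sorted-code array backend is the natural extension for
  memory-constrained settings.
* Per-patient profile counts are not normalized by mutation burden; a
  burden-normalization flag on the tissue classifier is the appropriate
  control when cohorts mix very different mutation loads.
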