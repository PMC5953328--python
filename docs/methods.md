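# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Data model and file dialect

The central object is the annotated rearrangement: one V(D)J-assembled
receptor sequence with its gene calls, junction, paired observed/germline
alignments, region coordinates and duplicate count. Files follow the AIRR
community TSV conventions: header-driven, tab-delimited, 1-based closed
coordinate intervals. The dialect is deliberately strict — no quoting;
tabs and newlines are forbidden inside values — so a write→read round trip
is bit-exact for every populated field. Tri-state booleans (`productive`,
`stop_codon`, `vj_in_frame`) serialize as `T`/`F`/empty: an empty cell
means *unknown*, which downstream strict filtering treats as failing,
never passing. A missing `duplicate_count` defaults to 1 (the one observed
read). Unknown columns are preserved verbatim and written back.

Study metadata is one TSV row per sample. Group membership lives in a
single `sample_group` column with semicolon-separated labels, so a sample
can belong to several groups; groups are constructed from the union of
labels. All metadata columns are optional; recognized MiAIRR-style names
are kept apart from user-defined ones but both are passthrough.

## Read QC

* Phred scores are decoded with the +33 offset only. Legacy +64 encoding
  is not autodetected; such data should be converted upstream.
* Mean read quality is the arithmetic mean of integer Phred scores, not an
  error-probability average, because quality thresholds in this domain are
  conventionally stated on the Phred scale ("average quality < 35").
* Per-position quantiles (p10, Q1, median, Q3, p90) and the median of
  per-read means use linear interpolation between order statistics (the
  common "type 7" rule, numpy's default). The test oracle uses the same
  rule, stated here so the numbers are reproducible elsewhere.
* GC percent is 100·(G+C)/(A+C+G+T) per read, floor-binned to integers;
  ambiguous bases are excluded from the denominator, and all-N reads
  (undefined GC) are excluded from the histogram but counted.
* Positions beyond a read's length contribute nothing: the denominator of
  every per-position statistic is the number of reads covering that
  position.
* Filtering partitions the input exactly — a read is discarded iff its
  mean quality or length is below threshold — and duplicate collapsing
  keeps the first occurrence as representative, conserving total read
  count in the copy sums.

## Rearrangement filtering

Eight record-level rules are evaluated, each a plain predicate on
annotation fields: frame-shifting indels (non-codon-multiple total
insertion or deletion length in the gapped alignment pair, or an explicit
`v_frameshift` flag when present), out-of-frame junction, stop codon,
truncated read length (opt-in threshold), V-gene germline identity below
0.85 (`v_identity`, the standard AIRR field, is used as the homology
measure), missing CDR3, missing coverage of V codons 31–92, and duplicate
count below 2. Afterwards, samples with fewer than 10 surviving unique
records are excluded entirely — repertoires that small cannot support
downstream statistics.

Three deliberate semantics:

* **Full accounting.** Every rule is evaluated for every record (no
  short-circuit): a record violating k rules increments k counters but is
  removed once, so the report attributes all violations.
* **Strict missing-field policy.** A record lacking the field an enabled
  rule needs counts as violating that rule; a rule whose field is absent
  on *every* record is a configuration error. Missing evidence never
  passes silently.
* **Pluggable codon numbering.** The coverage rule is expressed against a
  codon→germline-interval numbering (Chothia in antibody work). The
  default identity numbering (codon c ↦ nucleotides 3c−2..3c) is an
  approximation valid for ungapped germline references; a real Chothia
  table can be supplied per gene.

All thresholds are inclusive keeps: identity 0.85, 2 copies and 10 unique
reads are retained.

## Characterization

Gene calls are decomposed by the IMGT nomenclature grammar
(locus → family → gene → allele, e.g. IGH → IGHV3 → IGHV3-23 → \*01).
Multi-call strings are resolved by policy: `first_call` (default — upstream
aligners order calls by score), `fractional` (1/k per distinct name), or
`drop_ambiguous`. Relative usage divides by the number of contributing
records, so tables sum to 1 at every level and policy.

Clones are defined conventionally, not reconstructively: records agreeing
on V gene, J gene and junction length are single-linkage clustered on
junction-nucleotide Hamming distance (threshold 0 by default). Clone ids
are deterministic (clusters ordered by smallest member `sequence_id`), and
abundance ties rank lexicographically by clone id, so outputs are stable
across runs and record orderings.

The diversity profile reports Hill numbers over q = 0..4 in steps of 0.1.
At q = 1 the Hill limit exp(−Σ pᵢ ln pᵢ) is used so the profile is
continuous in q; the raw Shannon entropy H is exported alongside.
Abundance weighting defaults to `duplicate_count` (each record contributes
its raw copy number); `unique` weighting is available.

CDR3 physicochemistry operates on the junction amino-acid sequence:
hydropathy is the mean Kyte–Doolittle index; net charge uses
Henderson–Hasselbalch with EMBOSS sidechain pKa values (K 10.54, R 12.48,
H 6.04, D 3.90, E 4.07, C 8.18, Y 10.46) at pH 7.4 by default, with
termini excluded since the CDR3 is an internal fragment; aromaticity is
the F/W/Y fraction. Sequences containing a stop are excluded from
amino-acid metrics and counted.

## Mutation analysis

A mutation is a position where observed and germline alignments both carry
a determined (A/C/G/T) base and disagree. Classification is per codon: the
germline codon is translated against the fully-observed codon (all
substitutions applied at once), and every contributing nucleotide record
carries the codon's replacement/silent class — this keeps nucleotide-level
and codon-level tables consistent when a codon holds several substitutions.
Codons containing a gap or N in either string are non-informative: they
yield no calls and are excluded from frequency denominators, so ambiguity
never inflates mutation frequency (mutated / informative positions).
Whole-V totals cover FWR1–FWR3 only; CDR3 positions are junction
diversity, not hypermutation evidence. R:S ratios with zero silent
mutations are reported as undefined, never infinite. Only the standard
nuclear genetic code is supported.

## Group comparison

Numeric aggregation uses the sample (n−1) variance — the error bars
describe the spread of a small sample of repertoires — and treats a
category absent from a sample as a genuine 0, which keeps group means of
relative tables normalized. Single-sample groups report variance as
undefined. Sharing analysis is exact set algebra on combination keys;
CDR3-containing keys match at exactly the sequence level of the key type
(amino acid vs nucleotide), with no fuzzy matching. Intergroup comparison
requires disjoint groups. A cross-sample deduplication step (drop records
whose exact nucleotide sequence occurs in ≥ 2 samples) is available as a
pre-step for classifier-style workflows. No statistical testing is
performed on group differences; the outputs are descriptive.

## Provenance

Steps get version-4 UUIDs; objects get SHA-256 digests over file bytes
(the algorithm is named in the document header). The chain property —
every input is an external input or an earlier step's output — is
validated on every export and import; violating documents are refused,
never repaired. Export orders records topologically (ties broken by
append order), and import(export(d)) reproduces the document exactly. The
schema is this package's own, with a reserved optional `doi` field per
object.

## Synthetic data generator

The generator emulates what the pipeline consumes, not receptor biology.
Its built-in germline set (three V genes of 96 codons, two J genes of 16
codons, stop-free, fixed once) stands in for a reference database.
Sampling is clone-first: each clone draws a V and J gene from the
configured usage distributions and an in-frame junction (Cys...Trp
bracket, random non-stop codons between); clone sizes follow a
deterministic power law (rank^−1.5 by default) or an explicit size list.
Each read then receives independent per-site hypermutation at `shm_rate`
(default 0.02, a typical memory-B-cell load); substitutions that would
create a stop codon are re-targeted to another base — count preserved — so
baseline repertoires stay productive, as they would after upstream
cleaning. Defaults: 1,000 records, 50 clones, junction lengths 36–45 nt
uniform, read quality ≈ N(38, 4) clipped to [2, 40], duplicate counts
uniform in 2–5. One seeded NumPy generator drives all sampling, making
output byte-identical under a fixed seed.

Because gene usage is drawn per clone, record-level usage fluctuates with
the clone-size distribution; recovery checks therefore estimate usage on
one record per clone (a binomial with n = number of clones), or use
single-record clones when record-level binomial precision is wanted.

Violation injection corrupts exactly round(fraction·n) records so each
violates *only* the named filter rule (e.g. a 1-nt insertion for the
frameshift rule, `v_germline_start` pushed past codon 31 for coverage);
the labels make filter precision and recall exactly measurable, by
construction rather than by sampling.

What it does **not** emulate — and hence what passing tests do not show
about real data: V(D)J junctional mechanics (TdT additions, exonuclease
chew-back, D-segment usage in the sequence), SHM hotspot targeting and
transition bias, indel mutations, sequencing error profiles, primer/
barcode structure, or realistic germline allele diversity. Tests on this
generator validate the *bookkeeping and statistics* of the pipeline, not
biological realism.

## Problem sizes and tolerances

The test suite and the acceptance script run on simulated repertoires of
150–2,000 records (50 clones), 200-trial oracle comparisons for clones /
sharing / mutation calls, and 50–100 random instances for closed-form and
conservation properties — sizes at which the brute-force oracles remain
exact and the whole suite completes in well under a minute. Statistical
recovery checks use 3-standard-error bounds derived from the generative
model (binomial for usage and mutation rate). Closed-form identities
(Hill numbers, normalization sums) are asserted to 1e-9 relative error;
exact combinatorial checks (filter fidelity, sharing partitions, round
trips) are asserted with equality.

## Known limitations

* Productivity/frame annotations are trusted, not recomputed from raw
  sequence; the filter is only as good as the upstream annotator.
* The identity codon numbering is an approximation; accurate Chothia
  coverage filtering requires a per-gene numbering table.
* Clone definitions are conventional defaults, not a reimplementation of
  distance-threshold inference; no lineage trees or selection-pressure
  quantification.
* FASTA+QUAL and FASTQ loading assume well-formed single-end reads;
  paired-end merging, UMI handling and primer/barcode processing are out
  of scope.
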