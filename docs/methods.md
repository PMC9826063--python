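# Methods

## Model and assumptions

A target is one PCR amplicon (≤ ~10 kb) over a validated de novo SNV
(DNM) in a proband whose parents have been exome-sequenced. The package
assumes:

- the DNM's reference/alternate bases are known and independently
  validated — they are treated as ground truth ("anchoring"), never
  re-genotyped;
- reads are already aligned to the region reference with trustworthy
  CIGARs (alignment is upstream of this package);
- the amplicon contains no recombinant molecules, so every read carrying
  the DNM alternate base derives from a single physical haplotype;
- a postzygotic event is a mosaic of the mutant haplotype and its
  wild-type counterpart: a fraction *m* of the origin haplotype's
  molecules carry the alternate base, giving an expected mutant-molecule
  fraction of *m*/2 among all reads and a wild-type-of-mutant ("third
  allelic form") fraction of (1−*m*)/2.

The pipeline is deliberately simple — one DNM, one selected iSNP, one
cross-tabulation — rather than a general haplotype-graph phaser: with a
validated anchor and amplicon-level depth, multi-variant haplotype
assembly adds nothing.

## Stages and key rules

**Read QC.** Both read ends are trimmed while the terminal base quality is
below 10; reads shorter than 30 bp after trimming are removed. Trimming
operates on query bases and re-derives the alignment start and CIGAR, so
it is idempotent and safe on reads with indels. Reads without quality
values pass through with a warning (configurable to an error).

**Demultiplexing.** Pooled amplicons are separated by genome region, not
barcodes. A read belongs to the unique manifest target whose region
contains its alignment start; the manifest is rejected outright if any two
regions overlap, and unmatched reads are counted in an `unassigned` bin so
the operation always partitions its input.

**Variant calling.** A pileup column contributes a heterozygous candidate
when depth > 20 (strict), the alternate fraction lies in [0.20, 0.80]
(inclusive), and the heterozygosity posterior is ≥ 0.96. The posterior is
a three-genotype binomial model on the (ref, alt) counts with a uniform
prior; the per-allele error rate is estimated per column as half the
fraction of third/fourth bases and deletions, floored at 10⁻³. This is a
transparent stand-in for an external caller's confidence score; the 0.96
threshold is applied to it unchanged. Two deliberate asymmetries:

- *the DNM position is exempt from the fraction and confidence filters* —
  only the validated alternate allele is admitted there, at any fraction,
  because mosaic DNMs legitimately sit far below 20%;
- *homozygous-alternate columns* (fraction above 0.80) are retained
  separately — they are linked variants on both haplotypes and useful for
  the split-group search, but useless as iSNPs.

Single-base deletion alleles are called by the same rules and flagged with
a homopolymer context marker (in or adjacent to a same-base run ≥ 3).
Insertions are counted per column and reported but not genotyped; raw
long-read indel calls are overwhelmingly artefactual and no downstream
step consumes insertion genotypes.

**WES polishing.** A candidate at a position where the proband's WES depth
is ≥ 10 is kept only if the WES genotype contains the same alternate
allele; covered positions with no variant call imply homozygous reference
and remove the candidate. Depth < 10 renders WES uninformative rather than
contradictory: the candidate passes through flagged unvalidated. Indel
candidates with no orthogonal support (WES match or parental long-read
typing) are dropped; SNVs never are.

**iSNP discovery and attribution.** From trio WES: proband-het sites
within 10 kb of the DNM where each allele occurs in exactly one feasible
parental assignment (attribution by elimination) and both parents have
depth ≥ 5; multi-allelic sites are excluded. From parental long reads
(intronic, category-3 targets): a parent supports an allele when its
pileup fraction is ≥ 0.20 at depth ≥ 20, and the candidate is typed when
the two alleles resolve to different parents uniquely. Targets are
categorised by the nearest attributable iSNP: ≤ 300 bp (category 1, short
reads could phase), ≤ 10 kb (category 2, proband amplicon suffices),
otherwise category 3 (parental amplicons over ±5 kb required).

**Linkage vetting (the anchor's contribution).** Reads are split by their
observed DNM base; reads with any other base or a deletion go to a third
group that is excluded from linkage scoring but counted in the raw base
fraction. For each candidate, the majority base and its fraction are
computed within the DNM-alternate group and the DNM-reference group. A
usable candidate needs:

- majority fraction ≥ 0.90 within the *alternate* group (the mutant
  haplotype is a single molecule population, mosaic or not), and
- a *different* majority base in the reference group.

The reference group is deliberately **not** required to be homozygous:
under mosaicism it contains both the wild-type copies of the mutant
haplotype and the other parent's reads (e.g. a 33%/60% mix at *m* ≈ 0.3),
and a symmetric homozygosity requirement would discard every postzygotic
target. Sequencing-noise candidates fail the different-majority test
instead, which is what makes anchoring strictly stronger than
depth/fraction/confidence filtering alone. The reported agreement score is
the mean of the two majority fractions; groups with fewer than 10
candidate-covering reads mark the candidate insufficient.

**Selection.** Among non-discordant, parentally attributable candidates:
support category (primary > secondary > tertiary > unvalidated), then
agreement, then spanning coverage, then smaller |distance to DNM|, then
leftmost position. The order is lexicographic and total, so selection is a
pure function of its inputs; ties cannot depend on input order.

**Allele table and interpretation.** Reads covering both positions are
cross-tabulated by (DNM base, iSNP base); deletions tally under a distinct
`*` marker and count as allele-level noise. Fewer than 20 spanning reads
is an unphaseable outcome, not an error. With mutant pair (a, s₁), other
parent (r, s₂) and third allelic form (r, s₁):

- *error metrics*: total and maximum fractions of allele pairs outside
  those three (the third form is biologically plausible and never counted
  as known-false), plus total/maximum false-base fractions at the iSNP
  column; the per-target maximum false iSNP base is what the cohort
  summary averages as background noise;
- *third allele*: credible iff its fraction exceeds
  max(0.05, 2 × max false allele pair). The 0.05 floor reflects the ~4%
  background noise scale of raw amplicon long reads; any pair other than
  (r, s₁) — e.g. (a, s₂) — is never credible regardless of size, because
  it matches no biologically possible haplotype;
- *polished frequency*: n(a,s₁) over the credible pairs only (the third
  form joins the denominator when credible). When the error metrics are
  zero, polished and raw frequencies coincide exactly;
- *zygosity*: postzygotic iff a credible third allele exists, or the
  polished frequency leaves the prezygotic band [0.40, 0.60] *and* the
  long-read DNM base fraction deviates beyond the measured total base
  error. A frequency deviation without corroboration is adjudicated
  prezygotic with an `allelic_bias_suspected` flag (allele-specific
  amplification bias mimics mosaicism at the allele level but not at the
  base level). Missing or ≤ 10× WES coverage of the DNM adds a
  lower-confidence flag but does not block classification;
- *parent-of-origin*: the parent attributed the iSNP base s₁. The
  assignment thresholds on the alternate-group purity (≥ 0.90), not the
  mean agreement, for the same mosaicism reason as above.

A WES-only control (`phase_wes_only`) applies the identical table logic to
short reads for category-1 targets and marks the result acceptable only
when each haplotype allele has > 10 supporting reads.

**Cohort summaries** report the phased fraction, paternal fraction overall
and within zygosity strata, mean ± SEM (sd/√n, ddof = 1) of polished
frequencies per stratum, and mean background noise.

## Tunable parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `min_depth` | 20 | reads | noise floor for candidate calling (strict >) |
| `af_window` | 0.20–0.80 | fraction | heterozygote plausibility window (inclusive) |
| `min_confidence` | 0.96 | posterior | het posterior threshold |
| `wes_min_depth` | 10 | reads | WES considered informative for polishing |
| `min_parent_depth` | 5 | reads | parental WES typing floor for iSNP discovery |
| `isnp_window` | 10 000 | bp | amplicon-reachable iSNP search radius |
| `trio_window` | 5 000 | bp | parental-amplicon (intronic) search radius |
| `short_read_span` | 300 | bp | category-1 reach of paired short reads |
| `parental_support_af` / `parental_min_depth` | 0.20 / 20 | fraction / reads | allele support rule for parental long-read typing |
| `min_group_agreement` | 0.90 | fraction | mutant-group homozygosity requirement |
| `min_group_spanning` | 10 | reads | per-group coverage for linkage scoring |
| `min_spanning_reads` | 20 | reads | allele-table floor for a phaseable target |
| `prezygotic_band` | 0.40–0.60 | fraction | "around 50% ± 10%" germline expectation |
| `third_allele_floor` / `third_allele_k` | 0.05 / 2.0 | fraction / × | credibility screen vs background noise |
| `min_parent_agreement` | 0.90 | fraction | mutant-group purity for parent assignment |

All are fields of `PipelineConfig`, loadable from YAML.

## What the simulator emulates — and what it does not

The generator produces Mendelian trio genotypes with designated
informative sites (opposite-homozygote parents by default; one-parent-het
and explicit-genotype schemes available), places a DNM on one parental
haplotype at mosaic fraction *m*, and emits full-length amplicon reads
with i.i.d. substitution error (uniform over the three non-true bases) and
1-bp indel error whose rate is multiplied inside homopolymer runs ≥ 3.
WES-like evidence carries Poisson depths, binomial allele sampling,
capture gaps and per-position depth overrides (e.g. a 1×-covered DNM).
Reads are emitted pre-aligned with exact CIGARs; a separate truth file
records each read's haplotype and mutant status. One numpy generator
drives each dataset, so equal seeds give byte-identical outputs.

Not modelled: signal-level error structure and base-quality correlation,
realistic read-length distributions and partial amplicon spans (a span
sampler exists but defaults off), PCR chimeras and polymerase errors,
strand bias, mappability artefacts, and multi-nucleotide or structural
variants. Consequently, passing tests demonstrate the *logic* of anchored
phasing — splitting, polishing, selection, frequency arithmetic,
classification — under calibrated random error; they do not certify
performance against systematic, position-correlated error in real flow
cells. The default error preset (4% substitution, 1% indel, ×5 in
homopolymers) matches the ~4% background-noise scale of raw amplicon long
reads; its substitution/indel decomposition is a modelling choice, and
both rates are configurable.

## Numerical and degenerate-input choices

- Threshold comparisons follow their printed form exactly: depth strictly
  > 20, fraction window and parental depth inclusive.
- Majority ties within a split group break toward the lexicographically
  larger base; selection ties end at the leftmost position — both arbitrary
  but fixed, keeping every stage deterministic.
- An empty read set yields an empty pileup (not an error); a DNM position
  with zero coverage is a hard error (the amplicon failed); no usable
  iSNP or < 20 spanning reads are reported as unphaseable outcomes.
- The het posterior's error floor (10⁻³) prevents log(0) on clean columns;
  depths are capped only by memory (counts are 64-bit).
- Cohort SEM uses the sample standard deviation (ddof = 1); single-member
  strata report SEM 0.

## Problem sizes

The test suite and the reproduction script run entirely on simulated
data sized for a laptop: 3 kb amplicons, 200–1,000× coverage per target,
69-target prezygotic cohorts for the frequency statistics and a
200-target cohort (83% paternal, 10% postzygotic, *m* ∈ [0.1, 0.4]) for
parameter-recovery checks. These sizes keep the full suite under a minute
of compute while leaving binomial noise well below the tolerances tested.

## Known limitations

- SNV DNMs only; the anchor cannot be an indel.
- One iSNP per target by design; no multi-iSNP consensus or haplotype
  graph.
- Insertions are observed but never used as markers or polished calls.
- The zygosity classifier's bias branch encodes a qualitative judgement
  (allele-level deviation without base-level corroboration → bias flag);
  borderline mosaics near *m* ≈ 0.2 with shallow coverage can be
  conservatively labelled prezygotic-with-flag.
- Parent-of-origin is undetermined rather than guessed whenever the
  mutant-group purity falls below threshold; cohort "phased" fractions
  count only determined targets.
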