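# Methods

`fadiv` quantifies how replicate cell cultures diverge genetically and
transcriptionally in a 2-group × 2-replicate design: a disease cell
line (the canonical case is a FANCD2-deficient Fanconi-anemia PD20
line, "FA") and its retrovirally gene-corrected counterpart ("FA_RV"),
each cultured as two biological replicates. Variants shared by all
four samples predate the split from the parent culture; variants
confined to one group arose after correction; variants private to a
single replicate measure ongoing culture divergence. The package
implements the downstream arithmetic of that design — sharing algebra,
coverage-gated specific-SNP detection, microsatellite genotyping and
an expression consensus — on standard inputs (VCF, per-position depth
tables, FASTA, read-observation and expression TSVs). Upstream steps
(trimming, alignment, calling, functional annotation, FPKM estimation)
are consumed, not reimplemented.

## Variant sharing

Variant identity is the exact `(chrom, pos, ref, alt)` tuple. No
left-alignment or normalization is applied at load time; inputs are
expected to be normalized upstream (e.g. joint INDEL realignment
before calling). SNPs are single-base substitutions; INDELs are
allele pairs with a 1–10 bp length difference; anything else (MNPs,
longer or symbolic alleles) is excluded and counted. Multi-allelic
records contribute one variant per ALT allele.

Sharing statistics are plain set intersections: per sample, within
each replicate group, and across all samples. The "shared fraction"
reported alongside uses the **arithmetic mean of the per-sample
counts** as denominator — the only denominator consistent with the
headline fractions in the data this mirrors (128,179 shared SNPs over
a mean load of 196,826 → 65%) — rounded to the nearest integer
percent, ties away from zero. The SNP:INDEL composition is reported
as a one-decimal pair summing to 10 (`round1(10·n_snp/total)`,
`round1(10·n_indel/total)`, half away from zero).

High-impact gene sets use the four-level consequence scheme of
SnpEff-style annotators, read from the impact slot of an `ANN=` INFO
subfield (a variant without a parseable annotation is retained as
MODIFIER and counted). A gene is *case-specific* when a HIGH-impact
variant in it appears in ≥1 case sample and no control sample, and
*common* when such a variant appears in all four samples.

## Coverage-gated sample-specific SNPs

A SNP is specific to sample A relative to sample B when its alternate
base has **≥3 supporting reads in A and zero in B**, evaluated **only
at positions with ≥10 reads in both samples**; positions failing the
depth gate are uncallable and reported separately, never counted as
absent. "Zero in B" refers to reads supporting that alternate allele:
other alternates seen in B at the position do not disqualify (the
literal reading of the rule; base identity is matched between the
variant call and the pileup). The comparison is run on HIGH-impact
SNPs by default (matching how such matrices are usually reported) and
on all SNPs behind a flag. For a multi-sample design all ordered
pairs are evaluated; each unordered pair is summarized as the
arithmetic mean of its two directional counts.

Both gates are monotone (raising either threshold can only shrink the
output), which the property tests assert, and the whole computation is
deterministic with output sorted by `(chrom, pos, alt)`.

## Microsatellites

**Discovery.** The scanner reports every maximal perfect tandem
repeat with motif length 1–6, tract length ≥8 bp and ≥3 copies
(defaults; all configurable — typical STR-catalog settings). A tract
with period *k* is the maximal interval on which `seq[i] == seq[i−k]`
holds, so partial trailing copies are included and `copies` may be
fractional. Each tract is reported once, at its primitive period
(tracts wholly periodic at some *p* < *k* are suppressed at *k*).
Overlapping tracts of different periods are resolved to the longest,
ties to the smaller motif, then leftmost. Motifs are canonicalized by
minimal lexicographic rotation; reverse complements are *not* merged,
since the scan is single-strand against the reference.

**Ambiguity filter.** Loci sharing a canonical motif and identical
5′ and 3′ flanking sequences (5 bp by default) are indistinguishable
to short-read mapping, so **every** member of a colliding group is
removed — not all-but-one; e.g. GCTGC(A)₃₄CTTAG and GCTGC(A)₁₅CTTAG
both go. The filter is idempotent.

**Genotyping.** From the multiset of repeat-tract lengths observed in
spanning reads: a locus is callable with ≥10 reads; the modal length
is the primary allele (count ties break to the shorter allele); the
runner-up length is called as a second allele (heterozygous) when it
carries ≥30% of the reads and ≥2 reads; any further length with ≥3
reads is a minor allele (a candidate low-frequency somatic tract
mutation). The 10-read callability and 3-read minor gates are the
standard thresholds for this style of read-count STR genotyping. The
30% heterozygosity fraction is this package's own default — published
pipelines in this area defer to unpublished in-house rules — and is
exposed as `het_min_frac`; it should not be quoted as anyone else's
value. Summaries report percentages over callable loci only
(homozygous is computed as the complement of heterozygous, so the two
always sum to exactly 100), and group summaries are arithmetic means
of per-sample percentages at a configurable rounding.

## Expression consensus

Input is one record per gene: an FPKM-scale value per sample, a
p-value per sample pair (six pairs for four samples, the Cuffdiff
`gene_exp.diff` layout; a converter is provided), and the exon count
of the most expressed transcript per sample.

A gene is differentially expressed between the groups when p < α
(default 0.05) in the cross-group pairwise comparisons and p ≥ α in
**both** within-group comparisons. The within-group veto suppresses
genes whose apparent shift reflects replicate divergence rather than
the group contrast. Whether "the cross-group comparisons" means all
four or at least one is genuinely open; the default is **all four**
(the stricter intersection-style rule, consistent with consensus
counts being well below per-pair counts in data of this shape), with
`cross_rule="any"` available. Genes missing any pair or sample value
are reported as uncallable rather than silently dropped into either
class.

FDR is the plain Benjamini–Hochberg quotient
`p · total_tests / rank`, rank assigned in ascending p order, ties
taking consecutive ranks in input order. **No step-up monotonicity is
applied by default**, so reported values can exceed 1 — this mirrors
how the quotient is often tabulated in applied reports; pass
`step_up=True` for standard monotone q-values capped at 1 (validated
against `statsmodels.stats.multitest.multipletests` to 1e-12).

Fold changes are `log2(b/a)` on full-precision values, rounded to one
decimal (half away from zero) only in outputs; a non-positive baseline
is reported missing. Exon-count variation compares, per sample pair,
the fraction of genes expressed (>0) in *both* samples whose exon
counts differ, then averages that fraction over the four cross-group
and two within-group pairs separately.

## Synthetic data

The generator emulates the study conditions, not sequencing physics:

* **Variants.** Ancestral variants appear in every sample,
  group-specific variants in both members of one group,
  replicate-specific variants in exactly one sample. Defaults — 176
  ancestral SNPs + 24 ancestral INDELs, 35 group-specific and 75
  replicate-specific variants (SNP fraction 0.88 in the case group,
  0.92 in the control group, mirroring the case group's INDEL excess)
  — put the shared-in-all fraction near 65% and within-group sharing
  near 75%, the regime the sharing algebra is meant for. Impact
  labels are assigned directly (HIGH 3%, MODERATE 10%, LOW 10%,
  MODIFIER 77%) since annotation is out of scope.
* **Coverage.** Depth is Poisson with mean 12 (the 10–13× exome range
  the thresholds were designed around), independent across positions;
  a sample carrying a variant draws alternate reads binomially at
  fraction 0.5, a sample without it observes zero alternate reads.
  Sufficient for threshold-gate testing; real depth is overdispersed
  and spatially correlated, so absolute callable fractions on real
  data will differ.
* **Microsatellites.** Planted tracts get boundary-breaking guard
  bases so their coordinates are exactly rediscoverable; the
  assembled reference is re-scanned and planting retried (bounded) if
  a background repeat absorbs a tract, else the failure names the
  constraint. Deliberately ambiguous same-motif/same-flank pairs are
  planted for filter testing. Read noise is ±1 repeat-unit slippage
  at rate 0.01 — real PCR stutter is length- and motif-dependent, but
  slippage is all the classification thresholds see. True genotypes
  are heterozygous with probability 0.05 (second allele ±1–2 copies);
  a planted minor allele (+4 copies, 20% of reads) appears with
  probability 0.08 per locus/sample. The recovery tests override
  these to het 0.30 / minor 0.08 at depth 30 over 1000 loci and
  require the called fractions to lie within the 95% binomial band of
  the planted rates at n = 1000. Note the estimator is slightly
  conservative by construction: a true 50/50 heterozygote fails the
  30% runner-up gate with probability ≈2% at depth 30, so recovered
  het fractions sit just below the planted value.
* **Expression.** Log-normal baseline FPKM; 27 of 1000 genes get a
  log₂ shift of 2.5 in the corrected group (random sign). Pairwise
  p-values are *emitted*, not fitted — small (log-uniform 10⁻⁶–10⁻²·⁵)
  for cross-group pairs of shifted genes, uniform otherwise — because
  the pipeline consumes per-pair p-values; this isolates the consensus
  logic. `noiseless_p` fixes them (0.001/0.9/0.5) for exact recovery
  tests. Exon counts use two independent Bernoulli effects — a
  replicate-level shift (P = 0.235) and a group-level shift
  (P = 0.203) — chosen so the pair-averaged within- and cross-group
  varying fractions land near 23.5% and 28.5%.

Every output is a pure function of the configuration: one fixed seed
gives byte-identical files, and each stage draws from its own seeded
stream so stages can be rerun independently.

What passing these tests shows — and does not. Exact recovery of
planted provenance, genotypes and DE genes demonstrates the
*arithmetic* of the thresholds and set operations is right under the
stated noise model. It does not validate behaviour under alignment
artifacts, stutter beyond ±1 unit, overdispersed coverage, or
miscalibrated p-values, none of which the generator models.

## Numerical conventions

* Rounding in all tabulated outputs is half away from zero (via
  `decimal`), not banker's rounding: 8.45 → 8.5, 74.64 → 75.
* Percent sharing uses the mean per-sample count as denominator.
* Genotype count ties break to the shorter allele; scanner overlap
  ties break longest → smallest motif → leftmost.
* Degenerate inputs: empty observation maps are uncallable (not
  errors); zero callable loci yield missing percentages; zero total
  variants make the ratio undefined (error); genes with missing pairs
  are uncallable; a coverage position absent from a profile is depth 0.

## Problem sizes

Default simulations use a 100 kb reference, ~600 variants, 60–64
microsatellite loci and 1000 genes; the validation runs use 1000 loci
at depth 30 and 100 random 2-kb scanner sequences. These sizes give
the recovery statistics their stated confidence bands while keeping a
full run under a minute.

## Known limitations

* No variant normalization: unnormalized representations of the same
  INDEL count as distinct.
* Whether recurrence counts in published tables of this kind use
  genotype identity or position identity is rarely stated; allele-
  tuple identity is used here throughout.
* The scanner detects perfect repeats only — no compound or
  interrupted tracts — and does not merge reverse-complement motifs.
* The het/hom decision rule is a read-fraction heuristic, not a
  stutter-aware likelihood model; at low depth it is biased toward
  homozygous calls.
* The literal FDR quotient is not a valid adjusted p-value (it can
  exceed 1 and is non-monotone); it is provided for fidelity to how
  the quantity is often reported, with the standard correction behind
  a flag.
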