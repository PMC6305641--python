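# fadiv

Replicate-divergence analysis for two-group cell-line sequencing
designs: variant sharing, coverage-gated sample-specific SNPs,
microsatellite genotyping, and a cross-group differential-expression
consensus — with a synthetic-data generator that plants ground truth
for every stage.

## The problem

When a disease cell line and its gene-corrected counterpart are each
cultured as two biological replicates and sequenced (the canonical
case: a FANCD2-deficient Fanconi-anemia PD20 line "FA" and its
retrovirally corrected "FA_RV"), the variant lists encode three
timescales at once. Variants present in **all four** samples
accumulated before the cultures split; variants confined to **one
group** arose after correction; variants private to **one replicate**
measure ongoing divergence of each culture — the signature of an
impaired repair pathway. `fadiv` implements the arithmetic that
separates those layers, plus two companion analyses that are sensitive
to repair dysfunction: microsatellite (STR) instability genotyped from
read tract lengths, and a conservative differential-expression rule
that requires the group contrast to beat replicate noise.

The core statistics:

* **Sharing fractions** — for variant sets $V_1..V_4$,
  $|\bigcap_i V_i| \,/\, \overline{|V_i|}$ as a percent (mean
  per-sample load as denominator), per group and overall; SNP:INDEL
  composition as a one-decimal pair summing to 10.
* **Sample-specific SNPs** — SNP $s$ is specific to $A$ vs $B$ iff
  $\mathrm{alt}_A(s) \ge 3$, $\mathrm{alt}_B(s) = 0$, and
  $\mathrm{depth}_A(s), \mathrm{depth}_B(s) \ge 10$; pairs are
  summarized as the mean of the two directional counts.
* **STR genotypes** — callable at ≥10 spanning reads; heterozygous if
  the runner-up tract length holds ≥30% of reads (and ≥2 reads);
  minor alleles need ≥3 reads. Loci sharing a motif and identical
  5′/3′ flanks are removed entirely before genotyping.
* **DE consensus** — a gene is differentially expressed iff
  $p < \alpha$ in all four cross-group pairwise comparisons and
  $p \ge \alpha$ in both within-group comparisons; FDR is the literal
  quotient $p \cdot m / \mathrm{rank}$ (standard step-up behind a
  flag).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate the 2×2 design and run every stage on the result:

```sh
$ fadiv simulate --seed 7 --outdir demo/sim
wrote 15 files to demo/sim
$ fadiv run --input-dir demo/sim --outdir demo/out
INFO fadiv.report: FA1: 310 records in = 310 kept + 0 excluded
INFO fadiv.report: MST scan: 101 loci = 97 kept + 4 ambiguous
INFO fadiv.report: expression: 1000 genes = 1000 callable + 0 uncallable; 23 consensus DE
```

Each simulated sample carries 310 variants (200 ancestral + 35
group-specific + 75 replicate-specific). Because `demo/sim` includes
the generator's `truth.json`, the run ends with a scoring report
(`demo/out/truth_report.json`):

```json
{
 "variants": {
  "ancestral":  {"planted": 200, "exact": 200, "recall": 1.0},
  "group":      {"planted": 70,  "exact": 70,  "recall": 1.0},
  "replicate":  {"planted": 300, "exact": 300, "recall": 1.0},
  "spurious": 0
 },
 "mst": {"callable": 177, "zygosity_accuracy": 0.966, "minor_recall": 0.118},
 "de":  {"planted": 27, "called": 23, "recall": 0.852, "precision": 1.0}
}
```

Reading this: the sharing algebra reconstructed the planted
provenance of all 570 variants exactly. STR zygosity is 96.6% correct
at the default 12× depth, but minor alleles — which need 3 supporting
reads — are mostly invisible at that depth (11.8% recall; at the 30×
depth of the recovery tests they come back at ~94%). The DE consensus found
23 of 27 planted genes with no false positives: with realistic
(noisy) within-group p-values, a planted gene slips below the
within-group veto with probability $1 - 0.95^2 \approx 0.10$, so
~2–3 misses out of 27 is the expected price of that veto.

The same stages are callable as a library:

```python
>>> from fadiv import snp_indel_ratio, shared_fraction, genotype_locus
>>> shared_fraction(128_179, [201_940, 198_816, 194_954, 191_593])
65
>>> snp_indel_ratio(205_613, 28_631)
(8.8, 1.2)
>>> gt = genotype_locus({15: 10, 13: 3})
>>> gt.zygosity, gt.minor_alleles
('homozygous', [13])
```

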