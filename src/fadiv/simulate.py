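"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the study layout the analyses are built for: two
groups of two replicate cell-line samples that share an ancestral
variant load, plus group-specific variants (divergence after the
corrective intervention that separates the groups) and
replicate-specific variants (ongoing divergence of each culture).  It
also plants microsatellite loci with known genotypes and low-frequency
minor alleles, and genes with known cross-group expression shifts, so
that every pipeline stage can be scored against recorded truth.

Simplifications, by design: read depth is Poisson and independent
across positions; microsatellite read noise is +/-1 repeat-unit
slippage only; impact categories are assigned directly rather than
derived from consequence prediction; pairwise p-values are emitted
directly rather than via a fitted test.  These isolate the threshold
logic under test without modelling sequencing in full.

All outputs are a pure function of the configuration (including its
seed): the same config yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .coverage import CoverageProfile
from .design import StudyDesign
from .expression import GeneExpressionRecord, write_expression_tsv
from .microsatellites import (
    MstLocus,
    ScanParams,
    canonical_motif,
    scan_microsatellites,
    write_loci_bed,
    write_observations_tsv,
)
from .variants import AnnotatedVariant, Impact, Variant, write_vcf

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_reference",
    "simulate_variants",
    "simulate_mst_genotypes",
    "simulate_mst_reads",
    "simulate_expression",
    "simulate_all",
]

BASES = np.array(list("ACGT"))

# impact mix loosely matching exome annotation profiles: most variants
# are non-coding/modifier, a small minority high-impact
IMPACT_WEIGHTS = {
    Impact.HIGH: 0.03,
    Impact.MODERATE: 0.10,
    Impact.LOW: 0.10,
    Impact.MODIFIER: 0.77,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults emulate the target design.

    Counts are scaled far below real exome loads but keep the sharing
    structure: with the defaults each sample carries roughly
    ancestral + group + replicate variants in proportions that put the
    shared-in-all fraction near 65% for SNPs and the within-group
    fraction near 75%.  ``mean_depth`` defaults to the 10-13x range of
    exome coverage the thresholds were designed for.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_ancestral_snps: int = 176
    n_ancestral_indels: int = 24
    n_group_specific: int = 35  # per group
    n_replicate_specific: int = 75  # per sample
    snp_indel_ratio_case: float = 0.88  # fraction of non-ancestral variants that are SNPs
    snp_indel_ratio_control: float = 0.92
    mean_depth: float = 12.0
    alt_read_fraction: float = 0.5  # expected fraction of reads carrying the alt
    n_mst_loci: int = 60
    n_ambiguous_mst_pairs: int = 2
    mst_flank: int = 5
    het_fraction: float = 0.05
    minor_allele_fraction: float = 0.08
    minor_read_fraction: float = 0.2  # read share of a planted minor allele
    length_error_rate: float = 0.01
    n_genes: int = 1000
    n_de_genes: int = 27
    de_log2fc: float = 2.5
    exon_var_within: float = 0.235  # P(replicate-level exon-count shift)
    exon_var_cross: float = 0.203  # P(group-level exon-count shift)
    expression_dropout: float = 0.01
    noiseless_p: bool = False  # deterministic p-values (0.001 / 0.9 / 0.5)

    def __post_init__(self) -> None:
        counts = (
            self.genome_length, self.n_ancestral_snps, self.n_ancestral_indels,
            self.n_group_specific, self.n_replicate_specific, self.n_mst_loci,
            self.n_ambiguous_mst_pairs, self.n_genes, self.n_de_genes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        probs = (
            self.snp_indel_ratio_case, self.snp_indel_ratio_control,
            self.het_fraction, self.minor_allele_fraction, self.minor_read_fraction,
            self.length_error_rate, self.exon_var_within, self.exon_var_cross,
            self.expression_dropout,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be at least 1000")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng([stream, self.seed])


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class TruthMstGenotype:
    alleles: tuple[int, ...]  # 1 or 2 allele lengths, in repeat copies
    minor: int | None = None  # planted minor-allele length, if any

    @property
    def zygosity(self) -> str:
        return "heterozygous" if len(self.alleles) == 2 else "homozygous"


@dataclass
class GroundTruth:
    """Provenance of every planted record, keyed for JSON round-trip."""

    variants: dict[str, dict] = field(default_factory=dict)
    mst: dict[str, dict] = field(default_factory=dict)  # "locus|sample" -> genotype
    de_genes: dict[str, dict] = field(default_factory=dict)

    @staticmethod
    def variant_key(v: Variant) -> str:
        return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"

    @staticmethod
    def mst_key(locus_id: str, sample_id: str) -> str:
        return f"{locus_id}|{sample_id}"

    def truth_genotype(self, locus_id: str, sample_id: str) -> TruthMstGenotype:
        raw = self.mst[self.mst_key(locus_id, sample_id)]
        return TruthMstGenotype(alleles=tuple(raw["alleles"]), minor=raw["minor"])

    def variants_with_label(self, label: str) -> list[str]:
        return sorted(k for k, v in self.variants.items() if v["label"] == label)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"variants": self.variants, "mst": self.mst, "de_genes": self.de_genes},
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(variants=raw["variants"], mst=raw["mst"], de_genes=raw["de_genes"])


# ---------------------------------------------------------------------------
# reference + microsatellite loci
# ---------------------------------------------------------------------------


def _random_primitive_motif(rng: np.random.Generator, k: int) -> str:
    from .microsatellites import _minimal_period

    while True:
        motif = "".join(rng.choice(BASES, size=k))
        if _minimal_period(motif) == k:
            return motif


def _base_not(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return str(rng.choice(choices))


def simulate_reference(
    config: SimulationConfig, chrom: str = "chr1", max_attempts: int = 10
) -> tuple[str, list[MstLocus]]:
    """Random reference with planted, rediscoverable tandem repeats.

    Plants ``n_mst_loci`` unique loci plus ``n_ambiguous_mst_pairs``
    pairs that deliberately share a motif and identical flanks (to
    exercise the ambiguity filter).  Bases adjacent to each tract are
    forced to break the repeat periodicity so planted boundaries are
    exact; the assembled sequence is then re-scanned and planting is
    retried if any locus fails to come back exactly (background repeats
    can in rare layouts absorb a planted tract).
    """
    n_total = config.n_mst_loci + 2 * config.n_ambiguous_mst_pairs
    params = ScanParams(flank=config.mst_flank)
    slot = config.genome_length // max(n_total, 1)
    max_tract = 6 * 15  # longest plantable tract
    if n_total and slot < max_tract + 2 * config.mst_flank + 4:
        raise ValueError(
            f"cannot place {n_total} microsatellite loci without overlap in "
            f"{config.genome_length} bp (need ~{max_tract + 2 * config.mst_flank + 4} bp per locus)"
        )

    for attempt in range(max_attempts):
        rng = config.rng(10 + attempt)
        seq = rng.choice(BASES, size=config.genome_length)
        planted: list[MstLocus] = []

        specs: list[dict] = []
        for _ in range(config.n_mst_loci):
            k = int(rng.integers(1, 7))
            copies = int(rng.integers(max(3, -(-12 // k)), 16))
            specs.append({"motif": _random_primitive_motif(rng, k), "copies": copies, "pair": None})
        for pair_idx in range(config.n_ambiguous_mst_pairs):
            k = int(rng.integers(1, 4))
            motif = _random_primitive_motif(rng, k)
            lo_copies = max(3, -(-12 // k))
            c1 = int(rng.integers(lo_copies, lo_copies + 8))
            c2 = c1 + int(rng.integers(3, 7))
            flank5 = "".join(rng.choice(BASES, size=config.mst_flank))
            flank5 = flank5[:-1] + _base_not(rng, motif[-1])
            flank3 = _base_not(rng, motif[0]) + "".join(rng.choice(BASES, size=config.mst_flank - 1))
            for copies in (c1, c2):
                specs.append(
                    {"motif": motif, "copies": copies, "pair": pair_idx,
                     "flank5": flank5, "flank3": flank3}
                )

        order = rng.permutation(len(specs))
        ok = True
        for slot_idx, spec_idx in enumerate(order):
            spec = specs[spec_idx]
            motif, copies = spec["motif"], spec["copies"]
            tract = motif * copies
            lo = slot_idx * slot + config.mst_flank + 1
            hi = (slot_idx + 1) * slot - len(tract) - config.mst_flank - 1
            if hi <= lo:
                ok = False
                break
            start = int(rng.integers(lo, hi))
            end = start + len(tract)
            seq[start:end] = list(tract)
            if spec["pair"] is not None:
                seq[start - config.mst_flank : start] = list(spec["flank5"])
                seq[end : end + config.mst_flank] = list(spec["flank3"])
            else:
                seq[start - 1] = _base_not(rng, motif[-1], str(seq[start - 1]))
                seq[end] = _base_not(rng, motif[0], str(seq[end]))
            planted.append(
                MstLocus(
                    chrom=chrom, start=start, end=end, motif=motif, copies=float(copies),
                    flank5="".join(seq[start - config.mst_flank : start]),
                    flank3="".join(seq[end : end + config.mst_flank]),
                )
            )
        if not ok:
            continue

        sequence = "".join(seq)
        found = {(l.start, l.end, canonical_motif(l.motif)) for l in scan_microsatellites(sequence, params, chrom)}
        if all((l.start, l.end, l.canonical) in found for l in planted):
            planted.sort(key=lambda l: l.start)
            return sequence, planted

    raise RuntimeError(
        f"could not plant {n_total} non-overlapping rediscoverable microsatellite "
        f"loci in {config.genome_length} bp after {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# variants + coverage
# ---------------------------------------------------------------------------


def _draw_variant(rng: np.random.Generator, chrom: str, pos: int, is_snp: bool) -> Variant:
    ref_base = str(rng.choice(BASES))
    if is_snp:
        alt = _base_not(rng, ref_base)
        return Variant(chrom, pos, ref_base, alt)
    length = int(rng.integers(1, 11))
    tail = "".join(rng.choice(BASES, size=length))
    if rng.random() < 0.5:  # insertion
        return Variant(chrom, pos, ref_base, ref_base + tail)
    return Variant(chrom, pos, ref_base + tail, ref_base)


def _draw_impact(rng: np.random.Generator) -> Impact:
    cats = list(IMPACT_WEIGHTS)
    probs = np.array(list(IMPACT_WEIGHTS.values()))
    return cats[int(rng.choice(len(cats), p=probs / probs.sum()))]


def simulate_variants(
    design: StudyDesign, config: SimulationConfig, chrom: str = "chr1"
) -> tuple[dict[str, set[AnnotatedVariant]], dict[str, CoverageProfile], GroundTruth]:
    """Per-sample annotated variant sets, coverage profiles and truth.

    Ancestral variants appear in every sample, group-specific variants
    in both members of one group, replicate-specific variants in
    exactly one sample.  The SNP/INDEL mix of the non-ancestral
    variants follows the per-group ratio (the case group accumulates
    proportionally more INDELs).  Coverage at each variant position is
    Poisson around ``mean_depth``; samples carrying the variant draw
    alternate-read counts binomially at ``alt_read_fraction``, samples
    without it observe zero alternate reads.
    """
    rng = config.rng(1)
    truth = GroundTruth()
    ratios = {
        design.case_group: config.snp_indel_ratio_case,
        design.control_group: config.snp_indel_ratio_control,
    }

    n_total = (
        config.n_ancestral_snps
        + config.n_ancestral_indels
        + config.n_group_specific * len(design.groups)
        + config.n_replicate_specific * len(design.samples)
    )
    positions = rng.choice(config.genome_length - 20, size=n_total, replace=False) + 1
    pos_iter = iter(int(p) for p in positions)

    def plant(is_snp: bool, samples: tuple[str, ...], label: str) -> AnnotatedVariant:
        v = _draw_variant(rng, chrom, next(pos_iter), is_snp)
        impact = _draw_impact(rng)
        gene = f"GENE{v.pos // 1000:05d}"
        truth.variants[GroundTruth.variant_key(v)] = {
            "label": label,
            "samples": list(samples),
            "vtype": v.vtype,
            "impact": impact.value,
            "gene": gene,
        }
        return AnnotatedVariant(v, impact=impact, gene=gene)

    variant_sets: dict[str, set[AnnotatedVariant]] = {s: set() for s in design.samples}

    for _ in range(config.n_ancestral_snps):
        av = plant(True, design.samples, "ancestral")
        for s in design.samples:
            variant_sets[s].add(av)
    for _ in range(config.n_ancestral_indels):
        av = plant(False, design.samples, "ancestral")
        for s in design.samples:
            variant_sets[s].add(av)

    for group, members in design.groups.items():
        for _ in range(config.n_group_specific):
            av = plant(bool(rng.random() < ratios[group]), members, f"group:{group}")
            for s in members:
                variant_sets[s].add(av)

    for sample in design.samples:
        ratio = ratios[design.group_of(sample)]
        for _ in range(config.n_replicate_specific):
            av = plant(bool(rng.random() < ratio), (sample,), f"replicate:{sample}")
            variant_sets[sample].add(av)

    # coverage over the union of all planted positions
    all_variants = {
        key: data for key, data in truth.variants.items()
    }
    profiles: dict[str, CoverageProfile] = {}
    for sample in design.samples:
        prof = CoverageProfile(sample_id=sample)
        for key, data in all_variants.items():
            v_chrom, v_pos, _ref, alt = key.split(":")
            pos = int(v_pos)
            depth = int(rng.poisson(config.mean_depth))
            counts: dict[str, int] = {}
            if sample in data["samples"] and depth > 0:
                counts[alt] = int(rng.binomial(depth, config.alt_read_fraction))
            prof.add(v_chrom, pos, depth, counts)
        profiles[sample] = prof

    return variant_sets, profiles, truth


# ---------------------------------------------------------------------------
# microsatellite genotypes + read observations
# ---------------------------------------------------------------------------


def simulate_mst_genotypes(
    design: StudyDesign, loci: list[MstLocus], config: SimulationConfig
) -> dict[tuple[str, str], TruthMstGenotype]:
    """Assign a true genotype (and optional minor allele) per locus/sample.

    A fraction ``het_fraction`` of locus/sample genotypes are
    heterozygous (second allele offset by 1-2 repeat copies); a
    fraction ``minor_allele_fraction`` additionally carry a planted
    low-frequency minor allele 4 copies above the longest true allele,
    emulating a subclonal tract-length mutation.
    """
    rng = config.rng(2)
    genotypes: dict[tuple[str, str], TruthMstGenotype] = {}
    for locus in loci:
        ref_len = int(round(locus.copies))
        for sample in design.samples:
            if rng.random() < config.het_fraction:
                offset = int(rng.choice([-2, -1, 1, 2]))
                second = max(2, ref_len + offset)
                if second == ref_len:
                    second = ref_len + abs(offset)
                alleles = tuple(sorted((ref_len, second)))
            else:
                alleles = (ref_len,)
            minor = max(alleles) + 4 if rng.random() < config.minor_allele_fraction else None
            genotypes[(locus.locus_id, sample)] = TruthMstGenotype(alleles=alleles, minor=minor)
    return genotypes


def simulate_mst_reads(
    loci: list[MstLocus],
    genotypes: dict[tuple[str, str], TruthMstGenotype],
    config: SimulationConfig,
) -> dict[tuple[str, str], dict[int, int]]:
    """Per-locus, per-sample multisets of observed repeat-tract lengths.

    Depth is Poisson(``mean_depth``).  Each read reports one true
    allele (uniformly among the 1-2 alleles), or the planted minor
    allele with probability ``minor_read_fraction`` where one exists;
    the reported length then slips by +/-1 repeat copy with probability
    ``length_error_rate``.
    """
    rng = config.rng(3)
    observations: dict[tuple[str, str], dict[int, int]] = {}
    for locus in loci:
        for (locus_id, sample), gt in (
            ((locus.locus_id, s), genotypes.get((locus.locus_id, s)))
            for s in sorted({k[1] for k in genotypes})
        ):
            if gt is None:
                continue
            depth = int(rng.poisson(config.mean_depth))
            counts: dict[int, int] = {}
            for _ in range(depth):
                if gt.minor is not None and rng.random() < config.minor_read_fraction:
                    length = gt.minor
                else:
                    length = int(gt.alleles[int(rng.integers(len(gt.alleles)))])
                if rng.random() < config.length_error_rate:
                    length += int(rng.choice([-1, 1]))
                length = max(1, length)
                counts[length] = counts.get(length, 0) + 1
            observations[(locus_id, sample)] = counts
    return observations


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    design: StudyDesign, config: SimulationConfig
) -> tuple[list[GeneExpressionRecord], GroundTruth]:
    """Gene table with planted cross-group differential expression.

    Baseline FPKM is log-normal; genes selected as differentially
    expressed get a ``de_log2fc`` shift (random direction) applied to
    the second (control/corrected) group.  Cross-group p-values of DE
    genes are drawn small (log-uniform 1e-6..~3e-3); all other
    p-values are uniform.  With ``noiseless_p`` the p-values are fixed
    (0.001 cross / 0.9 within for DE genes, 0.5 elsewhere) so the
    consensus rule can be tested free of sampling noise.
    """
    rng = config.rng(4)
    truth = GroundTruth()
    gene_ids = [f"G{idx:05d}" for idx in range(config.n_genes)]
    de_idx = set(map(int, rng.choice(config.n_genes, size=config.n_de_genes, replace=False)))
    g1, g2 = design.group_labels
    records: list[GeneExpressionRecord] = []
    for idx, gid in enumerate(gene_ids):
        is_de = idx in de_idx
        base = float(rng.lognormal(mean=2.0, sigma=1.0))
        direction = int(rng.choice([-1, 1])) if is_de else 0
        fpkm: dict[str, float] = {}
        for sample in design.samples:
            value = base * float(2.0 ** rng.normal(0.0, 0.1))
            if is_de and design.group_of(sample) == g2:
                value *= float(2.0 ** (direction * config.de_log2fc))
            if rng.random() < config.expression_dropout:
                value = 0.0
            fpkm[sample] = round(value, 4)

        p_values: dict[tuple[str, str], float] = {}
        for a, b in design.sample_pairs():
            cross = design.group_of(a) != design.group_of(b)
            if config.noiseless_p:
                p = 0.001 if (is_de and cross) else (0.9 if is_de else 0.5)
            elif is_de and cross:
                p = float(10.0 ** -rng.uniform(2.5, 6.0))
            else:
                p = float(rng.uniform())
            p_values[(a, b)] = p

        e_base = int(rng.integers(2, 20))
        rep = int(rng.random() < config.exon_var_within)
        grp = int(rng.random() < config.exon_var_cross)
        members1, members2 = design.groups[g1], design.groups[g2]
        exon_counts = {members1[0]: e_base, members2[0]: e_base + grp}
        if len(members1) > 1:
            exon_counts[members1[1]] = e_base + rep
        if len(members2) > 1:
            exon_counts[members2[1]] = e_base + rep + grp

        if is_de:
            truth.de_genes[gid] = {"direction": g2 if direction > 0 else g1}
        records.append(GeneExpressionRecord(gid, fpkm, p_values, exon_counts))
    return records, truth


# ---------------------------------------------------------------------------
# one-call output writer
# ---------------------------------------------------------------------------


def simulate_all(
    design: StudyDesign, config: SimulationConfig, outdir: str | Path, chrom: str = "chr1"
) -> dict[str, Path]:
    """Generate every pipeline input under ``outdir``; returns paths.

    Writes the reference FASTA, planted-locus BED, per-sample VCF and
    coverage TSV, microsatellite observation TSV, expression TSV and a
    ``truth.json`` sidecar holding all planted ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sequence, loci = simulate_reference(config, chrom=chrom)
    fasta = outdir / "reference.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), 80):
            fh.write(sequence[i : i + 80] + "\n")
    paths["reference"] = fasta
    bed = outdir / "mst_loci.bed"
    write_loci_bed(loci, bed)
    paths["mst_loci"] = bed

    variant_sets, profiles, truth = simulate_variants(design, config, chrom=chrom)
    contigs = {chrom: config.genome_length}
    for sample in design.samples:
        vcf = outdir / f"{sample}.vcf"
        write_vcf(variant_sets[sample], vcf, contigs, sample_id=sample)
        paths[f"vcf:{sample}"] = vcf
        cov = outdir / f"{sample}.cov.tsv"
        profiles[sample].to_tsv(cov)
        paths[f"coverage:{sample}"] = cov

    genotypes = simulate_mst_genotypes(design, loci, config)
    observations = simulate_mst_reads(loci, genotypes, config)
    obs_path = outdir / "mst_observations.tsv"
    write_observations_tsv(observations, obs_path)
    paths["mst_observations"] = obs_path
    for (locus_id, sample), gt in genotypes.items():
        truth.mst[GroundTruth.mst_key(locus_id, sample)] = {
            "alleles": list(gt.alleles),
            "minor": gt.minor,
        }

    records, expr_truth = simulate_expression(design, config)
    expr_path = outdir / "expression.tsv"
    write_expression_tsv(design, records, expr_path)
    paths["expression"] = expr_path
    truth.de_genes = expr_truth.de_genes

    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path

    design_path = outdir / "design.yaml"
    design.to_yaml(design_path)
    paths["design"] = design_path

    config_path = outdir / "config.json"
    with open(config_path, "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
    paths["config"] = config_path
    return paths
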