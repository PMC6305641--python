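"""Pipeline orchestration, ground-truth scoring and the run manifest.

``run_pipeline`` wires the stages together on a directory of inputs
(typically written by :func:`fadiv.simulate.simulate_all`, but any
files in the documented formats work): variant sharing and composition
tables, the coverage-gated specific-SNP matrix, microsatellite
discovery/filtering/genotyping summaries, and the expression
consensus.  Every threshold in force is logged at INFO so a run is
auditable, and a manifest records digests of all outputs so a rerun
can be verified byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from . import __version__
from ._util import round_half_away, sha256_file
from .coverage import CoverageProfile
from .design import StudyDesign
from .expression import (
    consensus_de,
    exon_count_variation,
    pairwise_de_counts,
    read_expression_tsv,
    write_de_table,
)
from .microsatellites import (
    GenotypeThresholds,
    ScanParams,
    filter_ambiguous,
    genotype_locus,
    group_mean_percent,
    mst_summary,
    read_observations_tsv,
    scan_microsatellites,
    write_loci_bed,
)
from .sharing import high_impact_gene_sets, sharing_summary, write_sharing_tables
from .simulate import GroundTruth
from .specific import specific_snp_matrix
from .variants import load_variants

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "truth_report"]


@dataclass
class RunManifest:
    version: str
    design: dict
    thresholds: dict
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


DEFAULT_THRESHOLDS = {
    "specific_min_depth": 10,
    "specific_min_alt_reads": 3,
    "mst_callable_min_reads": 10,
    "mst_minor_min_reads": 3,
    "mst_het_min_frac": 0.30,
    "de_alpha": 0.05,
    "indel_size_range_bp": [1, 10],
}


def run_pipeline(
    design: StudyDesign,
    input_dir: str | Path,
    outdir: str | Path,
    alpha: float = 0.05,
) -> dict[str, Path]:
    """Run every stage on a directory of inputs; returns output paths.

    Expected inputs under ``input_dir``: ``<sample>.vcf`` and
    ``<sample>.cov.tsv`` per sample, ``reference.fa``,
    ``mst_observations.tsv`` and ``expression.tsv``; ``truth.json``
    (optional) triggers the ground-truth report.
    """
    input_dir, outdir = Path(input_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {input_dir}")
    for key, value in DEFAULT_THRESHOLDS.items():
        logger.info("threshold %s = %s", key, value)
    logger.info("de_alpha overridden to %s", alpha) if alpha != 0.05 else None

    manifest = RunManifest(
        version=__version__,
        design={g: list(m) for g, m in design.groups.items()},
        thresholds={**DEFAULT_THRESHOLDS, "de_alpha": alpha},
    )
    outputs: dict[str, Path] = {}

    # --- variants -------------------------------------------------------
    variant_sets, profiles = {}, {}
    for sample in design.samples:
        vcf = input_dir / f"{sample}.vcf"
        if not vcf.exists():
            raise FileNotFoundError(f"missing VCF for sample {sample}: {vcf}")
        vset, stats = load_variants(vcf)
        logger.info(
            "%s: %d records in = %d kept + %d excluded",
            sample, stats.n_records, stats.n_kept, stats.n_excluded,
        )
        variant_sets[sample] = vset
        manifest.inputs[f"vcf:{sample}"] = sha256_file(vcf)
        cov = input_dir / f"{sample}.cov.tsv"
        if not cov.exists():
            raise FileNotFoundError(f"missing coverage TSV for sample {sample}: {cov}")
        profiles[sample] = CoverageProfile.from_tsv(cov, sample_id=sample)
        manifest.inputs[f"coverage:{sample}"] = sha256_file(cov)

    outputs.update(write_sharing_tables(design, variant_sets, outdir))
    case_genes, common_genes = high_impact_gene_sets(design, variant_sets)
    gene_path = outdir / "high_impact_genes.tsv"
    pd.DataFrame(
        [("case_specific", g) for g in case_genes] + [("common", g) for g in common_genes],
        columns=["set", "gene"],
    ).to_csv(gene_path, sep="\t", index=False)
    outputs["high_impact_genes"] = gene_path

    matrix = specific_snp_matrix(design, variant_sets, profiles)
    matrix_path = outdir / "specific_matrix.tsv"
    matrix.to_tsv(matrix_path)
    outputs["specific_matrix"] = matrix_path

    # --- microsatellites ------------------------------------------------
    ref_path = input_dir / "reference.fa"
    obs_path = input_dir / "mst_observations.tsv"
    genotypes_by_sample: dict[str, list] = {}
    if ref_path.exists() and obs_path.exists():
        fasta = Fasta(str(ref_path))
        loci = []
        for name in fasta.keys():
            loci.extend(scan_microsatellites(str(fasta[name][:]), ScanParams(), chrom=name))
        kept, removed = filter_ambiguous(loci)
        logger.info("MST scan: %d loci = %d kept + %d ambiguous", len(loci), len(kept), len(removed))
        loci_path = outdir / "mst_loci_filtered.bed"
        write_loci_bed(kept, loci_path)
        outputs["mst_loci_filtered"] = loci_path
        manifest.inputs["reference"] = sha256_file(ref_path)

        observations = read_observations_tsv(obs_path)
        manifest.inputs["mst_observations"] = sha256_file(obs_path)
        kept_ids = {l.locus_id for l in kept}
        thresholds = GenotypeThresholds()
        geno_rows = []
        for (locus_id, sample), counts in sorted(observations.items()):
            if locus_id not in kept_ids:
                continue
            gt = genotype_locus(counts, locus_id=locus_id, sample_id=sample, thresholds=thresholds)
            genotypes_by_sample.setdefault(sample, []).append(gt)
            geno_rows.append(
                {
                    "locus_id": locus_id,
                    "sample_id": sample,
                    "callable": gt.callable,
                    "primary": gt.primary if gt.primary is not None else "",
                    "secondary": gt.secondary if gt.secondary is not None else "",
                    "minor_alleles": ",".join(map(str, gt.minor_alleles)),
                }
            )
        geno_path = outdir / "mst_genotypes.tsv"
        pd.DataFrame(geno_rows).to_csv(geno_path, sep="\t", index=False)
        outputs["mst_genotypes"] = geno_path

        summary_rows = []
        for sample in design.samples:
            summ = mst_summary(genotypes_by_sample.get(sample, []), sample_id=sample)
            summary_rows.append(
                {
                    "sample": sample,
                    "group": design.group_of(sample),
                    "callable_mst": summ.n_callable,
                    "homozygous_pct": summ.pct_homozygous,
                    "heterozygous_pct": summ.pct_heterozygous,
                    "minor_allele_pct": summ.pct_minor,
                }
            )
        summary_path = outdir / "mst_summary.tsv"
        pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
        outputs["mst_summary"] = summary_path

    # --- expression -----------------------------------------------------
    expr_path = input_dir / "expression.tsv"
    de_calls = []
    records = []
    if expr_path.exists():
        records = read_expression_tsv(design, expr_path)
        manifest.inputs["expression"] = sha256_file(expr_path)
        de_calls, uncallable = consensus_de(design, records, alpha=alpha)
        n_de = sum(1 for c in de_calls if c.is_de)
        logger.info(
            "expression: %d genes = %d callable + %d uncallable; %d consensus DE",
            len(records), len(de_calls), len(uncallable), n_de,
        )
        de_path = outdir / "de_genes.tsv"
        write_de_table(design, de_calls, records, de_path)
        outputs["de_genes"] = de_path

        counts = pairwise_de_counts(design, records, alpha=alpha)
        counts_path = outdir / "pairwise_de_counts.tsv"
        counts.to_csv(counts_path, sep="\t")
        outputs["pairwise_de_counts"] = counts_path

        variation = exon_count_variation(design, records)
        exon_path = outdir / "exon_variation.tsv"
        pd.DataFrame(
            [
                {
                    "scope": "cross_group",
                    "pct_varying": round_half_away(100 * variation.cross_fraction, 1),
                },
                {
                    "scope": "within_group",
                    "pct_varying": round_half_away(100 * variation.within_fraction, 1),
                },
            ]
        ).to_csv(exon_path, sep="\t", index=False)
        outputs["exon_variation"] = exon_path

    # --- truth report ---------------------------------------------------
    truth_path = input_dir / "truth.json"
    if truth_path.exists():
        report = truth_report(
            design,
            variant_sets=variant_sets,
            genotypes_by_sample=genotypes_by_sample,
            de_calls=de_calls,
            truth=GroundTruth.from_json(truth_path),
        )
        report_path = outdir / "truth_report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        outputs["truth_report"] = report_path

    for name, path in outputs.items():
        manifest.outputs[name] = sha256_file(path)
    manifest_path = outdir / "manifest.json"
    manifest.to_json(manifest_path)
    outputs["manifest"] = manifest_path
    return outputs


def truth_report(
    design: StudyDesign,
    variant_sets: dict,
    genotypes_by_sample: dict,
    de_calls: list,
    truth: GroundTruth,
) -> dict:
    """Recall/precision of pipeline outputs against planted truth."""
    report: dict = {}

    # variants: is each planted variant recovered in exactly its samples?
    from .simulate import GroundTruth as GT  # for key helper

    observed: dict[str, set[str]] = {}
    for sample, vset in variant_sets.items():
        for av in vset:
            observed.setdefault(GT.variant_key(av.variant), set()).add(sample)
    by_label: dict[str, dict[str, int]] = {}
    for key, data in truth.variants.items():
        label = data["label"].split(":")[0]
        tally = by_label.setdefault(label, {"planted": 0, "exact": 0})
        tally["planted"] += 1
        if observed.get(key, set()) == set(data["samples"]):
            tally["exact"] += 1
    n_spurious = len(set(observed) - set(truth.variants))
    report["variants"] = {
        label: {
            **tally,
            "recall": tally["exact"] / tally["planted"] if tally["planted"] else None,
        }
        for label, tally in by_label.items()
    }
    report["variants"]["spurious"] = n_spurious

    # MST zygosity + minor alleles, over callable loci only
    if truth.mst and genotypes_by_sample:
        n_callable = n_zyg_correct = n_minor_true = n_minor_found = 0
        for sample, genotypes in genotypes_by_sample.items():
            for gt in genotypes:
                key = GT.mst_key(gt.locus_id, gt.sample_id)
                if key not in truth.mst or not gt.callable:
                    continue
                n_callable += 1
                true_gt = truth.truth_genotype(gt.locus_id, gt.sample_id)
                if gt.zygosity == true_gt.zygosity:
                    n_zyg_correct += 1
                if true_gt.minor is not None:
                    n_minor_true += 1
                    if true_gt.minor in gt.minor_alleles:
                        n_minor_found += 1
        report["mst"] = {
            "callable": n_callable,
            "zygosity_accuracy": n_zyg_correct / n_callable if n_callable else None,
            "minor_recall": n_minor_found / n_minor_true if n_minor_true else None,
        }

    # DE consensus
    if truth.de_genes:
        called = {c.gene_id for c in de_calls if c.is_de}
        planted = set(truth.de_genes)
        tp = len(called & planted)
        report["de"] = {
            "planted": len(planted),
            "called": len(called),
            "recall": tp / len(planted) if planted else None,
            "precision": tp / len(called) if called else None,
        }
    return report
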