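"""Variant-sharing algebra across a two-group replicate design.

Given per-sample variant sets, these operations compute how many
variants recur within each replicate group and across all samples, the
SNP:INDEL composition of each sample, and the gene sets hit by
high-impact variants either case-specifically or in every sample.
Sharing fractions use the arithmetic mean of the per-sample counts as
denominator, rounded to the nearest integer percent (ties away from
zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from pathlib import Path

import pandas as pd

from ._util import round_half_away, round_int
from .design import StudyDesign
from .variants import AnnotatedVariant, Impact

__all__ = [
    "SharingSummary",
    "shared_fraction",
    "sharing_summary",
    "snp_indel_ratio",
    "high_impact_gene_sets",
]


def shared_fraction(shared_count: int, per_sample_counts: list[int]) -> int:
    """Percent of the mean per-sample load that is shared.

    ``round(100 * shared / mean(counts))`` with ties away from zero;
    this is the statistic quoted as "X% of loci were commonly callable".
    """
    if not per_sample_counts or sum(per_sample_counts) == 0:
        raise ValueError("per-sample counts must be non-empty and non-zero")
    mean = sum(per_sample_counts) / len(per_sample_counts)
    return round_int(100.0 * shared_count / mean)


def snp_indel_ratio(n_snp: int, n_indel: int) -> tuple[float, float]:
    """SNP:INDEL composition as a one-decimal pair summing to 10.

    e.g. 205,613 SNPs and 28,631 INDELs -> ``(8.8, 1.2)``.
    """
    total = n_snp + n_indel
    if total <= 0:
        raise ValueError("need at least one variant to form a ratio")
    return (
        round_half_away(10.0 * n_snp / total, 1),
        round_half_away(10.0 * n_indel / total, 1),
    )


@dataclass
class SharingSummary:
    """Counts of variant recurrence for one variant type (or all types)."""

    vtype: str | None
    per_sample: dict[str, int]
    per_group_shared: dict[str, int]
    shared_in_all: int
    per_group_shared_pct: dict[str, int]
    shared_in_all_pct: int

    def to_frame(self, design: StudyDesign) -> pd.DataFrame:
        rows = []
        for group, members in design.groups.items():
            for sample in members:
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "variant_count": self.per_sample[sample],
                        "repeated_in_replicates": self.per_group_shared[group],
                        "repeated_in_all": self.shared_in_all,
                    }
                )
        return pd.DataFrame(rows)


def _variant_keys(vset: set[AnnotatedVariant], vtype: str | None) -> set:
    return {
        av.variant.key
        for av in vset
        if vtype is None or av.vtype == vtype
    }


def sharing_summary(
    design: StudyDesign,
    variant_sets: dict[str, set[AnnotatedVariant]],
    vtype: str | None = None,
) -> SharingSummary:
    """Per-sample, within-group and all-sample sharing counts.

    Variant identity is the exact ``(chrom, pos, ref, alt)`` tuple.
    ``vtype`` restricts to ``"SNP"`` or ``"INDEL"``; ``None`` keeps all.
    """
    missing = set(design.samples) - set(variant_sets)
    if missing:
        raise KeyError(f"variant sets missing for samples: {sorted(missing)}")
    keys = {s: _variant_keys(variant_sets[s], vtype) for s in design.samples}
    per_sample = {s: len(k) for s, k in keys.items()}
    per_group_shared = {
        g: len(reduce(set.intersection, (keys[s] for s in members)))
        for g, members in design.groups.items()
    }
    shared_all = len(reduce(set.intersection, (keys[s] for s in design.samples)))
    per_group_pct = {
        g: shared_fraction(per_group_shared[g], [per_sample[s] for s in members])
        for g, members in design.groups.items()
    }
    all_pct = shared_fraction(shared_all, [per_sample[s] for s in design.samples])
    return SharingSummary(
        vtype=vtype,
        per_sample=per_sample,
        per_group_shared=per_group_shared,
        shared_in_all=shared_all,
        per_group_shared_pct=per_group_pct,
        shared_in_all_pct=all_pct,
    )


def high_impact_gene_sets(
    design: StudyDesign,
    variant_sets: dict[str, set[AnnotatedVariant]],
) -> tuple[list[str], list[str]]:
    """Gene sets hit by HIGH-impact variants: (case-specific, common).

    A gene is *case-specific* if it carries a HIGH-impact variant seen in
    at least one case-group sample and in no control-group sample; it is
    *common* if it carries a HIGH-impact variant present in every sample.
    Both lists are sorted; a gene can appear in both (via different
    variants).  Variants without a gene symbol are ignored.
    """
    case_samples = design.groups[design.case_group]
    control_samples = design.groups[design.control_group]

    presence: dict[tuple, dict[str, set[str]]] = {}
    gene_of: dict[tuple, str] = {}
    for sample, vset in variant_sets.items():
        for av in vset:
            if av.impact is not Impact.HIGH or not av.gene:
                continue
            entry = presence.setdefault(av.variant.key, {"samples": set()})
            entry["samples"].add(sample)
            gene_of[av.variant.key] = av.gene

    case_specific: set[str] = set()
    common: set[str] = set()
    for key, entry in presence.items():
        samples = entry["samples"]
        if samples & set(case_samples) and not samples & set(control_samples):
            case_specific.add(gene_of[key])
        if set(design.samples) <= samples:
            common.add(gene_of[key])
    return sorted(case_specific), sorted(common)


def write_sharing_tables(
    design: StudyDesign,
    variant_sets: dict[str, set[AnnotatedVariant]],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the sharing summary and ratio tables; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for vtype in ("INDEL", "SNP"):
        summ = sharing_summary(design, variant_sets, vtype)
        df = summ.to_frame(design)
        df.insert(0, "variant_type", vtype)
        frames.append(df)
    sharing_path = outdir / "sharing_summary.tsv"
    pd.concat(frames, ignore_index=True).to_csv(sharing_path, sep="\t", index=False)

    rows = []
    for sample in design.samples:
        n_snp = len(_variant_keys(variant_sets[sample], "SNP"))
        n_indel = len(_variant_keys(variant_sets[sample], "INDEL"))
        r_snp, r_indel = snp_indel_ratio(n_snp, n_indel)
        rows.append(
            {
                "sample": sample,
                "group": design.group_of(sample),
                "total_variants": n_snp + n_indel,
                "snp": n_snp,
                "indel": n_indel,
                "snp_indel_ratio": f"{r_snp}:{r_indel}",
            }
        )
    ratio_path = outdir / "ratio.tsv"
    pd.DataFrame(rows).to_csv(ratio_path, sep="\t", index=False)
    return {"sharing_summary": sharing_path, "ratio": ratio_path}
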