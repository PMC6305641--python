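"""Variant records and annotated-VCF input/output.

A variant is identified by its exact ``(chrom, pos, ref, alt)`` tuple;
no left-alignment or normalization pass is applied at load time, so
inputs are expected to be normalized upstream (e.g. by joint INDEL
realignment before calling).  Records are classified as SNPs
(single-base substitution) or INDELs with a length difference of
1-10 bp; anything else (MNPs, long structural alleles, symbolic alts)
is excluded and counted.

Functional-impact categories follow the four-level consequence scheme
used by SnpEff-style annotators (HIGH / MODERATE / LOW / MODIFIER),
read from the impact slot of an ``ANN=`` INFO subfield.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pysam

MAX_INDEL_BP = 10

__all__ = [
    "Impact",
    "Variant",
    "AnnotatedVariant",
    "VariantLoadStats",
    "MalformedVcfError",
    "classify_alleles",
    "load_variants",
    "write_vcf",
]


class Impact(str, enum.Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


class MalformedVcfError(ValueError):
    """Raised when a VCF record cannot be parsed; names the record number."""


def classify_alleles(ref: str, alt: str) -> str | None:
    """Classify a ref/alt pair as ``"SNP"``, ``"INDEL"`` or ``None``.

    SNP: both alleles a single base.  INDEL: absolute length difference
    of 1-10 bp.  Equal-length multi-base substitutions (MNPs) and longer
    events return ``None`` and are excluded from analysis.
    """
    if not ref or not alt or not alt[0].isalpha():
        return None
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    diff = abs(len(ref) - len(alt))
    if 1 <= diff <= MAX_INDEL_BP:
        return "INDEL"
    return None


@dataclass(frozen=True, order=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    @property
    def vtype(self) -> str:
        vt = classify_alleles(self.ref, self.alt)
        if vt is None:
            raise ValueError(f"unclassifiable alleles {self.ref}>{self.alt}")
        return vt

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True, order=True)
class AnnotatedVariant:
    variant: Variant
    impact: Impact = Impact.MODIFIER
    gene: str = ""

    @property
    def vtype(self) -> str:
        return self.variant.vtype


@dataclass
class VariantLoadStats:
    """Bookkeeping from a VCF load: records in = kept + excluded."""

    n_records: int = 0
    n_kept: int = 0
    n_excluded: int = 0
    n_missing_impact: int = 0
    excluded: list[tuple[str, int, str, str]] = field(default_factory=list)


def _parse_ann(info, alt: str) -> tuple[Impact, str] | None:
    """Extract (impact, gene) for ``alt`` from an ANN-style INFO field.

    ANN entries are pipe-delimited: ``Allele|Annotation|Impact|Gene|...``.
    The first entry whose allele matches wins; if no allele matches, the
    first entry is used (single-annotation files often omit the allele).
    """
    try:
        raw = info["ANN"]
    except KeyError:
        return None
    entries = (raw,) if isinstance(raw, str) else tuple(raw)
    chosen = None
    for entry in entries:
        parts = entry.split("|")
        if len(parts) >= 3 and parts[0] == alt:
            chosen = parts
            break
    if chosen is None and entries:
        parts = entries[0].split("|")
        chosen = parts if len(parts) >= 3 else None
    if chosen is None:
        return None
    impact_txt = chosen[2].strip().upper()
    try:
        impact = Impact(impact_txt)
    except ValueError:
        return None
    gene = chosen[3].strip() if len(chosen) > 3 else ""
    return impact, gene


def load_variants(
    vcf_path: str | Path,
) -> tuple[set[AnnotatedVariant], VariantLoadStats]:
    """Load one annotated variant per ALT allele from a VCF file.

    Multi-allelic records are split into independent variants.  Records
    that are neither SNPs nor 1-10 bp INDELs are excluded and tallied.
    Variants without a parseable impact annotation are kept with impact
    MODIFIER and counted in ``n_missing_impact``.
    """
    stats = VariantLoadStats()
    out: set[AnnotatedVariant] = set()
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise MalformedVcfError(f"{vcf_path}: cannot open as VCF: {exc}") from exc
    with vf:
        record_no = 0
        iterator = iter(vf)
        while True:
            try:
                rec = next(iterator)
            except StopIteration:
                break
            except Exception as exc:  # pysam raises various types on bad rows
                raise MalformedVcfError(
                    f"{vcf_path}: malformed VCF record #{record_no + 1}: {exc}"
                ) from exc
            record_no += 1
            stats.n_records += 1
            ref = rec.ref or ""
            for alt in rec.alts or ():
                vt = classify_alleles(ref, alt)
                if vt is None:
                    stats.n_excluded += 1
                    stats.excluded.append((rec.chrom, rec.pos, ref, alt))
                    continue
                ann = _parse_ann(rec.info, alt)
                if ann is None:
                    stats.n_missing_impact += 1
                    impact, gene = Impact.MODIFIER, ""
                else:
                    impact, gene = ann
                out.add(
                    AnnotatedVariant(
                        Variant(rec.chrom, rec.pos, ref, alt), impact=impact, gene=gene
                    )
                )
                stats.n_kept += 1
    return out, stats


def write_vcf(
    variants: Iterable[AnnotatedVariant],
    path: str | Path,
    contigs: dict[str, int],
    sample_id: str | None = None,
) -> None:
    """Write annotated variants as an uncompressed VCF 4.2 text file.

    The impact category and gene symbol are carried in a minimal
    ANN-style INFO subfield (``Allele|custom|Impact|Gene``).
    """
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_line(
        '##INFO=<ID=ANN,Number=.,Type=String,'
        'Description="Functional annotations: Allele|Annotation|Annotation_Impact|Gene_Name">'
    )
    if sample_id is not None:
        header.add_line(f"##sample={sample_id}")
    ordered = sorted(variants, key=lambda av: (av.variant.chrom, av.variant.pos, av.variant.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for av in ordered:
            v = av.variant
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.info["ANN"] = f"{v.alt}|custom|{av.impact.value}|{av.gene}"
            out.write(rec)
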