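"""Coverage-gated pairwise detection of sample-specific SNPs.

A SNP is *specific to sample A relative to sample B* when the alternate
base is supported by at least ``min_alt`` reads (default 3) in A and by
zero reads in B, and the comparison is attempted only at positions
covered by at least ``min_depth`` reads (default 10) in *both* samples.
Positions failing the depth gate in either sample are uncallable and
reported separately rather than counted as absent.

For a multi-sample design every ordered pair is evaluated and each
unordered pair is summarized as the arithmetic mean of its two
directional counts ("A-specific vs B" and "B-specific vs A").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import round_half_away
from .coverage import CoverageProfile
from .design import StudyDesign
from .variants import AnnotatedVariant, Impact

__all__ = [
    "MIN_DEPTH",
    "MIN_ALT_READS",
    "SpecificSnpResult",
    "SpecificSnpMatrix",
    "specific_snps",
    "specific_snp_matrix",
]

MIN_DEPTH = 10
MIN_ALT_READS = 3


@dataclass
class SpecificSnpResult:
    """One directional comparison: SNPs specific to A, absent from B."""

    sample_a: str
    sample_b: str
    specific: list[AnnotatedVariant] = field(default_factory=list)
    skipped_low_depth: list[AnnotatedVariant] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.specific)


def _sort_key(av: AnnotatedVariant):
    return (av.variant.chrom, av.variant.pos, av.variant.alt)


def specific_snps(
    sample_a: str,
    sample_b: str,
    snps_a: set[AnnotatedVariant],
    cov_a: CoverageProfile,
    cov_b: CoverageProfile,
    min_depth: int = MIN_DEPTH,
    min_alt: int = MIN_ALT_READS,
) -> SpecificSnpResult:
    """SNPs of sample A that pass the specificity gates against sample B.

    Gates, applied per candidate SNP position: depth >= ``min_depth`` in
    both samples (else the position is skipped as uncallable); alternate
    reads >= ``min_alt`` in A; alternate reads == 0 in B.  "Not present
    even once" refers to reads supporting that alternate allele — other
    alternates observed in B at the position do not disqualify.
    """
    result = SpecificSnpResult(sample_a=sample_a, sample_b=sample_b)
    for av in sorted(snps_a, key=_sort_key):
        v = av.variant
        if v.vtype != "SNP":
            continue
        if cov_a.depth(v.chrom, v.pos) < min_depth or cov_b.depth(v.chrom, v.pos) < min_depth:
            result.skipped_low_depth.append(av)
            continue
        if cov_a.alt_count(v.chrom, v.pos, v.alt) >= min_alt and cov_b.alt_count(
            v.chrom, v.pos, v.alt
        ) == 0:
            result.specific.append(av)
    return result


@dataclass
class SpecificSnpMatrix:
    """Directional counts plus the symmetrized pairwise summary."""

    samples: list[str]
    directional: dict[tuple[str, str], SpecificSnpResult]

    def cell(self, a: str, b: str) -> float:
        """Mean of the two directional counts for an unordered pair."""
        if a == b:
            raise ValueError("diagonal cells are undefined")
        mean = (self.directional[(a, b)].count + self.directional[(b, a)].count) / 2.0
        return round_half_away(mean, 1)

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for a in self.samples:
            row = {}
            for b in self.samples:
                if a == b:
                    row[b] = None
                else:
                    cell = self.cell(a, b)
                    row[b] = int(cell) if cell == int(cell) else cell
            data[a] = row
        return pd.DataFrame(data).T.loc[self.samples, self.samples]

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample"
        df.to_csv(path, sep="\t", na_rep="-")


def specific_snp_matrix(
    design: StudyDesign,
    snp_sets: dict[str, set[AnnotatedVariant]],
    profiles: dict[str, CoverageProfile],
    min_depth: int = MIN_DEPTH,
    min_alt: int = MIN_ALT_READS,
    high_impact_only: bool = True,
) -> SpecificSnpMatrix:
    """Evaluate all ordered sample pairs of the design.

    ``high_impact_only`` pre-filters each sample's SNPs to impact HIGH
    before comparison (the usual reporting mode); set it False to run
    the comparison on all SNPs.
    """
    samples = list(design.samples)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    filtered: dict[str, set[AnnotatedVariant]] = {}
    for s in samples:
        vset = snp_sets[s]
        if high_impact_only:
            vset = {av for av in vset if av.impact is Impact.HIGH}
        filtered[s] = vset
    directional = {}
    for a in samples:
        for b in samples:
            if a == b:
                continue
            directional[(a, b)] = specific_snps(
                a, b, filtered[a], profiles[a], profiles[b], min_depth, min_alt
            )
    return SpecificSnpMatrix(samples=samples, directional=directional)
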