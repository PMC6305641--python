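"""Microsatellite (STR) discovery, ambiguity filtering and genotyping.

Discovery scans a reference sequence for maximal perfect tandem repeats
of motif length 1-6 (configurable).  Candidate repeats that overlap are
resolved to the longest (ties: smaller motif, then leftmost), so each
reported locus is an independent tract.  Motifs are canonicalized by
minimal lexicographic rotation; reverse complements are *not* merged —
the scan is single-strand with respect to the reference.

Two loci that share a motif and identical 5'/3' flanking sequences are
indistinguishable to short-read mapping; the ambiguity filter removes
*all* members of such a colliding group (e.g. both "GCTGC(A)34CTTAG"
and "GCTGC(A)15CTTAG"), not all-but-one.

Genotyping classifies a locus from the multiset of repeat-tract lengths
observed in spanning reads: a locus is callable with >= 10 reads; the
modal length is the primary allele; a second allele is called
(heterozygous) when the runner-up length carries at least
``het_min_frac`` of the reads (default 0.30) and at least 2 reads; any
further length supported by >= 3 reads is reported as a minor allele.
The 10-read callability and 3-read minor-allele gates are the standard
thresholds for this kind of read-count genotyping; the heterozygosity
fraction is this package's own default and is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import round_half_away

__all__ = [
    "MstLocus",
    "MstGenotype",
    "MstSummary",
    "ScanParams",
    "GenotypeThresholds",
    "canonical_motif",
    "scan_microsatellites",
    "filter_ambiguous",
    "genotype_locus",
    "mst_summary",
    "group_mean_percent",
    "write_loci_bed",
    "read_loci_bed",
    "write_observations_tsv",
    "read_observations_tsv",
]

CALLABLE_MIN_READS = 10
MINOR_MIN_READS = 3


def canonical_motif(motif: str) -> str:
    """Minimal lexicographic rotation of a motif (strand not merged)."""
    m = motif.upper()
    return min(m[i:] + m[:i] for i in range(len(m)))


def _minimal_period(s: str) -> int:
    """Smallest p such that s[i] == s[i-p] for all i >= p."""
    n = len(s)
    for p in range(1, n):
        if all(s[i] == s[i - p] for i in range(p, n)):
            return p
    return n


@dataclass(frozen=True)
class MstLocus:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    motif: str  # as it appears at `start`
    copies: float  # tract length / motif length (may be fractional)
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != round(self.copies * len(self.motif)):
            raise ValueError(
                f"inconsistent locus span {self.start}-{self.end} for "
                f"{self.copies} x {self.motif!r}"
            )

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def canonical(self) -> str:
        return canonical_motif(self.motif)

    @property
    def ambiguity_key(self) -> tuple[str, str, str]:
        return (self.canonical, self.flank5.upper(), self.flank3.upper())


@dataclass(frozen=True)
class ScanParams:
    max_motif: int = 6
    min_copies: float = 3.0
    min_total: int = 8  # minimum tract length in bp
    flank: int = 5  # flanking bases recorded for the ambiguity key


def scan_microsatellites(
    reference: str,
    params: ScanParams = ScanParams(),
    chrom: str = "chr1",
) -> list[MstLocus]:
    """All maximal perfect tandem repeats passing the length thresholds.

    A tract with period ``k`` is the maximal interval on which
    ``seq[i] == seq[i-k]`` holds; partial trailing copies are included,
    so ``copies`` may be fractional.  Tracts whose repeat unit is itself
    periodic (e.g. "ATAT" with k=4) are reported once, at the primitive
    period.  Overlapping tracts of different periods are resolved to the
    longest, ties to the smaller motif, then leftmost.
    """
    seq = str(reference).upper()
    n = len(seq)
    if n == 0:
        raise ValueError("reference sequence is empty")
    candidates: list[tuple[int, int, int]] = []  # (start, end, k)
    for k in range(1, params.max_motif + 1):
        i = k
        run_start = -1
        while i <= n:
            matched = i < n and seq[i] == seq[i - k]
            if matched:
                if run_start < 0:
                    run_start = i - k
            elif run_start >= 0:
                start, end = run_start, i
                length = end - start
                if length >= params.min_total and length / k >= params.min_copies:
                    # report each tract once, at its primitive period: skip
                    # if the whole tract is also periodic at some p < k
                    if not _has_smaller_period(seq, start, end, k):
                        candidates.append((start, end, k))
                run_start = -1
            i += 1

    # overlap resolution: longest first, ties smaller motif then leftmost
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[2], c[0]))
    accepted: list[tuple[int, int, int]] = []
    for start, end, k in candidates:
        if all(end <= s or start >= e for s, e, _ in accepted):
            accepted.append((start, end, k))
    accepted.sort()

    loci = []
    for start, end, k in accepted:
        loci.append(
            MstLocus(
                chrom=chrom,
                start=start,
                end=end,
                motif=seq[start : start + k],
                copies=(end - start) / k,
                flank5=seq[max(0, start - params.flank) : start],
                flank3=seq[end : end + params.flank],
            )
        )
    return loci


def _has_smaller_period(seq: str, start: int, end: int, k: int) -> bool:
    """True if the whole tract is also p-periodic for some p < k."""
    for p in range(1, k):
        if all(seq[i] == seq[i - p] for i in range(start + p, end)):
            return True
    return False


def filter_ambiguous(loci: list[MstLocus]) -> tuple[list[MstLocus], list[MstLocus]]:
    """Drop every locus whose (motif, 5'-flank, 3'-flank) key collides.

    Returns ``(kept, removed)``.  All members of a colliding group are
    removed, since reads cannot be assigned uniquely to any of them.
    """
    groups: dict[tuple[str, str, str], list[MstLocus]] = {}
    for locus in loci:
        groups.setdefault(locus.ambiguity_key, []).append(locus)
    kept, removed = [], []
    for locus in loci:
        (kept if len(groups[locus.ambiguity_key]) == 1 else removed).append(locus)
    return kept, removed


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeThresholds:
    min_reads: int = CALLABLE_MIN_READS
    minor_min_reads: int = MINOR_MIN_READS
    het_min_frac: float = 0.30
    het_min_reads: int = 2


@dataclass
class MstGenotype:
    locus_id: str
    sample_id: str
    observations: dict[int, int]
    callable: bool
    primary: int | None = None
    secondary: int | None = None
    minor_alleles: list[int] = field(default_factory=list)

    @property
    def zygosity(self) -> str | None:
        if not self.callable:
            return None
        return "heterozygous" if self.secondary is not None else "homozygous"

    @property
    def has_minor(self) -> bool:
        return bool(self.minor_alleles)


def genotype_locus(
    observations: dict[int, int],
    locus_id: str = "",
    sample_id: str = "",
    thresholds: GenotypeThresholds = GenotypeThresholds(),
) -> MstGenotype:
    """Call a genotype from allele-length read counts at one locus.

    An empty or shallow observation map yields an uncallable genotype
    rather than an error.  Ties on read count are broken toward the
    shorter allele, deterministically.
    """
    obs = {int(l): int(c) for l, c in observations.items() if c > 0}
    if any(c < 0 for c in observations.values()):
        raise ValueError("negative read count")
    total = sum(obs.values())
    if total < thresholds.min_reads:
        return MstGenotype(locus_id, sample_id, obs, callable=False)
    ranked = sorted(obs.items(), key=lambda lc: (-lc[1], lc[0]))
    primary = ranked[0][0]
    secondary = None
    if len(ranked) > 1:
        length, count = ranked[1]
        if count >= thresholds.het_min_reads and count >= thresholds.het_min_frac * total:
            secondary = length
    called = {primary} | ({secondary} if secondary is not None else set())
    minors = sorted(
        l for l, c in obs.items() if l not in called and c >= thresholds.minor_min_reads
    )
    return MstGenotype(
        locus_id, sample_id, obs, callable=True,
        primary=primary, secondary=secondary, minor_alleles=minors,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass
class MstSummary:
    sample_id: str
    n_callable: int
    pct_homozygous: float | None
    pct_heterozygous: float | None
    pct_minor: float | None


def mst_summary(genotypes: list[MstGenotype], sample_id: str = "") -> MstSummary:
    """Percentages of homozygous / heterozygous / minor-allele loci.

    Percentages are over callable loci only, to one decimal, and
    homozygous + heterozygous sums to 100 exactly (the heterozygous
    share is computed and the homozygous share is its complement).
    With zero callable loci the percentages are reported missing.
    """
    callable_gts = [g for g in genotypes if g.callable]
    n = len(callable_gts)
    if n == 0:
        return MstSummary(sample_id, 0, None, None, None)
    n_het = sum(1 for g in callable_gts if g.zygosity == "heterozygous")
    n_minor = sum(1 for g in callable_gts if g.has_minor)
    pct_het = round_half_away(100.0 * n_het / n, 1)
    return MstSummary(
        sample_id=sample_id,
        n_callable=n,
        pct_homozygous=round_half_away(100.0 - pct_het, 1),
        pct_heterozygous=pct_het,
        pct_minor=round_half_away(100.0 * n_minor / n, 1),
    )


def group_mean_percent(per_sample_pcts: list[float], ndigits: int = 1) -> float:
    """Arithmetic mean of per-sample percentages, half away from zero.

    ``ndigits=0`` returns an integer-valued float (e.g. the "5%" style
    of whole-percent group summaries); ``ndigits=1`` the one-decimal
    style (e.g. "3.5%").
    """
    if not per_sample_pcts:
        raise ValueError("no percentages to average")
    mean = sum(per_sample_pcts) / len(per_sample_pcts)
    return round_half_away(mean, ndigits)


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------


def write_loci_bed(loci: list[MstLocus], path: str | Path) -> None:
    """BED (0-based half-open) + motif, copies, flank columns."""
    rows = [
        (
            l.chrom, l.start, l.end, l.locus_id, l.motif,
            round_half_away(l.copies, 2), l.flank5, l.flank3,
        )
        for l in loci
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "motif", "copies", "flank5", "flank3"],
    ).to_csv(path, sep="\t", index=False, header=False)


def read_loci_bed(path: str | Path) -> list[MstLocus]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "motif", "copies", "flank5", "flank3"],
        dtype={"chrom": str, "motif": str, "flank5": str, "flank3": str},
        keep_default_na=False,
    )
    loci = []
    for row in df.itertuples(index=False):
        loci.append(
            MstLocus(
                chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                motif=str(row.motif),
                copies=(int(row.end) - int(row.start)) / len(str(row.motif)),
                flank5=str(row.flank5), flank3=str(row.flank3),
            )
        )
    return loci


def write_observations_tsv(
    observations: dict[tuple[str, str], dict[int, int]], path: str | Path
) -> None:
    """``locus_id  sample_id  allele_length  read_count`` rows."""
    rows = [
        (locus_id, sample_id, length, count)
        for (locus_id, sample_id), lengths in sorted(observations.items())
        for length, count in sorted(lengths.items())
    ]
    pd.DataFrame(
        rows, columns=["locus_id", "sample_id", "allele_length", "read_count"]
    ).to_csv(path, sep="\t", index=False)


def read_observations_tsv(path: str | Path) -> dict[tuple[str, str], dict[int, int]]:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "sample_id": str})
    out: dict[tuple[str, str], dict[int, int]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.locus_id), str(row.sample_id))
        out.setdefault(key, {})[int(row.allele_length)] = int(row.read_count)
    return out
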