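"""Per-position read-depth and alternate-allele counts.

A :class:`CoverageProfile` answers two questions for the coverage-gated
pairwise comparison: how many reads cover a genomic position in this
sample, and how many of them support a particular alternate allele.
Positions absent from the profile count as depth 0 (uncallable).

Profiles round-trip through a simple per-position TSV
(``chrom  pos  depth  alt_count  [alt]``, 1-based positions).  The
optional fifth column records which alternate allele the count refers
to; without it the count applies to any queried allele at the position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

ANY_ALLELE = "*"

__all__ = ["CoverageProfile", "ANY_ALLELE"]


@dataclass
class CoverageProfile:
    """Sparse per-position depth + per-allele alternate read counts."""

    sample_id: str
    positions: dict[tuple[str, int], tuple[int, dict[str, int]]] = field(default_factory=dict)

    def add(self, chrom: str, pos: int, depth: int, alt_counts: dict[str, int] | None = None) -> None:
        alt_counts = dict(alt_counts or {})
        if any(c > depth for c in alt_counts.values()):
            raise ValueError(f"alt count exceeds depth at {chrom}:{pos}")
        if (chrom, pos) in self.positions:
            raise ValueError(f"duplicate position {chrom}:{pos} in profile {self.sample_id}")
        self.positions[(chrom, pos)] = (int(depth), alt_counts)

    def depth(self, chrom: str, pos: int) -> int:
        entry = self.positions.get((chrom, pos))
        return entry[0] if entry else 0

    def alt_count(self, chrom: str, pos: int, allele: str) -> int:
        entry = self.positions.get((chrom, pos))
        if entry is None:
            return 0
        counts = entry[1]
        if allele in counts:
            return counts[allele]
        return counts.get(ANY_ALLELE, 0)

    def covered(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    # ---- TSV round trip -------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for (chrom, pos), (depth, counts) in sorted(self.positions.items()):
            if not counts:
                rows.append((chrom, pos, depth, 0, "."))
            else:
                for allele, count in sorted(counts.items()):
                    rows.append((chrom, pos, depth, count, allele))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "depth", "alt_count", "alt"])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "CoverageProfile":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"chrom", "pos", "depth", "alt_count"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: coverage TSV needs columns {sorted(required)}")
        prof = cls(sample_id=sample_id or Path(path).stem)
        has_alt = "alt" in df.columns
        for key, sub in df.groupby(["chrom", "pos"], sort=False):
            chrom, pos = str(key[0]), int(key[1])
            depth = int(sub["depth"].iloc[0])
            counts: dict[str, int] = {}
            for _, row in sub.iterrows():
                allele = str(row["alt"]) if has_alt and str(row.get("alt", ".")) != "." else ANY_ALLELE
                count = int(row["alt_count"])
                if count > 0 or allele != ANY_ALLELE:
                    counts[allele] = counts.get(allele, 0) + count
            prof.add(chrom, pos, depth, counts)
        return prof
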