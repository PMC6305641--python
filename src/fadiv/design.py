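"""Study design: two labeled groups of replicate samples.

The analyses in this package are built around a 2-group x 2-replicate
layout: a disease cell line (e.g. a FANCD2-deficient PD20 line, "FA")
and its gene-corrected counterpart ("FA_RV"), each cultured in two
biological replicates.  The design object carries the group membership
that every sharing, pairwise-comparison and consensus operation needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterator

import yaml


@dataclass(frozen=True)
class StudyDesign:
    """Sample identifiers partitioned into exactly two labeled groups.

    Parameters
    ----------
    groups
        Mapping ``group label -> tuple of sample ids``, in a fixed order.
        The first group is treated as the "case" group by operations that
        distinguish case from control (e.g. case-specific gene sets).
    """

    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"FA": ("FA1", "FA2"), "FA_RV": ("FA_RV1", "FA_RV2")}
    )

    def __post_init__(self) -> None:
        if len(self.groups) != 2:
            raise ValueError(f"expected exactly 2 groups, got {len(self.groups)}")
        ids = [s for members in self.groups.values() for s in members]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids must be unique across groups")
        if any(len(members) == 0 for members in self.groups.values()):
            raise ValueError("every group needs at least one sample")

    @property
    def group_labels(self) -> tuple[str, str]:
        a, b = self.groups
        return a, b

    @property
    def case_group(self) -> str:
        return self.group_labels[0]

    @property
    def control_group(self) -> str:
        return self.group_labels[1]

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(s for members in self.groups.values() for s in members)

    def group_of(self, sample: str) -> str:
        for label, members in self.groups.items():
            if sample in members:
                return label
        raise KeyError(f"unknown sample {sample!r}")

    def sample_pairs(self) -> Iterator[tuple[str, str]]:
        """All unordered sample pairs, in design order."""
        return combinations(self.samples, 2)

    def within_group_pairs(self) -> list[tuple[str, str]]:
        return [p for p in self.sample_pairs() if self.group_of(p[0]) == self.group_of(p[1])]

    def cross_group_pairs(self) -> list[tuple[str, str]]:
        return [p for p in self.sample_pairs() if self.group_of(p[0]) != self.group_of(p[1])]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"groups": {g: list(m) for g, m in self.groups.items()}}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        groups = {str(g): tuple(map(str, m)) for g, m in raw["groups"].items()}
        return cls(groups=groups)


def pd20_design() -> StudyDesign:
    """The default FA / FA_RV two-replicate design."""
    return StudyDesign()
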