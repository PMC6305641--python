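"""Cross-group differential-expression consensus and FDR reporting.

Expression input is one record per gene: an FPKM-scale value per
sample, a p-value for each of the six pairwise sample comparisons
(Cuffdiff-style), and the exon count of the gene's most expressed
transcript per sample.

The consensus rule: a gene is differentially expressed between the two
groups when its p-value is below alpha in the cross-group pairwise
comparisons (all four by default) *and* at or above alpha in both
within-group (replicate) comparisons.  Requiring non-significance
within replicates suppresses genes whose apparent shift reflects
culture divergence rather than the group contrast.

FDR here is the plain Benjamini-Hochberg quotient
``p * total_tests / rank`` with ranks assigned in ascending p order.
By default no step-up monotonicity enforcement is applied, so reported
values can exceed 1 for large p; pass ``step_up=True`` for the standard
monotone adjusted q-values (capped at 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import round_half_away
from .design import StudyDesign

__all__ = [
    "GeneExpressionRecord",
    "DeCall",
    "FdrResult",
    "log2_fold_change",
    "bh_fdr",
    "consensus_de",
    "pairwise_de_counts",
    "exon_count_variation",
    "read_expression_tsv",
    "write_expression_tsv",
    "from_cuffdiff",
]

Pair = tuple[str, str]


@dataclass
class GeneExpressionRecord:
    gene_id: str
    fpkm: dict[str, float]
    p_values: dict[Pair, float]
    exon_counts: dict[str, int] = field(default_factory=dict)

    def complete_for(self, design: StudyDesign) -> bool:
        pairs = set(design.sample_pairs())
        have = {tuple(p) for p in self.p_values if not math.isnan(self.p_values[p])}
        return pairs <= have and set(design.samples) <= set(self.fpkm)


def log2_fold_change(fpkm_a: float, fpkm_b: float) -> float | None:
    """Signed log2 ratio of b over a; ``None`` when undefined.

    e.g. ``(3.4, 108.6) -> 4.997...`` which rounds to the reported 5.0.
    A zero or negative baseline has no finite fold change and returns
    ``None`` (reported as missing downstream).
    """
    if fpkm_a <= 0 or fpkm_b < 0:
        return None
    if fpkm_b == 0:
        return None
    return math.log2(fpkm_b / fpkm_a)


@dataclass(frozen=True)
class FdrResult:
    p_value: float
    rank: int  # 1-based ascending
    total_tests: int
    fdr: float


def bh_fdr(p_values: list[float], step_up: bool = False) -> list[FdrResult]:
    """Benjamini-Hochberg quotients for a list of p-values.

    Results are returned in input order.  Ties receive consecutive
    ranks in input order (stable sort).  With ``step_up=False`` the raw
    quotient ``p * m / rank`` is reported (it may exceed 1); with
    ``step_up=True`` the standard monotone step-up adjustment is
    applied and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    fdr = p * m / ranks
    if step_up:
        sorted_q = fdr[order]
        monotone = np.minimum.accumulate(sorted_q[::-1])[::-1]
        fdr = np.empty(m)
        fdr[order] = np.minimum(monotone, 1.0)
    return [
        FdrResult(p_value=float(p[i]), rank=int(ranks[i]), total_tests=m, fdr=float(fdr[i]))
        for i in range(m)
    ]


def _norm_pair(record: GeneExpressionRecord, pair: Pair) -> float:
    a, b = pair
    if pair in record.p_values:
        return record.p_values[pair]
    if (b, a) in record.p_values:
        return record.p_values[(b, a)]
    return float("nan")


@dataclass
class DeCall:
    gene_id: str
    is_de: bool
    cross_log2fc: dict[Pair, float | None] = field(default_factory=dict)
    higher_group: str | None = None

    @property
    def direction(self) -> str | None:
        """"+" when the second (control/corrected) group is higher."""
        return None if self.higher_group is None else self.higher_group


def consensus_de(
    design: StudyDesign,
    records: list[GeneExpressionRecord],
    alpha: float = 0.05,
    cross_rule: str = "all",
) -> tuple[list[DeCall], list[str]]:
    """Apply the replicate-consensus differential-expression rule.

    Returns ``(calls, uncallable_gene_ids)``.  ``cross_rule="all"``
    requires p < alpha in all four cross-group pairs; ``"any"`` relaxes
    to at least one.  Either way both within-group pairs must be
    non-significant (p >= alpha).  Genes with missing pairs or samples
    are not callable and are listed separately.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if cross_rule not in ("all", "any"):
        raise ValueError("cross_rule must be 'all' or 'any'")
    cross_pairs = design.cross_group_pairs()
    within_pairs = design.within_group_pairs()
    g1, g2 = design.group_labels
    calls: list[DeCall] = []
    uncallable: list[str] = []
    for rec in records:
        if not rec.complete_for(design):
            uncallable.append(rec.gene_id)
            continue
        cross_p = [_norm_pair(rec, p) for p in cross_pairs]
        within_p = [_norm_pair(rec, p) for p in within_pairs]
        cross_ok = all(p < alpha for p in cross_p) if cross_rule == "all" else any(
            p < alpha for p in cross_p
        )
        within_ok = all(p >= alpha for p in within_p)
        is_de = cross_ok and within_ok
        call = DeCall(gene_id=rec.gene_id, is_de=is_de)
        if is_de:
            for a, b in cross_pairs:
                call.cross_log2fc[(a, b)] = log2_fold_change(rec.fpkm[a], rec.fpkm[b])
            mean1 = float(np.mean([rec.fpkm[s] for s in design.groups[g1]]))
            mean2 = float(np.mean([rec.fpkm[s] for s in design.groups[g2]]))
            call.higher_group = g2 if mean2 > mean1 else g1
        calls.append(call)
    return calls, uncallable


def pairwise_de_counts(
    design: StudyDesign,
    records: list[GeneExpressionRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Symmetric matrix of per-pair significant-gene counts (p < alpha)."""
    samples = list(design.samples)
    mat = pd.DataFrame(0, index=samples, columns=samples)
    for a, b in design.sample_pairs():
        n = sum(
            1
            for rec in records
            if not math.isnan(_norm_pair(rec, (a, b))) and _norm_pair(rec, (a, b)) < alpha
        )
        mat.loc[a, b] = n
        mat.loc[b, a] = n
    return mat


@dataclass
class ExonVariation:
    cross_fraction: float  # mean over the 4 cross-group pairs
    within_fraction: float  # mean over the 2 within-group pairs
    per_pair: dict[Pair, float] = field(default_factory=dict)


def exon_count_variation(
    design: StudyDesign, records: list[GeneExpressionRecord]
) -> ExonVariation:
    """Fractions of expressed genes whose exon counts differ per pair.

    For each sample pair the denominator is genes expressed (FPKM > 0)
    in *both* samples; the numerator is those whose most-expressed-
    transcript exon counts differ.  Pair fractions are then averaged
    over the cross-group pairs and within-group pairs separately.
    """
    per_pair: dict[Pair, float] = {}
    for a, b in design.sample_pairs():
        expressed = [
            rec
            for rec in records
            if rec.fpkm.get(a, 0) > 0
            and rec.fpkm.get(b, 0) > 0
            and a in rec.exon_counts
            and b in rec.exon_counts
        ]
        if not expressed:
            per_pair[(a, b)] = float("nan")
            continue
        n_vary = sum(1 for rec in expressed if rec.exon_counts[a] != rec.exon_counts[b])
        per_pair[(a, b)] = n_vary / len(expressed)
    cross = [per_pair[p] for p in design.cross_group_pairs()]
    within = [per_pair[p] for p in design.within_group_pairs()]
    return ExonVariation(
        cross_fraction=float(np.nanmean(cross)) if cross else float("nan"),
        within_fraction=float(np.nanmean(within)) if within else float("nan"),
        per_pair=per_pair,
    )


# ---------------------------------------------------------------------------
# table formats
# ---------------------------------------------------------------------------


def _pair_col(a: str, b: str) -> str:
    return f"p_{a}__{b}"


def write_expression_tsv(
    design: StudyDesign, records: list[GeneExpressionRecord], path: str | Path
) -> None:
    rows = []
    for rec in records:
        row: dict[str, object] = {"gene_id": rec.gene_id}
        for s in design.samples:
            row[f"fpkm_{s}"] = rec.fpkm.get(s, float("nan"))
        for a, b in design.sample_pairs():
            row[_pair_col(a, b)] = _norm_pair(rec, (a, b))
        for s in design.samples:
            row[f"exons_{s}"] = rec.exon_counts.get(s, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression_tsv(design: StudyDesign, path: str | Path) -> list[GeneExpressionRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    records = []
    for row in df.itertuples(index=False):
        # itertuples mangles pair column names; index by position instead
        d = dict(zip(df.columns, row))
        fpkm = {s: float(d[f"fpkm_{s}"]) for s in design.samples if f"fpkm_{s}" in d}
        pvals = {}
        for a, b in design.sample_pairs():
            col = _pair_col(a, b)
            if col in d:
                pvals[(a, b)] = float(d[col])
        exons = {}
        for s in design.samples:
            col = f"exons_{s}"
            if col in d and d[col] != "" and not pd.isna(d[col]):
                exons[s] = int(d[col])
        records.append(
            GeneExpressionRecord(
                gene_id=str(d["gene_id"]), fpkm=fpkm, p_values=pvals, exon_counts=exons
            )
        )
    return records


def from_cuffdiff(
    design: StudyDesign,
    gene_exp_diff: str | Path,
    fpkm_tracking: str | Path | None = None,
) -> list[GeneExpressionRecord]:
    """Build records from a Cuffdiff ``gene_exp.diff``-style table.

    Needs columns ``gene_id`` (or ``gene``), ``sample_1``, ``sample_2``,
    ``value_1``, ``value_2`` and ``p_value``; each row contributes one
    pairwise p-value and the two samples' FPKM values.  Exon counts of
    the most expressed transcript can be supplied via a
    ``genes.fpkm_tracking``-style table with ``gene_id``, ``sample_id``
    and ``exons`` columns (one row per gene per sample).
    """
    df = pd.read_csv(gene_exp_diff, sep="\t")
    gene_col = "gene_id" if "gene_id" in df.columns else "gene"
    recs: dict[str, GeneExpressionRecord] = {}
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        gid = str(d[gene_col])
        rec = recs.setdefault(gid, GeneExpressionRecord(gid, {}, {}, {}))
        a, b = str(d["sample_1"]), str(d["sample_2"])
        rec.fpkm[a] = float(d["value_1"])
        rec.fpkm[b] = float(d["value_2"])
        rec.p_values[(a, b)] = float(d["p_value"])
    if fpkm_tracking is not None:
        tr = pd.read_csv(fpkm_tracking, sep="\t")
        for row in tr.itertuples(index=False):
            d = dict(zip(tr.columns, row))
            gid = str(d["gene_id"])
            if gid in recs:
                recs[gid].exon_counts[str(d["sample_id"])] = int(d["exons"])
    return [recs[g] for g in sorted(recs)]


def write_de_table(
    design: StudyDesign,
    calls: list[DeCall],
    records: list[GeneExpressionRecord],
    path: str | Path,
) -> None:
    """Write the consensus DE gene table (gene, mean fold change, direction)."""
    by_gene = {r.gene_id: r for r in records}
    g1, g2 = design.group_labels
    rows = []
    for call in calls:
        if not call.is_de:
            continue
        rec = by_gene[call.gene_id]
        mean1 = float(np.mean([rec.fpkm[s] for s in design.groups[g1]]))
        mean2 = float(np.mean([rec.fpkm[s] for s in design.groups[g2]]))
        lfc = log2_fold_change(mean1, mean2)
        rows.append(
            {
                "gene_id": call.gene_id,
                "log2_fold_change": "" if lfc is None else round_half_away(lfc, 1),
                f"higher_in_{g2}": "+" if call.higher_group == g2 else "-",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
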