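"""Fold changes, the literal FDR quotient, and the DE consensus rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from fadiv._util import round_half_away
from fadiv.expression import (
    GeneExpressionRecord,
    bh_fdr,
    consensus_de,
    exon_count_variation,
    from_cuffdiff,
    log2_fold_change,
    pairwise_de_counts,
    read_expression_tsv,
    write_expression_tsv,
)

# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [(3.4, 108.6, 5.0), (4.6, 3.4, -0.4), (7.7, 7.7, 0.0)],
)
def test_log2_fold_change_examples(a, b, expected):
    assert round_half_away(log2_fold_change(a, b), 1) == expected


def test_zero_baseline_is_undefined():
    assert log2_fold_change(0.0, 5.0) is None
    assert log2_fold_change(5.0, 0.0) is None


@given(
    a=st.floats(0.01, 1e6, allow_nan=False),
    b=st.floats(0.01, 1e6, allow_nan=False),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_fold_change_antisymmetry(a, b):
    assert math.isclose(log2_fold_change(a, b), -log2_fold_change(b, a), abs_tol=1e-12)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def test_fdr_quotient_is_literal():
    (res,) = [r for r in bh_fdr([0.01] + [0.5] * 99) if r.rank == 1]
    assert res.fdr == pytest.approx(0.01 * 100 / 1)  # = 1.0
    (single,) = bh_fdr([0.5])
    assert single.fdr == 0.5 and single.rank == 1 and single.total_tests == 1


def test_literal_fdr_can_exceed_one():
    results = bh_fdr([0.9, 0.95, 0.99])
    assert max(r.fdr for r in results) > 1.0  # no cap without step-up


def test_ties_get_consecutive_ranks_in_input_order():
    results = bh_fdr([0.5, 0.5, 0.1])
    assert [r.rank for r in results] == [2, 3, 1]


def test_empty_input():
    assert bh_fdr([]) == []


def test_rejects_out_of_range_p():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_step_up_matches_reference_implementation():
    rng = np.random.default_rng(0)
    for _ in range(50):
        p = rng.uniform(size=int(rng.integers(1, 80)))
        ours = np.array([r.fdr for r in bh_fdr(list(p), step_up=True)])
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)


# ---------------------------------------------------------------------------
# consensus rule
# ---------------------------------------------------------------------------


def _record(design, cross_p, within_p, fpkm=None, gene="G1", exons=None):
    cross = dict(zip(design.cross_group_pairs(), cross_p))
    within = dict(zip(design.within_group_pairs(), within_p))
    fpkm = fpkm or {s: 10.0 for s in design.samples}
    rec = GeneExpressionRecord(gene, fpkm, {**cross, **within}, exons or {})
    return rec


def test_consensus_positive_case(design):
    rec = _record(design, [0.01, 0.02, 0.01, 0.03], [0.5, 0.9])
    (call,), uncallable = consensus_de(design, [rec])
    assert call.is_de and not uncallable


def test_within_group_significance_vetoes(design):
    rec = _record(design, [0.01, 0.02, 0.01, 0.03], [0.01, 0.9])
    (call,), _ = consensus_de(design, [rec])
    assert not call.is_de


def test_one_cross_pair_failing_blocks_all_rule_but_not_any_rule(design):
    rec = _record(design, [0.01, 0.06, 0.01, 0.01], [0.5, 0.9])
    (call_all,), _ = consensus_de(design, [rec], cross_rule="all")
    (call_any,), _ = consensus_de(design, [rec], cross_rule="any")
    assert not call_all.is_de
    assert call_any.is_de


def test_missing_pair_makes_gene_uncallable(design):
    rec = _record(design, [0.01, 0.02, 0.01, 0.03], [0.5, 0.9])
    del rec.p_values[design.cross_group_pairs()[0]]
    calls, uncallable = consensus_de(design, [rec])
    assert calls == [] and uncallable == ["G1"]


def test_alpha_boundaries(design):
    recs = [
        _record(design, [0.4, 0.4, 0.4, 0.4], [0.6, 0.7], gene=f"G{i}") for i in range(5)
    ]
    calls_tiny, _ = consensus_de(design, recs, alpha=1e-9)
    assert not any(c.is_de for c in calls_tiny)
    calls_wide, _ = consensus_de(design, recs, alpha=0.999)
    # with alpha near 1 every cross pair is "significant" but the
    # within-group veto fires too, so nothing is called
    assert not any(c.is_de for c in calls_wide)
    with pytest.raises(ValueError):
        consensus_de(design, recs, alpha=0.0)


def test_direction_follows_group_means(design):
    fpkm = {"FA1": 4.6, "FA2": 3.4, "FA_RV1": 108.6, "FA_RV2": 124.2}
    rec = _record(design, [0.001] * 4, [0.9, 0.9], fpkm=fpkm)
    (call,), _ = consensus_de(design, [rec])
    assert call.is_de and call.higher_group == "FA_RV"
    lfc = call.cross_log2fc[("FA2", "FA_RV1")]
    assert round_half_away(lfc, 1) == 5.0


def test_de_calls_are_subset_of_cross_significant(design):
    rng = np.random.default_rng(8)
    recs = [
        _record(design, list(rng.uniform(size=4)), list(rng.uniform(size=2)), gene=f"G{i}")
        for i in range(300)
    ]
    calls, _ = consensus_de(design, recs, alpha=0.3)
    cross = design.cross_group_pairs()
    for call in calls:
        if call.is_de:
            rec = next(r for r in recs if r.gene_id == call.gene_id)
            assert all(rec.p_values[p] < 0.3 for p in cross)


# ---------------------------------------------------------------------------
# pairwise counts and exon variation
# ---------------------------------------------------------------------------


def test_pairwise_counts_planted_noiseless(design):
    recs = [
        _record(design, [0.001] * 4, [0.9, 0.9], gene=f"DE{i}") for i in range(20)
    ] + [_record(design, [0.9] * 4, [0.9, 0.9], gene=f"N{i}") for i in range(80)]
    counts = pairwise_de_counts(design, recs, alpha=0.05)
    for a, b in design.cross_group_pairs():
        assert counts.loc[a, b] == 20
    for a, b in design.within_group_pairs():
        assert counts.loc[a, b] == 0
    assert (counts.values == counts.values.T).all()


def test_pairwise_counts_uniform_null_binomial(design):
    rng = np.random.default_rng(9)
    recs = [
        _record(design, list(rng.uniform(size=4)), list(rng.uniform(size=2)), gene=f"G{i}")
        for i in range(1000)
    ]
    counts = pairwise_de_counts(design, recs, alpha=0.05)
    # each pair count ~ Binomial(1000, 0.05): 50 +/- 4.3 sd
    for a, b in design.sample_pairs():
        assert 25 <= counts.loc[a, b] <= 75


def test_exon_variation_identical_counts(design):
    recs = [
        _record(design, [0.5] * 4, [0.5] * 2, gene=f"G{i}", exons={s: 7 for s in design.samples})
        for i in range(10)
    ]
    var = exon_count_variation(design, recs)
    assert var.cross_fraction == 0.0 and var.within_fraction == 0.0


def test_exon_variation_cross_only_construction(design):
    g2_members = design.groups[design.control_group]
    recs = []
    for i in range(100):
        exons = {s: 5 for s in design.samples}
        if i < 10:  # 10% of genes shift exon count in the second group
            for s in g2_members:
                exons[s] = 6
        recs.append(_record(design, [0.5] * 4, [0.5] * 2, gene=f"G{i}", exons=exons))
    var = exon_count_variation(design, recs)
    assert var.cross_fraction == pytest.approx(0.10)
    assert var.within_fraction == 0.0


def test_unexpressed_gene_excluded_from_pair_denominator(design):
    fpkm_on = {s: 5.0 for s in design.samples}
    fpkm_off = dict(fpkm_on, FA1=0.0)
    recs = [
        _record(design, [0.5] * 4, [0.5] * 2, fpkm=fpkm_on, gene="ON",
                exons={s: 3 for s in design.samples}),
        _record(design, [0.5] * 4, [0.5] * 2, fpkm=fpkm_off, gene="OFF",
                exons=dict({s: 3 for s in design.samples}, FA1=9)),
    ]
    var = exon_count_variation(design, recs)
    # the OFF gene's divergent FA1 exon count never enters any FA1 pair
    assert var.cross_fraction == 0.0 and var.within_fraction == 0.0


# ---------------------------------------------------------------------------
# table formats
# ---------------------------------------------------------------------------


def test_expression_tsv_round_trip(tmp_path, design):
    recs = [
        _record(design, [0.01, 0.2, 0.3, 0.04], [0.5, 0.9], gene=f"G{i}",
                exons={s: 4 + i for s in design.samples})
        for i in range(5)
    ]
    path = tmp_path / "expr.tsv"
    write_expression_tsv(design, recs, path)
    back = read_expression_tsv(design, path)
    assert [r.gene_id for r in back] == [r.gene_id for r in recs]
    for orig, loaded in zip(recs, back):
        assert loaded.fpkm == pytest.approx(orig.fpkm)
        for pair in design.sample_pairs():
            assert loaded.p_values[pair] == pytest.approx(orig.p_values[pair])
        assert loaded.exon_counts == orig.exon_counts


def test_cuffdiff_converter(tmp_path, design):
    rows = ["gene_id\tsample_1\tsample_2\tvalue_1\tvalue_2\tp_value"]
    for a, b in design.sample_pairs():
        rows.append(f"FANCD2\t{a}\t{b}\t4.6\t108.6\t0.001")
    diff = tmp_path / "gene_exp.diff"
    diff.write_text("\n".join(rows) + "\n")
    tracking = tmp_path / "genes.fpkm_tracking"
    tracking.write_text(
        "gene_id\tsample_id\texons\n"
        + "\n".join(f"FANCD2\t{s}\t44" for s in design.samples)
        + "\n"
    )
    (rec,) = from_cuffdiff(design, diff, tracking)
    assert rec.gene_id == "FANCD2"
    assert rec.complete_for(design)
    assert rec.exon_counts == {s: 44 for s in design.samples}
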