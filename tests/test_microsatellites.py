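"""Tandem-repeat discovery, ambiguity filtering and genotyping."""

import numpy as np
import pytest

from fadiv.microsatellites import (
    GenotypeThresholds,
    MstLocus,
    ScanParams,
    canonical_motif,
    filter_ambiguous,
    genotype_locus,
    group_mean_percent,
    mst_summary,
    read_loci_bed,
    read_observations_tsv,
    scan_microsatellites,
    write_loci_bed,
    write_observations_tsv,
)

# ---------------------------------------------------------------------------
# scanner
# ---------------------------------------------------------------------------


def test_mononucleotide_run_with_flanks():
    seq = "GCTGC" + "A" * 34 + "CTTAG"
    (locus,) = scan_microsatellites(seq)
    assert locus.motif == "A"
    assert locus.copies == 34
    assert (locus.flank5, locus.flank3) == ("GCTGC", "CTTAG")


def test_tetranucleotide_three_copies():
    loci = scan_microsatellites("ACGTACGTACGT", ScanParams(min_copies=3))
    (locus,) = loci
    assert locus.motif == "ACGT" and locus.copies == 3


def test_all_distinct_sequence_has_no_loci():
    assert scan_microsatellites("ACGT") == []


def test_partial_trailing_copy_is_fractional():
    seq = "TTGCA" + "AC" * 5 + "A" + "GGTTC"  # (AC)5.5
    (locus,) = scan_microsatellites(seq)
    assert locus.motif == "AC"
    assert locus.copies == 5.5


def test_composite_motif_reported_at_primitive_period():
    # ATATATATATAT is periodic at 2; no period-4 "ATAT" locus is emitted
    loci = scan_microsatellites("GGCGC" + "AT" * 6 + "CGGCG")
    (locus,) = loci
    assert locus.motif == "AT"


def test_canonical_motif_is_minimal_rotation():
    assert canonical_motif("TA") == "AT"
    assert canonical_motif("GAC") == "ACG"
    assert canonical_motif("A") == "A"


def _oracle_scan(seq, params=ScanParams()):
    """Independent enumeration: per-start maximal extension per period."""
    n = len(seq)
    found = []
    for k in range(1, params.max_motif + 1):
        for start in range(n - k):
            # left-maximality: cannot extend the tract one base left
            if start > 0 and seq[start - 1] == seq[start - 1 + k]:
                continue
            end = start + k
            while end < n and seq[end] == seq[end - k]:
                end += 1
            length = end - start
            if length < max(params.min_total, int(np.ceil(params.min_copies * k))):
                continue
            if length / k < params.min_copies:
                continue
            # primitive period over the whole tract
            if any(
                all(seq[i] == seq[i - p] for i in range(start + p, end))
                for p in range(1, k)
            ):
                continue
            found.append((start, end, k))
    # same resolution rule, written directly
    found.sort(key=lambda c: (-(c[1] - c[0]), c[2], c[0]))
    accepted = []
    for s, e, k in found:
        if all(e <= s2 or s >= e2 for s2, e2, _ in accepted):
            accepted.append((s, e, k))
    return sorted(accepted)


@pytest.mark.parametrize("seed", range(10))
def test_scanner_matches_periodicity_oracle(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    loci = scan_microsatellites(seq)
    got = sorted((l.start, l.end, len(l.motif)) for l in loci)
    assert got == _oracle_scan(seq)


# ---------------------------------------------------------------------------
# ambiguity filter
# ---------------------------------------------------------------------------


def _locus(start, motif, copies, flank5, flank3):
    return MstLocus(
        "chr1", start, start + len(motif) * copies, motif, float(copies), flank5, flank3
    )


def test_same_motif_identical_flanks_removes_all_members():
    a = _locus(100, "A", 34, "GCTGC", "CTTAG")
    b = _locus(900, "A", 15, "GCTGC", "CTTAG")
    kept, removed = filter_ambiguous([a, b])
    assert kept == [] and set(removed) == {a, b}


def test_different_flanks_are_retained():
    a = _locus(100, "A", 34, "GCTGC", "CTTAG")
    b = _locus(900, "A", 15, "GCTGC", "TTTAG")
    kept, removed = filter_ambiguous([a, b])
    assert set(kept) == {a, b} and removed == []


def test_rotated_motifs_collide():
    # TA repeats are the same tract class as AT repeats
    a = _locus(100, "AT", 6, "GCTGC", "CTTAG")
    b = _locus(900, "TA", 8, "GCTGC", "CTTAG")
    kept, _ = filter_ambiguous([a, b])
    assert kept == []


def test_filter_is_idempotent():
    rng = np.random.default_rng(2)
    loci = [
        _locus(
            int(i * 1000),
            str(rng.choice(["A", "AT", "CAG"])),
            int(rng.integers(4, 12)),
            "".join(rng.choice(list("ACGT"), size=5)),
            "".join(rng.choice(list("ACGT"), size=5)),
        )
        for i in range(40)
    ]
    once_kept, once_removed = filter_ambiguous(loci)
    twice_kept, twice_removed = filter_ambiguous(once_kept)
    assert twice_kept == once_kept and twice_removed == []


# ---------------------------------------------------------------------------
# genotyper
# ---------------------------------------------------------------------------


def test_nine_reads_is_uncallable():
    gt = genotype_locus({15: 9})
    assert not gt.callable and gt.zygosity is None


def test_heterozygous_at_forty_percent_runner_up():
    gt = genotype_locus({15: 6, 17: 4})
    assert gt.callable
    assert gt.zygosity == "heterozygous"
    assert (gt.primary, gt.secondary) == (15, 17)
    assert gt.minor_alleles == []


def test_runner_up_below_fraction_becomes_minor_allele():
    gt = genotype_locus({15: 10, 13: 3})  # 3/13 = 23% < 30%, but >= 3 reads
    assert gt.zygosity == "homozygous"
    assert gt.minor_alleles == [13]


def test_two_read_runner_up_is_neither_secondary_nor_minor():
    gt = genotype_locus({15: 10, 13: 2})
    assert gt.zygosity == "homozygous"
    assert gt.minor_alleles == []


def test_empty_observations_yield_uncallable_not_error():
    gt = genotype_locus({})
    assert not gt.callable


def test_minor_alleles_beyond_secondary_pair():
    gt = genotype_locus({15: 12, 17: 10, 20: 4, 22: 2})
    assert gt.zygosity == "heterozygous"
    assert gt.minor_alleles == [20]


def test_genotyper_threshold_overrides():
    strict = GenotypeThresholds(min_reads=20)
    assert not genotype_locus({15: 15}, thresholds=strict).callable
    relaxed = GenotypeThresholds(het_min_frac=0.10)
    assert genotype_locus({15: 10, 13: 3}, thresholds=relaxed).zygosity == "heterozygous"


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def test_summary_percentages_sum_to_100():
    genotypes = [genotype_locus(obs) for obs in ({15: 20}, {15: 7, 17: 6}, {12: 30}, {9: 5})]
    summ = mst_summary(genotypes, "S")
    assert summ.n_callable == 3
    assert summ.pct_homozygous + summ.pct_heterozygous == 100.0


def test_all_homozygous_summary():
    genotypes = [genotype_locus({15: 20}) for _ in range(5)]
    summ = mst_summary(genotypes)
    assert (summ.pct_homozygous, summ.pct_heterozygous, summ.pct_minor) == (100.0, 0.0, 0.0)


def test_zero_callable_loci_reported_missing():
    summ = mst_summary([genotype_locus({15: 3})])
    assert summ.n_callable == 0 and summ.pct_heterozygous is None


def test_group_means_at_both_roundings():
    assert group_mean_percent([5.5, 4.5, 4.0, 6.1], ndigits=0) == 5
    assert group_mean_percent([3.4, 2.9, 3.4, 4.4], ndigits=1) == 3.5


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------


def test_bed_and_observation_round_trips(tmp_path):
    loci = [
        _locus(100, "AT", 6, "GCTGC", "CTTAG"),
        _locus(900, "CAG", 5, "AAAAC", "TTTTG"),
    ]
    bed = tmp_path / "loci.bed"
    write_loci_bed(loci, bed)
    back = read_loci_bed(bed)
    assert [(l.start, l.end, l.motif, l.flank5) for l in back] == [
        (l.start, l.end, l.motif, l.flank5) for l in loci
    ]

    obs = {("chr1:100-112", "FA1"): {6: 10, 7: 3}, ("chr1:900-915", "FA2"): {5: 12}}
    tsv = tmp_path / "obs.tsv"
    write_observations_tsv(obs, tsv)
    assert read_observations_tsv(tsv) == obs
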