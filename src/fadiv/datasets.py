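"""Published per-sample summary statistics used as worked examples.

These are the printed exome/RNA-seq summary tables for a four-sample
FANCD2 cell-line experiment (two FA replicates, two retrovirally
corrected FA_RV replicates) together with 1000 Genomes Project control
samples.  They serve as fixed inputs for the pure summary-statistic
operations — sharing fractions, SNP:INDEL ratios, microsatellite group
means and fold changes — whose outputs can be checked against the
quoted headline numbers.
"""

from __future__ import annotations

# Per-sample variant counts and recurrence: sample -> (group, total count),
# plus within-group and all-sample intersection counts per variant type.
VARIANT_COUNTS = {
    "SNP": {
        "per_sample": {
            "GRL1398": ("FA", 201_940),
            "GRL1399": ("FA", 198_816),
            "GRL1400": ("FA_RV", 194_954),
            "GRL1401": ("FA_RV", 191_593),
        },
        "within_group": {"FA": 153_043, "FA_RV": 144_266},
        "all_samples": 128_179,
    },
    "INDEL": {
        "per_sample": {
            "GRL1398": ("FA", 28_053),
            "GRL1399": ("FA", 27_218),
            "GRL1400": ("FA_RV", 27_386),
            "GRL1401": ("FA_RV", 25_966),
        },
        "within_group": {"FA": 19_556, "FA_RV": 18_836},
        "all_samples": 15_023,
    },
}

# sample -> (n_snp, n_indel) for the composition ratio
SNP_INDEL_COUNTS = {
    "GRL1398": (205_613, 28_631),
    "GRL1399": (202_186, 27_786),
    "GRL1400": (198_180, 27_952),
    "GRL1401": (194_671, 26_415),
    "HG02003": (258_715, 22_521),
    "HG02008": (250_147, 21_448),
    "HG02009": (232_261, 20_282),
    "HG02010": (255_466, 23_093),
}

# microsatellite genotyping summaries:
# sample -> (callable loci, %homozygous, %heterozygous, %minor alleles)
MST_SUMMARY = {
    "FA1": (5_395, 95.4, 4.6, 7.6),
    "FA2": (5_011, 94.9, 5.1, 7.7),
    "FA_RV1": (5_818, 94.9, 5.1, 9.2),
    "FA_RV2": (4_519, 95.0, 5.0, 9.3),
    "HG02003": (4_485, 96.6, 3.4, 5.5),
    "HG02008": (3_834, 97.1, 2.9, 4.5),
    "HG02009": (3_211, 96.6, 3.4, 4.0),
    "HG02010": (4_158, 95.6, 4.4, 6.1),
}

FA_SAMPLES = ("FA1", "FA2", "FA_RV1", "FA_RV2")
KGP_SAMPLES = ("HG02003", "HG02008", "HG02009", "HG02010")

# FANCD2 pairwise FPKM comparisons: (sample_1, sample_2, fpkm_1, fpkm_2)
FANCD2_FPKM_PAIRS = [
    ("FA1", "FA2", 4.6, 3.4),
    ("FA1", "FA_RV1", 4.6, 108.6),
    ("FA2", "FA_RV1", 3.4, 108.6),
    ("FA1", "FA_RV2", 4.6, 124.2),
    ("FA2", "FA_RV2", 3.4, 124.2),
    ("FA_RV1", "FA_RV2", 108.6, 124.2),
]
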