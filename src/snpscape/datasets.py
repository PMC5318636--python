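"""Published summary tables used as worked examples.

Counts come from a resequencing panel of five rice landraces (three indica,
two japonica) called against the Nipponbare reference: the six unordered
base-change classes per landrace, and the SNP effect-category counts per
landrace. They exercise the spectrum and effect-summary arithmetic at
published scale without needing the underlying reads.
"""

#: base-change counts per landrace: six unordered pairs
BASE_CHANGE_COUNTS: dict[str, dict[tuple[str, str], int]] = {
    "indica_12": {
        ("A", "G"): 705_908, ("C", "T"): 707_496,
        ("A", "C"): 155_310, ("A", "T"): 182_882,
        ("C", "G"): 101_541, ("G", "T"): 154_639,
    },
    "indica_13": {
        ("A", "G"): 671_815, ("C", "T"): 672_959,
        ("A", "C"): 149_265, ("A", "T"): 176_243,
        ("C", "G"): 95_523, ("G", "T"): 148_304,
    },
    "indica_15": {
        ("A", "G"): 787_002, ("C", "T"): 787_976,
        ("A", "C"): 174_014, ("A", "T"): 205_343,
        ("C", "G"): 113_736, ("G", "T"): 173_286,
    },
    "japonica_11": {
        ("A", "G"): 255_473, ("C", "T"): 255_542,
        ("A", "C"): 59_111, ("A", "T"): 70_949,
        ("C", "G"): 39_460, ("G", "T"): 59_011,
    },
    "japonica_14": {
        ("A", "G"): 236_847, ("C", "T"): 237_620,
        ("A", "C"): 55_410, ("A", "T"): 68_165,
        ("C", "G"): 37_120, ("G", "T"): 55_639,
    },
}

#: published Ts/Tv ratios as printed (3 decimals)
PUBLISHED_TS_TV: dict[str, float] = {
    "indica_12": 2.378,
    "indica_13": 2.362,
    "indica_15": 2.364,  # printed value; the counts above give 2.363
    "japonica_11": 2.236,
    "japonica_14": 2.193,
}

#: SNP effect-category counts per landrace
SNP_EFFECT_COUNTS: dict[str, dict[str, int]] = {
    "indica_12": dict(
        intergenic=1_374_419, genic=633_408, intron_and_regulatory=288_375,
        utrs=85_749, cds=259_284, nonsynonymous=151_998, synonymous=107_286,
    ),
    "indica_13": dict(
        intergenic=1_329_647, genic=584_505, intron_and_regulatory=279_350,
        utrs=82_611, cds=222_544, nonsynonymous=131_754, synonymous=90_790,
    ),
    "indica_15": dict(
        intergenic=1_527_754, genic=713_664, intron_and_regulatory=320_956,
        utrs=96_948, cds=295_760, nonsynonymous=172_767, synonymous=122_993,
    ),
    "japonica_11": dict(
        intergenic=488_888, genic=250_766, intron_and_regulatory=109_191,
        utrs=29_587, cds=111_988, nonsynonymous=66_645, synonymous=45_343,
    ),
    "japonica_14": dict(
        intergenic=454_811, genic=236_104, intron_and_regulatory=101_187,
        utrs=28_138, cds=106_779, nonsynonymous=63_962, synonymous=42_817,
    ),
}

#: published effect percentages as printed (2 decimals)
PUBLISHED_EFFECT_PCT: dict[str, dict[str, float]] = {
    "indica_12": dict(intergenic=68.45, genic=31.55, nonsynonymous=58.62, synonymous=41.38),
    "indica_13": dict(intergenic=69.46, genic=30.54, nonsynonymous=59.20, synonymous=40.80),
    "indica_15": dict(intergenic=68.16, genic=31.84, nonsynonymous=58.41, synonymous=41.59),
    "japonica_11": dict(intergenic=66.10, genic=33.90, nonsynonymous=59.51, synonymous=40.49),
    "japonica_14": dict(intergenic=65.83, genic=34.17, nonsynonymous=59.90, synonymous=40.10),
}
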