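"""Published date-palm small-RNA study values used as pipeline inputs.

These are the printed per-library sequencing tallies, the printed conserved
mature miRNA sequences (a miRBase-style reference set at desk scale), and
the printed target-prediction tallies for the four-library leaf/root x
control/NaCl design.  They serve as fixed inputs for arithmetic checks and
as the default reference catalogue for the synthetic-data generator; the
package never re-derives them.
"""

from __future__ import annotations

LIBRARIES = ("leaf_control", "leaf_nacl", "root_control", "root_nacl")

#: per-library read tallies, {row: {"redundant": (4 cells), "unique": (4 cells)}};
#: cells are ordered as :data:`LIBRARIES`
LIBRARY_SUMMARY: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "total_reads": {
        "redundant": (69_820_252, 57_749_080, 53_893_175, 70_138_817),
        "unique": (5_488_113, 7_354_391, 6_018_618, 7_192_892),
    },
    "reads_after_filtration": {
        "redundant": (67_941_166, 53_269_570, 47_716_479, 63_423_863),
        "unique": (4_110_970, 5_632_666, 4_534_884, 5_235_066),
    },
    "mapped": {
        "redundant": (48_597_554, 39_388_275, 25_753_815, 34_829_777),
        "unique": (1_070_750, 1_405_067, 1_209_183, 1_511_547),
    },
    "known_small_rna": {
        "redundant": (26_439_310, 19_827_140, 18_686_729, 24_574_312),
        "unique": (348_574, 361_770, 443_727, 429_316),
    },
    "known_mirna": {
        "redundant": (376_803, 591_326, 224_471, 347_865),
        "unique": (5_176, 10_171, 6_194, 5_827),
    },
    "predicted_mirna": {
        "redundant": (314_899, 903_299, 36_325, 73_887),
        "unique": (4_434, 4_410, 2_622, 3_071),
    },
    "rRNA": {
        "redundant": (19_241_412, 8_896_131, 14_891_035, 20_437_750),
        "unique": (263_646, 210_394, 337_115, 332_132),
    },
    "tRNA": {
        "redundant": (3_090_812, 6_156_880, 1_293_910, 842_345),
        "unique": (32_510, 47_369, 40_966, 33_476),
    },
    "snoRNA": {
        "redundant": (613_764, 696_722, 429_123, 352_090),
        "unique": (35_143, 64_141, 42_891, 41_814),
    },
    "snRNA": {
        "redundant": (106_920, 238_688, 167_258, 159_847),
        "unique": (12_099, 29_695, 16_561, 16_067),
    },
    "no_hit": {
        "redundant": (19_343_612, 13_881_295, 21_962_664, 28_594_086),
        "unique": (3_040_220, 4_227_599, 3_325_701, 3_723_519),
    },
}

#: printed mature sequences of conserved date-palm miRNAs (subset with both
#: duplex arms reported); miRBase-style ids
REFERENCE_MATURE_MIRNAS: dict[str, str] = {
    "pda-miR156a": "UGACAGAAGAGAGUGAGCAC",
    "pda-miR156i-3p": "GCUCACUUCUCUUUCUGUCAGCC",
    "pda-miR156h": "UUGACAGAAGAUAGAGAGCAC",
    "pda-MIR156h-p3": "GCUCUCUAUGCUUCUGUCAUC",
    "pda-miR160a-5p": "UGCCUGGCUCCCUGUAUGCCA",
    "pda-miR160a-3p": "GCGUGCAAGGAGCCAAGCAU",
    "pda-miR166a-5p": "GGGAAUGUUGUCUGGUUCGAG",
    "pda-miR166a": "UCGGACCAGGCUUCAUUCCCC",
    "pda-miR166i-3p": "UCUCGGAUCAGGCUUCAUUCC",
    "pda-miR167a": "UGAAGCUGCCAGCAUGAUCUA",
    "pda-miR167b-3p": "GGUCAUGCUCUGACAGCCUCACU",
    "pda-miR168a": "UCGCUUGGUGCAGGUCGGGA",
    "pda-miR168a-3p": "CCCGCCUUGCAUCAACUGAA",
    "pda-miR169a": "UAGCCAAGGAUGACUUGCCU",
    "pda-miR169j-3p": "GGCAGUCUCCUUGGCUAGUC",
    "pda-miR172b-5p": "UGGCAUCAUCAAGAUUCACAU",
    "pda-miR172a": "GGAAUCUUGAUGAUGCUGCA",
    "pda-miR390a": "AAGCUCAGGAGGGAUAGCGCC",
    "pda-miR390a-3p": "CGCUAUCUAUCCUGAGUUU",
    "pda-miR393a": "UCCAAAGGGAUCGCAUUGAUC",
    "pda-miR393b-3p": "AUCAUGCGAUCCUUUUGGAU",
    "pda-miR394a-5p": "UUGGCAUUCUGUCCACCUCC",
    "pda-MIR394a-p3": "AGCUCUGUUGGCUUCUCUUUG",
    "pda-miR395": "CUGAAGUGUUUGGGGGAACG",
    "pda-miR395a-5p": "GUUCCCUCAGACACUUCAU",
    "pda-miR396a-5p": "UCACAGGCUUUCUUGAACU",
    "pda-miR396": "UUCCACGGCUUUCUUGAACU",
}

#: printed mature sequence of pda-miR156h (21 nt)
MIR156H_MATURE = REFERENCE_MATURE_MIRNAS["pda-miR156h"]

#: printed target-prediction tallies: (predicted targets, cleavage sites,
#: translational-inhibition sites)
TARGET_TALLIES = {
    "leaf": (898, 660, 239),
    "root": (721, 531, 190),
}

#: headline catalogue sizes reported for the full-scale study
HEADLINE_COUNTS = {"conserved": 153, "variants": 89, "novel": 180}
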