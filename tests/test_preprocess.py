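"""Adaptor trimming, filtering, collapsing and ncRNA annotation removal."""

from collections import Counter

import pytest

from palmirna.preprocess import (
    UniqueTag,
    collapse,
    filter_annotated,
    filter_reads,
    length_distribution,
    trim_adaptor,
)
from palmirna.published import REFERENCE_MATURE_MIRNAS
from palmirna.synthetic import LibraryDesign, generate_genome, simulate_libraries


def test_trim_exact_adaptor_at_offset():
    read = "ACGTACGTACGTACGTACGTA" + "TCGTATGCCG" + "TTTTT"
    assert trim_adaptor(read, "TCGTATGCCG") == "ACGTACGTACGTACGTACGTA"


def test_trim_rejects_when_no_adaptor():
    assert trim_adaptor("ACGT" * 9, "TTGGCCAATT") is None


def test_trim_leftmost_occurrence_wins():
    read = "AAAA" + "TCGTAT" + "CCCC" + "TCGTAT"
    assert trim_adaptor(read, "TCGTAT") == "AAAA"


def test_trim_tolerates_mismatch_within_rate():
    insert = "ACGTACGTACGTACGTACGTA"
    adaptor = "TCGTATGCCGTCTT"
    read = insert + "TCGTATGCCGTCAT"  # one mismatch in 14 nt (rate 0.07)
    assert trim_adaptor(read, adaptor, max_mismatch_rate=0.1) == insert


def test_trim_input_errors():
    with pytest.raises(ValueError):
        trim_adaptor("", "TCGTAT")
    with pytest.raises(ValueError):
        trim_adaptor("ACGT", "")
    with pytest.raises(ValueError):
        trim_adaptor("ACGTACGT", "TCGTAT", min_overlap=4)


def test_simulated_reads_trim_back_to_their_inserts():
    genome = generate_genome(
        30_000, 0.45, 4, 0, REFERENCE_MATURE_MIRNAS, seed=3
    )
    design = LibraryDesign("lib", 1000, seed=5, ncrna_fraction=0.0)
    fastq, truth = simulate_libraries(genome, [design])
    inserts = Counter()
    for rid, seq, _q in fastq["lib"]:
        insert = trim_adaptor(seq, design.adaptor_3p)
        assert insert is not None
        inserts[insert] += 1
    # every planted mature was recovered exactly, at its emitted count
    for t in genome.mir_loci:
        for arm, mat in (("5p", t.mature_5p), ("3p", t.mature_3p)):
            emitted = int(truth.loc[f"{t.locus_id}/{arm}", "lib"])
            assert inserts[mat.replace("U", "T")] >= emitted


def test_filter_reads_reasons_and_conservation():
    inserts = [
        ("A" * 17, 35.0),   # too short
        ("A" * 21, 35.0),   # kept
        ("A" * 26, 35.0),   # too long
        ("A" * 21, 10.0),   # low quality
    ]
    kept, stats = filter_reads(inserts)
    assert kept == ["A" * 21]
    assert (stats.too_short, stats.too_long, stats.low_quality, stats.kept) == (1, 1, 1, 1)
    assert stats.total == len(inserts)
    assert filter_reads([]) == ([], stats.__class__())


def test_collapse_counts_and_alphabet():
    tags = collapse({"lib1": ["AAGAAGAAGAAGAAGAAGT", "AAGAAGAAGAAGAAGAAGT",
                              "CCTCCTCCTCCTCCTCCTC"]})
    by_seq = {t.sequence: t for t in tags}
    assert by_seq["AAGAAGAAGAAGAAGAAGU"].counts == {"lib1": 2}
    assert by_seq["CCUCCUCCUCCUCCUCCUC"].counts == {"lib1": 1}


def test_collapse_shared_sequence_across_libraries():
    seq = "ACGUACGUACGUACGUACG"
    tags = collapse({"a": [seq], "b": [seq, seq]})
    assert len(tags) == 1
    assert tags[0].counts == {"a": 1, "b": 2}


def test_collapse_round_trips_the_multiset(rng):
    libs = {
        "x": ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(50)],
        "y": ["".join(rng.choice(list("ACGT"), size=21)) for _ in range(30)],
    }
    tags = collapse(libs)
    for lib, seqs in libs.items():
        expanded = Counter()
        for t in tags:
            expanded[t.sequence] += t.counts.get(lib, 0)
        assert expanded == Counter(s.replace("T", "U") for s in seqs)


def test_filter_annotated_priority_and_passthrough():
    rrna = "G" * 30 + "ACGUACGUACGUACGUACGUA" + "G" * 30
    trna = "C" * 20 + "ACGUACGUACGUACGUACGUA" + "C" * 20
    tags = collapse({"lib": ["ACGTACGTACGTACGTACGTA", "TTTTGGGGTTTTGGGGTTTT"]})
    passed, removed, tally = filter_annotated(
        tags, {"rRNA": [rrna], "tRNA": [trna]}
    )
    assert [t.category for t in removed] == ["rRNA"]  # priority over tRNA
    assert [t.sequence for t in passed] == ["UUUUGGGGUUUUGGGGUUUU"]
    assert tally.loc["rRNA", "lib_redundant"] == 1


def test_filter_annotated_rejects_unknown_category():
    with pytest.raises(ValueError):
        filter_annotated([], {"mRNA": ["ACGU"]})


def test_ncrna_fraction_recovered_from_synthetic_run():
    genome = generate_genome(
        40_000, 0.45, 3, 4, REFERENCE_MATURE_MIRNAS, seed=11
    )
    design = LibraryDesign("lib", 5000, seed=21, ncrna_fraction=0.3)
    fastq, truth = simulate_libraries(genome, [design])
    nc_reads = truth.loc[[i for i in truth.index if i.startswith("ncrna/")], "lib"].sum()
    total = truth["lib"].sum()
    frac = nc_reads / total
    # binomial 3-sigma band around the design fraction
    sigma = (0.3 * 0.7 / total) ** 0.5
    assert abs(frac - 0.3) < max(3 * sigma, 0.02)


def test_length_distribution_forced_arithmetic():
    tags = [
        UniqueTag("A" * 21, {"lib": 9}),
        UniqueTag("C" * 24, {"lib": 1}),
    ]
    table = length_distribution(tags)
    assert table[("lib", "redundant")][21] == pytest.approx(90.0)
    assert table[("lib", "redundant")][24] == pytest.approx(10.0)
    assert table[("lib", "unique")][21] == pytest.approx(50.0)
    assert table[("lib", "unique")][24] == pytest.approx(50.0)
    assert table.sum(axis=0).to_numpy() == pytest.approx([100.0, 100.0])


def test_length_distribution_single_tag_and_empty():
    single = length_distribution([UniqueTag("G" * 21, {"lib": 5})])
    assert single[("lib", "redundant")][21] == pytest.approx(100.0)
    assert single[("lib", "unique")][21] == pytest.approx(100.0)
    assert length_distribution([]).empty


def test_unique_tag_invariants():
    with pytest.raises(ValueError):
        UniqueTag("A" * 17, {"lib": 1})
    with pytest.raises(ValueError):
        UniqueTag("A" * 20, {"lib": 0})
    with pytest.raises(ValueError):
        UniqueTag("A" * 20, {"lib": -1})
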