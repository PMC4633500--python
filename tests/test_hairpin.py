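"""Hairpin criteria evaluation, windows, MFEI and duplex detection."""

import dataclasses

import numpy as np
import pytest

from palmirna.folding import (
    SecondaryStructure,
    dotbracket_to_pairs,
    fold,
    pairs_to_table,
)
from palmirna.hairpin import (
    HairpinCriteria,
    PrecursorWindow,
    TagOnWindow,
    compute_mfei,
    detect_duplex,
    evaluate_hairpin,
    extract_candidate_windows,
)
from palmirna.mapping import Alignment
from palmirna.published import REFERENCE_MATURE_MIRNAS
from palmirna.synthetic import generate_genome


def _evaluate(seq, tags, criteria=HairpinCriteria()):
    window = PrecursorWindow("c", 0, len(seq), "+", seq)
    return evaluate_hairpin(window, fold(seq), tags, criteria)


def test_mfei_arithmetic():
    assert compute_mfei(-60.0, 100, 0.50) == pytest.approx(1.2)
    assert compute_mfei(0.0, 100, 0.50) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        compute_mfei(-60.0, 100, 0.0)
    with pytest.raises(ValueError):
        compute_mfei(-60.0, 0, 0.5)


def test_sixteen_pair_stem_passes_all_criteria():
    seq = "G" * 16 + "A" * 25 + "C" * 16  # 57 nt, perfect 16-bp stem
    cand = _evaluate(seq, [TagOnWindow("G" * 16 + "AA", 0, 10)])
    assert cand.passed, cand.report
    assert cand.stem_bp_count == 16
    assert cand.terminal_loop_len == 25
    assert len(cand.precursor_seq) == 57
    assert cand.mfe == pytest.approx(16 * -3.0 + 15 * -0.5 + 3.0)


def test_fifteen_pair_stem_fails_only_min_stem_bp():
    seq = "G" * 15 + "A" * 27 + "C" * 15
    cand = _evaluate(seq, [TagOnWindow("G" * 15 + "AAA", 0, 10)])
    assert not cand.passed
    failing = [k for k, (_, _, _, ok) in cand.report.items() if not ok]
    assert failing == ["stem_bp"]
    assert cand.report["stem_bp"][0] == 15


def test_weak_stem_fails_free_energy():
    seq = "A" * 20 + "G" * 6 + "A" * 45 + "C" * 6 + "A" * 20
    # 6 GC pairs: mfe = -18 - 2.5 + 3 = -17.5 .. make it weaker with AU
    seq = "A" * 6 + "C" * 45 + "U" * 6
    cand = _evaluate(seq, [TagOnWindow("A" * 6 + "CCC", 0, 12)])
    assert cand.mfe == pytest.approx(6 * -2.0 + 5 * -0.5 + 3.0)  # -11.5
    assert not cand.report["free_energy"][3]
    assert not cand.passed


def test_read_support_thresholds():
    seq = "G" * 16 + "A" * 25 + "C" * 16
    tag = TagOnWindow("G" * 16 + "AA", 0, 9)
    cand = _evaluate(seq, [tag])
    assert not cand.report["total_reads"][3]
    cand = _evaluate(seq, [dataclasses.replace(tag, count=10)])
    assert cand.report["total_reads"][3] and cand.passed


def test_multibranch_subtree_fails_single_hairpin():
    # hand-built structure: an outer stem enclosing two terminal loops
    db = "((((..((((....))))..((((....))))..))))"
    seq = "G" * len(db)
    pairs = dotbracket_to_pairs(db)
    structure = SecondaryStructure(seq, db, -20.0, pairs_to_table(pairs, len(db)))
    window = PrecursorWindow("c", 0, len(seq), "+", seq)
    tag = TagOnWindow(seq[:18], 1, 50)
    cand = evaluate_hairpin(window, structure, [tag])
    assert not cand.passed
    assert cand.fail_reason == "not a single hairpin"


def test_mature_outside_any_hairpin_fails():
    seq = "GGGGAAAACCCC" + "A" * 40
    window = PrecursorWindow("c", 0, len(seq), "+", seq)
    cand = evaluate_hairpin(window, fold(seq), [TagOnWindow("A" * 20, 30, 50)])
    assert not cand.passed and "not enclosed" in cand.fail_reason


def test_verdict_is_monotone_under_threshold_relaxation(rng):
    seq = "G" * 16 + "A" * 25 + "C" * 16
    base = HairpinCriteria()
    cand0 = _evaluate(seq, [TagOnWindow("G" * 16 + "AA", 0, 10)], base)
    for _ in range(30):
        relaxed = HairpinCriteria(
            max_errors_one_bulge_stem=base.max_errors_one_bulge_stem + int(rng.integers(0, 5)),
            min_stem_bp=base.min_stem_bp - int(rng.integers(0, 5)),
            max_free_energy=base.max_free_energy + float(rng.uniform(0, 10)),
            min_hairpin_len=base.min_hairpin_len - int(rng.integers(0, 10)),
            max_terminal_loop=base.max_terminal_loop + int(rng.integers(0, 50)),
            max_errors_one_bulge_mature=base.max_errors_one_bulge_mature + int(rng.integers(0, 4)),
            max_biased_errors_one_bulge_mature=base.max_biased_errors_one_bulge_mature + int(rng.integers(0, 4)),
            max_biased_bulges_mature=base.max_biased_bulges_mature + int(rng.integers(0, 3)),
            min_mature_bp=base.min_mature_bp - int(rng.integers(0, 5)),
            min_pm_stem_fraction=base.min_pm_stem_fraction - float(rng.uniform(0, 0.3)),
            max_errors_mature=base.max_errors_mature + int(rng.integers(0, 4)),
            min_total_reads=base.min_total_reads - int(rng.integers(0, 5)),
            stringent_max_mfe=base.stringent_max_mfe + float(rng.uniform(0, 20)),
            min_mfei=base.min_mfei - float(rng.uniform(0, 0.5)),
            min_precursor_len=base.min_precursor_len - int(rng.integers(0, 10)),
            max_precursor_len=base.max_precursor_len + int(rng.integers(0, 50)),
        )
        cand1 = _evaluate(seq, [TagOnWindow("G" * 16 + "AA", 0, 10)], relaxed)
        assert not (cand0.passed and not cand1.passed)


def test_criteria_validation():
    with pytest.raises(ValueError):
        HairpinCriteria(max_free_energy=5.0)
    with pytest.raises(ValueError):
        HairpinCriteria(min_pm_stem_fraction=0.0)


def _planted_candidate(seed=13):
    genome = generate_genome(20_000, 0.45, 1, 0, REFERENCE_MATURE_MIRNAS, seed=seed)
    t = genome.mir_loci[0]
    seq = t.precursor_seq
    tags = [
        TagOnWindow(t.mature_5p, t.mature_5p_offset, 30),
        TagOnWindow(t.mature_3p, t.mature_3p_offset, 10),
    ]
    window = PrecursorWindow(t.chrom, t.start, t.end, t.strand, seq)
    return evaluate_hairpin(window, fold(seq), tags), t


def test_planted_duplex_recovered_with_two_nt_overhangs():
    cand, _t = _planted_candidate()
    assert cand.passed
    duplex = detect_duplex(cand)
    assert duplex is not None
    assert (duplex.overhang_5p_side, duplex.overhang_3p_side) == (2, 2)


def test_duplex_absent_with_one_arm_only():
    cand, t = _planted_candidate()
    one_arm = evaluate_hairpin(
        cand.window, cand.structure, [TagOnWindow(t.mature_5p, t.mature_5p_offset, 30)]
    )
    assert one_arm.passed  # candidate retained without duplex evidence
    assert detect_duplex(one_arm) is None


def test_duplex_rejects_three_nt_overhang():
    cand, t = _planted_candidate()
    shifted = evaluate_hairpin(
        cand.window,
        cand.structure,
        [
            TagOnWindow(t.mature_5p, t.mature_5p_offset, 30),
            TagOnWindow(t.mature_3p, t.mature_3p_offset + 1, 10),
        ],
    )
    assert detect_duplex(shifted) is None


def test_window_ladder_interior_and_edges():
    genome = {"c": "ACGT" * 300}
    interior = Alignment("A" * 21, "c", 500, "+", ())
    windows = extract_candidate_windows(interior, genome)
    assert len(windows) >= 6
    assert all(len(w) >= 50 for w in windows)
    edge = Alignment("A" * 21, "c", 2, "+", ())
    for w in extract_candidate_windows(edge, genome):
        assert w.start >= 0 and w.end <= 1200


def test_ladder_covers_planted_precursor():
    genome = generate_genome(20_000, 0.45, 2, 0, REFERENCE_MATURE_MIRNAS, seed=29)
    for t in genome.mir_loci:
        if t.strand == "+":
            start = t.start + t.mature_5p_offset
        else:
            start = t.end - t.mature_5p_offset - len(t.mature_5p)
        aln = Alignment(
            t.mature_5p.replace("U", "T"), t.chrom, start, t.strand, ()
        )
        windows = extract_candidate_windows(aln, genome.contigs)
        assert any(w.start <= t.start and w.end >= t.end for w in windows)
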