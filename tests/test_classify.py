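"""Conserved/variant/novel classification, families, presence sets."""

from itertools import combinations

import numpy as np
import pytest

from palmirna.classify import (
    MiRNAAnnotation,
    assign_family,
    classify_mirna,
    match_reference,
    presence_sets,
)


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "U", "U": "A"}[out[p]]
    return "".join(out)


def test_exact_match_is_found(reference_set):
    assert match_reference("UGACAGAAGAGAGUGAGCAC", reference_set) == (
        "pda-miR156a", 0,
    )


def test_two_mismatch_match(reference_set):
    query = _mutate(reference_set["pda-miR160a-5p"], [3, 7])
    ref, mm = match_reference(query, reference_set)
    assert mm == 2


def test_no_match_beyond_budget(reference_set):
    query = _mutate(reference_set["pda-miR160a-5p"], [3, 7, 11])
    assert match_reference(query, reference_set, max_mismatches=2) is None


def test_match_requires_min_overlap():
    assert match_reference("ACGUACGUACGUACGUACGU", {"r": "ACGUACGUACGUACG"}) is None


def test_empty_reference_rejected():
    with pytest.raises(ValueError):
        match_reference("ACGUACGUACGUACGUACGU", {})


def test_match_equals_exhaustive_scan(rng):
    """Independent all-placements scan over random queries/references."""
    bases = np.array(list("ACGU"))
    refs = {
        f"ref{i:02d}": "".join(rng.choice(bases, size=int(rng.integers(18, 25))))
        for i in range(12)
    }
    for _ in range(60):
        q = "".join(rng.choice(bases, size=int(rng.integers(16, 26))))
        if rng.random() < 0.5:  # bias towards near-matches
            base = refs[f"ref{int(rng.integers(12)):02d}"]
            k = int(rng.integers(0, 3))
            q = _mutate(base, rng.choice(len(base), size=k, replace=False))
        best = None
        for rid in sorted(refs):
            r = refs[rid]
            short, long = (q, r) if len(q) <= len(r) else (r, q)
            if len(short) < 16:
                continue
            for off in range(len(long) - len(short) + 1):
                mm = sum(1 for i in range(len(short)) if short[i] != long[off + i])
                if mm <= 2:
                    key = (mm, -len(short), rid)
                    if best is None or key < best:
                        best = key
        expected = None if best is None else (best[2], best[0])
        assert match_reference(q, refs) == expected


def test_classification_rules(reference_set):
    seq = reference_set["pda-miR167a"]
    conserved = classify_mirna(seq, 100, ("pda-miR167a", 0))
    assert conserved.klass == "conserved" and conserved.mismatches == 0
    variant = classify_mirna(_mutate(seq, [2, 5]), 100, ("pda-miR167a", 2))
    assert variant.klass == "variant" and variant.mismatches == 2
    # no reference counterpart: read support decides
    assert classify_mirna("ACGUACGUACGUACGUACGUA", 9, None) is None
    novel = classify_mirna("ACGUACGUACGUACGUACGUA", 10, None, arm="3p", serial=8)
    assert novel.klass == "novel"
    assert novel.mirna_id == "pda-3p-8_10"


def test_variant_band_switch(reference_set):
    # a 3-mismatch best hit is outside the default 1-2 variant band (it
    # falls through to the novel rules) but inside the widened 1-3 band
    match = ("pda-miR167a", 3)
    default_band = classify_mirna("A" * 21, 50, match, variant_max_mismatches=2)
    assert default_band.klass == "novel"
    widened = classify_mirna("A" * 21, 50, match, variant_max_mismatches=3)
    assert widened.klass == "variant" and widened.mismatches == 3


def test_family_parsing():
    assert assign_family("osa-miR156a-5p") == "miR156"
    assert assign_family("ath-miR396b") == "miR396"
    assert assign_family("pda-MIR394a-p3") == "miR394"
    with pytest.warns(UserWarning):
        assert assign_family("not-an-id") is None


def test_family_sizes_on_constructed_set():
    refs = [
        "osa-miR156a", "osa-miR156b-5p", "ath-miR156c", "zma-miR166a",
        "ath-miR166b", "osa-miR396a", "osa-miR396b", "osa-miR396c-3p",
        "ath-miR408", "ppt-miR319a",
    ]
    families = {}
    for r in refs:
        families.setdefault(assign_family(r), 0)
        families[assign_family(r)] += 1
    assert families == {"miR156": 3, "miR166": 2, "miR396": 3, "miR408": 1, "miR319": 1}


def test_annotation_invariants():
    with pytest.raises(ValueError):
        MiRNAAnnotation("x", "A" * 20, "5p", "conserved", "r", 1, "miR1")
    with pytest.raises(ValueError):
        MiRNAAnnotation("x", "A" * 20, "5p", "novel", "r", None, None)
    with pytest.raises(ValueError):
        MiRNAAnnotation("x", "A" * 20, "5p", "conserved", "r", 0, None)


def _annotation(i):
    return MiRNAAnnotation(f"m{i}", "A" * 20, "5p", "novel", None, None, None)


def test_presence_simple_cases():
    anns = [_annotation(0), _annotation(1)]
    counts = {"m0": {"a": 5, "b": 0, "c": 0, "d": 0},
              "m1": {"a": 2, "b": 1, "c": 9, "d": 3}}
    present, inter = presence_sets(anns, counts)
    assert present["a"] == {"m0", "m1"}
    assert present["b"] == {"m1"}
    assert inter[frozenset({"a", "b", "c", "d"})] == 1  # m1 everywhere


def test_presence_matches_set_algebra_oracle(rng):
    libs = ["a", "b", "c", "d"]
    anns = [_annotation(i) for i in range(20)]
    counts = {
        f"m{i}": {lib: int(rng.integers(0, 4)) for lib in libs} for i in range(20)
    }
    present, inter = presence_sets(anns, counts)
    for r in range(2, 5):
        for combo in combinations(libs, r):
            expected = [
                m for m in counts if all(counts[m][lib] >= 1 for lib in combo)
            ]
            assert inter[frozenset(combo)] == len(expected)
    # inclusion-exclusion for the union of two libraries
    union = len(present["a"] | present["b"])
    assert union == len(present["a"]) + len(present["b"]) - inter[frozenset({"a", "b"})]


def test_presence_needs_two_libraries():
    with pytest.raises(ValueError):
        presence_sets([_annotation(0)], {"m0": {"a": 1}})
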