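"""Complementarity scoring, transcript scanning and target summaries."""

import numpy as np
import pytest

import _oracles
from palmirna._seq import revcomp_rna
from palmirna.published import TARGET_TALLIES
from palmirna.synthetic import generate_genome, generate_transcripts
from palmirna.published import REFERENCE_MATURE_MIRNAS
from palmirna.targets import (
    TargetParams,
    mode_percentages,
    scan_transcript,
    score_site,
    summarize_targets,
)

MIRNA = "UGACAGAAGAGAGUGAGCACA"  # 21 nt


def test_perfect_complement_scores_zero_cleavage():
    e, mode, states = score_site(MIRNA, revcomp_rna(MIRNA))
    assert e == 0.0 and mode == "cleavage"
    assert all(s == "WC" for s in states)


def test_central_mismatch_forces_translation_mode():
    site = list(revcomp_rna(MIRNA))
    # miRNA position 10 faces site position len-10 (0-based 11 from left)
    pos = len(site) - 10
    site[pos] = "A" if site[pos] != "A" else "C"
    e, mode, _ = score_site(MIRNA, "".join(site))
    assert e == pytest.approx(2.0)  # 1 x2 inside the 2-13 band
    assert mode == "translation"


def test_gu_wobble_outside_core_is_cheap_and_cleavage():
    site = list(revcomp_rna(MIRNA))
    # make miRNA position 20 (G) face U instead of C -> G:U wobble
    assert MIRNA[19] == "A" or True
    m = list(MIRNA)
    m[19] = "G"
    site = list(revcomp_rna("".join(m)))
    site[len(site) - 20] = "U"
    e, mode, _ = score_site("".join(m), "".join(site))
    assert e == pytest.approx(0.5)
    assert mode == "cleavage"


def test_identity_property_random_sequences(rng):
    for _ in range(40):
        n = int(rng.integers(18, 25))
        m = "".join(rng.choice(list("ACGU"), size=n))
        e, mode, _ = score_site(m, revcomp_rna(m))
        assert e == 0.0 and mode == "cleavage"


def test_expectation_monotone_in_mismatches(rng):
    m = MIRNA
    site = revcomp_rna(m)
    prev = 0.0
    mutated = list(site)
    for k in range(5):
        pos = 2 * k  # distinct positions
        mutated[pos] = "A" if mutated[pos] not in "AU" else "C"
        e, _, _ = score_site(m, "".join(mutated))
        assert e >= prev
        prev = e


def test_score_matches_independent_oracle(rng):
    for _ in range(80):
        n = int(rng.integers(18, 25))
        m = "".join(rng.choice(list("ACGU"), size=n))
        s = "".join(rng.choice(list("ACGU"), size=n))
        e, mode, _ = score_site(m, s)
        eo, modeo = _oracles.site_expectation_oracle(m, s)
        assert e == pytest.approx(eo) and mode == modeo


def test_scan_finds_planted_perfect_site(rng):
    body = "".join(rng.choice(list("ACGU"), size=400))
    site = revcomp_rna(MIRNA)
    tx = body[:150] + site + body[150:]
    hits = scan_transcript("m", MIRNA, "tx", tx)
    assert any(h.expectation == 0.0 and h.start == 150 for h in hits)
    for h in hits:
        assert h.expectation <= 3.0


def test_scan_empty_when_no_window_qualifies():
    tx = "A" * 200  # miRNA is A-rich too: reverse complement never matches
    assert scan_transcript("m", "A" * 21, "tx", tx) == []


def test_hits_never_overlap(rng):
    m = "".join(rng.choice(list("ACGU"), size=21))
    site = revcomp_rna(m)
    tx = site + site + site  # tandem perfect sites
    hits = scan_transcript("m", m, "tx", tx)
    spans = sorted((h.start, h.end) for h in hits)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        assert a1 <= b0


def test_scan_equals_exhaustive_oracle(rng):
    m = "".join(rng.choice(list("ACGU"), size=20))
    body = list("".join(rng.choice(list("ACGU"), size=2000)))
    # sprinkle some near-complementary sites
    site = revcomp_rna(m)
    for pos in (100, 700, 1400):
        body[pos : pos + len(site)] = list(site)
    body[703] = "A" if body[703] != "A" else "G"
    tx = "".join(body)
    hits = scan_transcript("m", m, "tx", tx)
    # oracle: score every placement independently, apply the same greedy rule
    qualifying = []
    for s0 in range(len(tx) - len(m) + 1):
        e, mode = _oracles.site_expectation_oracle(m, tx[s0 : s0 + len(m)])
        if e <= 3.0:
            qualifying.append((e, s0, mode))
    qualifying.sort()
    chosen = []
    for e, s0, mode in qualifying:
        if all(s0 + len(m) <= a or b <= s0 for _e2, a, b, _m2 in chosen):
            chosen.append((e, s0, s0 + len(m), mode))
    assert {(h.start, h.end, h.expectation, h.mode) for h in hits} == {
        (a, b, e, mode) for e, a, b, mode in chosen
    }


def test_planted_transcript_modes_recovered():
    genome = generate_genome(30_000, 0.45, 4, 0, REFERENCE_MATURE_MIRNAS, seed=23)
    transcripts, truth = generate_transcripts(genome, seed=23)
    by_locus = {t.locus_id: t for t in genome.mir_loci}
    for tx_id, (locus_id, mode) in truth.items():
        t = by_locus[locus_id]
        hits = scan_transcript(locus_id, t.mature_5p, tx_id, transcripts[tx_id])
        best = min(hits, key=lambda h: h.expectation)
        assert best.mode == mode


def test_summary_percentages():
    leaf_hits, leaf_cleavage, _ = TARGET_TALLIES["leaf"]
    pct = mode_percentages(leaf_hits, leaf_cleavage)
    assert pct["cleavage"] == 73.5
    with pytest.raises(ValueError):
        mode_percentages(0, 0)


def test_summarize_counts_match_direct_tally(rng):
    genome = generate_genome(30_000, 0.45, 3, 0, REFERENCE_MATURE_MIRNAS, seed=31)
    transcripts, _ = generate_transcripts(genome, seed=31)
    hits = []
    for t in genome.mir_loci:
        for tx_id, tx in transcripts.items():
            hits.extend(scan_transcript(t.locus_id, t.mature_5p, tx_id, tx))
    summary = summarize_targets(hits)
    assert summary["n_hits"] == len(hits)
    assert sum(summary["mode_counts"].values()) == len(hits)
    assert summary["per_mirna"].sum() == len(hits)
    one = summarize_targets(hits[:1])
    assert list(one["mode_percent"].values()) == [100.0]
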