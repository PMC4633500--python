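"""Classify accepted mature sequences against a reference mature-miRNA set.

A mature sequence with an exact (0-mismatch) containment match to a
reference catalogue entry is *conserved*; with 1-2 mismatches (optionally
1-3) it is a *variant*; with no acceptable match it is *novel* provided it
carries at least 10 reads across the libraries and its precursor passed the
hairpin filter.  Families are named from the numeric field of the matched
miRBase-style identifier (e.g. osa-miR156a-5p -> miR156).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from ._seq import to_rna

NOVEL_MIN_TOTAL_READS = 10


@dataclass
class MiRNAAnnotation:
    mirna_id: str
    mature_seq: str  # RNA alphabet
    arm: str  # '5p', '3p' or 'unknown'
    klass: str  # 'conserved', 'variant' or 'novel'
    reference_match: str | None
    mismatches: int | None
    family: str | None
    duplex_partner: str | None = None
    precursor_id: str | None = None

    def __post_init__(self) -> None:
        if self.klass == "conserved" and self.mismatches != 0:
            raise ValueError("conserved miRNA must have 0 mismatches")
        if self.klass == "variant" and self.mismatches not in (1, 2, 3):
            raise ValueError("variant miRNA must have 1-3 mismatches")
        if self.klass == "novel" and self.reference_match is not None:
            raise ValueError("novel miRNA cannot carry a reference match")
        if (self.family is not None) != (self.reference_match is not None):
            raise ValueError("family present iff reference_match present")


def _placements(short: str, long: str) -> list[int]:
    return list(range(len(long) - len(short) + 1))


def match_reference(
    query: str,
    reference: dict[str, str],
    max_mismatches: int = 2,
    min_overlap: int = 16,
) -> tuple[str, int] | None:
    """Best ungapped containment match of ``query`` in a reference set.

    The shorter of query/reference must be fully contained in the longer
    with overlap >= ``min_overlap``; best = fewest mismatches, ties broken
    by longer overlap then lexicographically smallest reference id.
    Returns ``(reference id, mismatch count)`` or ``None``.
    """
    if not reference:
        raise ValueError("reference set is empty")
    q = to_rna(query)
    best: tuple[int, int, str] | None = None  # (mm, -overlap, ref_id)
    for ref_id in sorted(reference):
        ref = to_rna(reference[ref_id])
        short, long = (q, ref) if len(q) <= len(ref) else (ref, q)
        overlap = len(short)
        if overlap < min_overlap:
            continue
        for off in _placements(short, long):
            mm = sum(1 for i in range(overlap) if short[i] != long[off + i])
            if mm > max_mismatches:
                continue
            key = (mm, -overlap, ref_id)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[2], best[0]


def assign_family(reference_id: str) -> str | None:
    """miRBase-style id -> family name ("miR" + leading digits)."""
    m = re.search(r"mir(\d+)", reference_id, flags=re.IGNORECASE)
    if m is None:
        warnings.warn(f"cannot parse family from {reference_id!r}")
        return None
    return f"miR{m.group(1)}"


def classify_mirna(
    mature_seq: str,
    total_reads: int,
    match: tuple[str, int] | None,
    arm: str = "unknown",
    serial: int = 1,
    variant_max_mismatches: int = 2,
) -> MiRNAAnnotation | None:
    """Classify a hairpin-validated mature sequence.

    0 mismatches -> conserved; 1..variant_max_mismatches -> variant; no match
    -> novel iff total reads >= 10, else ``None`` (discarded).  Novel ids
    embed arm, a serial and the total read count (pda-3p-<serial>_<reads>).
    """
    seq = to_rna(mature_seq)
    if match is not None and match[1] <= variant_max_mismatches:
        ref_id, mm = match
        core = re.sub(r"^[a-z]{2,4}-", "", ref_id, flags=re.IGNORECASE)
        family = assign_family(ref_id)
        if mm == 0:
            return MiRNAAnnotation(
                f"pda-{core}", seq, arm, "conserved", ref_id, 0, family
            )
        return MiRNAAnnotation(
            f"pda-{core}_{mm}mm", seq, arm, "variant", ref_id, mm, family
        )
    if total_reads < NOVEL_MIN_TOTAL_READS:
        return None
    arm_tag = arm if arm in ("5p", "3p") else "xp"
    return MiRNAAnnotation(
        f"pda-{arm_tag}-{serial}_{total_reads}", seq, arm, "novel", None, None, None
    )


def presence_sets(
    annotations: list[MiRNAAnnotation],
    counts: dict[str, dict[str, int]],
    min_count: int = 1,
) -> tuple[dict[str, set[str]], dict[frozenset[str], int]]:
    """Per-library presence sets and all >= 2-way intersection counts.

    ``counts`` maps mirna_id -> {library: count}; a miRNA is present in a
    library when its count there is >= ``min_count``.
    """
    libraries = sorted({lib for c in counts.values() for lib in c})
    if len(libraries) < 2:
        raise ValueError("at least two libraries are required")
    present = {
        lib: {
            a.mirna_id
            for a in annotations
            if counts.get(a.mirna_id, {}).get(lib, 0) >= min_count
        }
        for lib in libraries
    }
    inter: dict[frozenset[str], int] = {}
    from itertools import combinations

    for r in range(2, len(libraries) + 1):
        for combo in combinations(libraries, r):
            s = set.intersection(*(present[lib] for lib in combo))
            inter[frozenset(combo)] = len(s)
    return present, inter
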