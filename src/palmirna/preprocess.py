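"""From raw small-RNA reads to unique tags with per-library counts.

The stages mirror standard small-RNA practice: 3' adaptor removal, length
and quality filtering (18-25 nt inserts), collapsing identical inserts into
unique tags, and removal of tags contained in annotated structural ncRNAs
(rRNA, tRNA, snoRNA, snRNA).  Every read is accounted for exactly once; the
per-stage tallies feed the run summary table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._seq import to_dna, to_rna

NCRNA_PRIORITY = ("rRNA", "tRNA", "snoRNA", "snRNA")
MIN_TAG_LEN = 18
MAX_TAG_LEN = 25


@dataclass
class UniqueTag:
    """A distinct 18-25 nt insert with per-library read counts."""

    sequence: str  # RNA alphabet
    counts: dict[str, int]
    category: str = "unassigned"

    def __post_init__(self) -> None:
        if not (MIN_TAG_LEN <= len(self.sequence) <= MAX_TAG_LEN):
            raise ValueError(
                f"tag length {len(self.sequence)} outside "
                f"[{MIN_TAG_LEN}, {MAX_TAG_LEN}]"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count")
        if self.counts and not any(self.counts.values()):
            raise ValueError("tag with all-zero counts")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class TrimStats:
    trimmed: int = 0
    no_adaptor: int = 0


@dataclass
class FilterStats:
    kept: int = 0
    too_short: int = 0
    too_long: int = 0
    low_quality: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.too_short + self.too_long + self.low_quality


def trim_adaptor(
    read: str,
    adaptor_3p: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> str | None:
    """Return the insert preceding the leftmost 3' adaptor occurrence.

    An occurrence at read offset ``p`` covers ``min(len(adaptor),
    len(read) - p)`` nucleotides; it qualifies when that overlap is at least
    ``min_overlap`` and its mismatch fraction is at most
    ``max_mismatch_rate``.  ``None`` signals "no adaptor found" (the insert
    presumably ran past the read end) and the read is rejected upstream.
    """
    if not read or not adaptor_3p:
        raise ValueError("empty read or adaptor")
    if min_overlap < 6:
        raise ValueError("min_overlap must be >= 6")
    read = to_dna(read)
    adaptor = to_dna(adaptor_3p)
    for p in range(0, len(read) - min_overlap + 1):
        overlap = min(len(adaptor), len(read) - p)
        mismatches = sum(
            1 for i in range(overlap) if read[p + i] != adaptor[i]
        )
        if mismatches <= max_mismatch_rate * overlap:
            return read[:p]
    return None


def filter_reads(
    inserts: list[tuple[str, float]],
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    min_mean_quality: float = 20.0,
) -> tuple[list[str], FilterStats]:
    """Keep inserts within [min_len, max_len] whose mean Phred quality
    passes; ``inserts`` is a list of (sequence, mean quality) pairs."""
    if min_len <= 0 or max_len <= 0:
        raise ValueError("length thresholds must be positive")
    kept: list[str] = []
    stats = FilterStats()
    for seq, mean_q in inserts:
        if len(seq) < min_len:
            stats.too_short += 1
        elif len(seq) > max_len:
            stats.too_long += 1
        elif mean_q < min_mean_quality:
            stats.low_quality += 1
        else:
            kept.append(seq)
            stats.kept += 1
    return kept, stats


def collapse(inserts_per_library: dict[str, list[str]]) -> list[UniqueTag]:
    """Collapse filtered inserts into unique tags (RNA alphabet).

    Per-library counts sum to the per-library input sizes; tags are sorted
    by descending total count then sequence for determinism.
    """
    libraries = list(inserts_per_library)
    counters = {lib: Counter(map(to_rna, seqs)) for lib, seqs in inserts_per_library.items()}
    all_seqs = set()
    for c in counters.values():
        all_seqs.update(c)
    tags = [
        UniqueTag(seq, {lib: counters[lib].get(seq, 0) for lib in libraries})
        for seq in all_seqs
    ]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def filter_annotated(
    tags: list[UniqueTag],
    annotation: dict[str, list[str]],
) -> tuple[list[UniqueTag], list[UniqueTag], pd.DataFrame]:
    """Partition tags into (unassigned, annotated ncRNA) by exact substring.

    ``annotation`` maps a category (subset of rRNA/tRNA/snoRNA/snRNA) to its
    sequences.  A tag takes the first category, in the fixed priority order
    rRNA > tRNA > snoRNA > snRNA, whose sequences contain it exactly.
    Returns the pass-through tags, the annotated tags (category set), and a
    per-category tally frame (redundant and unique, per library).
    """
    bad = set(annotation) - set(NCRNA_PRIORITY)
    if bad:
        raise ValueError(f"unknown annotation categories: {sorted(bad)}")
    norm = {
        cat: [to_rna(s) for s in seqs] for cat, seqs in annotation.items()
    }
    libraries = sorted({lib for t in tags for lib in t.counts})
    passed: list[UniqueTag] = []
    removed: list[UniqueTag] = []
    rows: dict[str, dict[str, int]] = {}
    for t in tags:
        cat = None
        for c in NCRNA_PRIORITY:
            if c in norm and any(t.sequence in ref for ref in norm[c]):
                cat = c
                break
        if cat is None:
            passed.append(t)
        else:
            t.category = cat
            removed.append(t)
            row = rows.setdefault(cat, {f"{lib}_redundant": 0 for lib in libraries})
            for lib in libraries:
                row[f"{lib}_redundant"] = row.get(f"{lib}_redundant", 0) + t.counts.get(lib, 0)
                row[f"{lib}_unique"] = row.get(f"{lib}_unique", 0) + (
                    1 if t.counts.get(lib, 0) > 0 else 0
                )
    tally = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    tally = tally.reindex([c for c in NCRNA_PRIORITY if c in rows])
    return passed, removed, tally


def length_distribution(tags: list[UniqueTag]) -> pd.DataFrame:
    """Per-length percentage table (18-25 nt), redundant and unique.

    Columns are a MultiIndex (library, {redundant, unique}); each column
    sums to 100% over the represented lengths.  Empty input gives an empty
    frame.
    """
    if not tags:
        return pd.DataFrame()
    libraries = sorted({lib for t in tags for lib in t.counts})
    lengths = range(MIN_TAG_LEN, MAX_TAG_LEN + 1)
    data: dict[tuple[str, str], list[float]] = {}
    for lib in libraries:
        red = Counter()
        uni = Counter()
        for t in tags:
            c = t.counts.get(lib, 0)
            if c > 0:
                red[t.length] += c
                uni[t.length] += 1
        rtot = sum(red.values()) or 1
        utot = sum(uni.values()) or 1
        data[(lib, "redundant")] = [100.0 * red.get(n, 0) / rtot for n in lengths]
        data[(lib, "unique")] = [100.0 * uni.get(n, 0) / utot for n in lengths]
    frame = pd.DataFrame(data, index=pd.Index(lengths, name="length"))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["library", "kind"])
    return frame
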