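"""Candidate precursor excision and hairpin criteria filtering.

Around every tag alignment a ladder of genomic windows is cut, folded, and
screened against the full hairpin rule set used for plant miRNA precursor
calling: stem pairing, free energy, terminal-loop size, per-bulge error
budgets in the stem and the mature region, the fraction of supporting small
RNAs on the stem (pm), a minimum read support, plus the stringent MFE <= -40
kcal/mol and MFEI >= 0.85 cut-offs.  A precursor is the single-hairpin
subtree of the folded window that contains the supporting tag; windows whose
tag-bearing subtree branches into several terminal loops are rejected as
"not a single hairpin".

"Errors" follow the stem-loop pipeline convention: an error is an unpaired
nucleotide; a bulge is a maximal run of unpaired positions on one arm; a
biased bulge is such a run with no opposing unpaired run on the partner arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from ._seq import gc_fraction, revcomp_dna, to_dna, to_rna
from .folding import SecondaryStructure, _direct_children, score_structure
from .mapping import Alignment

WINDOW_FLANKS = (20, 60, 120, 250)
ASYM_NEAR_FLANK = 5  # short-side flank of the asymmetric window variants


@dataclass(frozen=True)
class HairpinCriteria:
    """Thresholds of the hairpin filter (defaults are the study settings)."""

    max_errors_one_bulge_stem: int = 12
    min_stem_bp: int = 16
    max_free_energy: float = -15.0  # kcal/mol
    min_hairpin_len: int = 50
    max_terminal_loop: int = 350
    max_errors_one_bulge_mature: int = 8
    max_biased_errors_one_bulge_mature: int = 4
    max_biased_bulges_mature: int = 2
    min_mature_bp: int = 12
    min_pm_stem_fraction: float = 0.80
    max_errors_mature: int = 7
    min_total_reads: int = 10
    stringent_max_mfe: float = -40.0  # kcal/mol
    min_mfei: float = 0.85
    min_precursor_len: int = 57
    max_precursor_len: int = 264

    def __post_init__(self) -> None:
        for f in fields(self):
            if not np.isfinite(getattr(self, f.name)):
                raise ValueError(f"criterion {f.name} must be finite")
        if self.max_free_energy >= 0 or self.stringent_max_mfe >= 0:
            raise ValueError("energy thresholds must be negative")
        if not (0 < self.min_pm_stem_fraction <= 1):
            raise ValueError("min_pm_stem_fraction must be in (0, 1]")


@dataclass(frozen=True)
class PrecursorWindow:
    """A strand-oriented genomic window around a tag alignment."""

    chrom: str
    start: int  # 0-based half-open, forward-strand coordinates
    end: int
    strand: str
    sequence: str  # 5'->3' on `strand`, RNA alphabet

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TagOnWindow:
    """A supporting tag placed on a window (offset in window 5'->3')."""

    sequence: str
    offset: int
    count: int  # summed over libraries


@dataclass
class MatureDuplex:
    five_p: TagOnWindow
    three_p: TagOnWindow
    overhang_5p_side: int
    overhang_3p_side: int


@dataclass
class PrecursorCandidate:
    """A folded window with its measured criteria and verdict."""

    window: PrecursorWindow
    structure: SecondaryStructure
    precursor_span: tuple[int, int]  # window-local, half-open
    precursor_seq: str
    mfe: float
    gc_fraction: float
    mfei: float
    stem_bp_count: int
    terminal_loop_len: int
    mature_span: tuple[int, int]  # window-local, half-open
    mature_arm: str  # '5p', '3p' or 'unknown'
    mature_errors: int
    mature_max_bulge: int
    mature_max_biased_bulge: int
    mature_biased_bulges: int
    mature_bp: int
    pm_stem_fraction: float
    total_reads: int
    passed: bool
    report: dict[str, tuple[float, str, float, bool]]
    tags: list[TagOnWindow] = field(default_factory=list)
    fail_reason: str | None = None
    duplex: MatureDuplex | None = None

    @property
    def genomic_span(self) -> tuple[int, int]:
        """Forward-strand genomic coordinates of the precursor (half-open)."""
        a, b = self.precursor_span
        if self.window.strand == "+":
            return (self.window.start + a, self.window.start + b)
        return (self.window.end - b, self.window.end - a)

    @property
    def mature_3p_span(self) -> tuple[int, int] | None:
        if self.duplex is None:
            return None
        t = self.duplex.three_p
        return (t.offset, t.offset + len(t.sequence))

    @property
    def mature_5p_span(self) -> tuple[int, int] | None:
        if self.duplex is None:
            return None
        t = self.duplex.five_p
        return (t.offset, t.offset + len(t.sequence))


def extract_candidate_windows(
    alignment: Alignment,
    contigs: dict[str, str],
    max_flank: int = 250,
) -> list[PrecursorWindow]:
    """Ladder of windows around an alignment: symmetric flanks of 20, 60,
    120 and 250 nt plus asymmetric variants placing the read near either
    window end.  Windows are clipped to contig bounds; only windows of at
    least 50 nt are returned."""
    contig = to_dna(contigs[alignment.chrom])
    n = len(contig)
    spans: list[tuple[int, int]] = []
    for f in WINDOW_FLANKS:
        if f > max_flank:
            continue
        for left, right in ((f, f), (ASYM_NEAR_FLANK, f), (f, ASYM_NEAR_FLANK)):
            start = max(0, alignment.start - left)
            end = min(n, alignment.end + right)
            if end - start >= 50:
                spans.append((start, end))
    out: list[PrecursorWindow] = []
    for start, end in sorted(set(spans)):
        seg = contig[start:end]
        if alignment.strand == "-":
            seg = revcomp_dna(seg)
        out.append(
            PrecursorWindow(
                alignment.chrom, start, end, alignment.strand, to_rna(seg)
            )
        )
    return out


def compute_mfei(mfe: float, length: int, gc: float) -> float:
    """MFEI = (|MFE| / length x 100) / (GC fraction x 100)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0 < gc <= 1):
        raise ValueError("gc fraction must be in (0, 1]")
    return (abs(mfe) / length * 100.0) / (gc * 100.0)


def _unpaired_runs(positions: list[int], table: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of unpaired positions (inclusive spans) within a sorted
    position list."""
    runs: list[tuple[int, int]] = []
    run_start = None
    prev = None
    for p in positions:
        unpaired = table[p] < 0
        if unpaired and (run_start is None or prev != p - 1):
            if run_start is not None:
                runs.append((run_start, prev))
            run_start = p
        elif not unpaired and run_start is not None:
            runs.append((run_start, prev))
            run_start = None
        if unpaired:
            prev = p
    if run_start is not None:
        runs.append((run_start, prev))
    return runs


def _is_biased(run: tuple[int, int], table: np.ndarray, lo: int, hi: int) -> bool:
    """A run is biased when the opposing region on the partner arm, between
    the partners of its flanking pairs, contains no unpaired position."""
    left = run[0] - 1
    while left >= lo and table[left] < 0:
        left -= 1
    right = run[1] + 1
    while right <= hi and table[right] < 0:
        right += 1
    if left < lo or right > hi or table[left] < 0 or table[right] < 0:
        return True  # run at an arm end: nothing to oppose it
    a, b = int(table[right]), int(table[left])
    if a > b:
        a, b = b, a
    return b - a <= 1  # no unpaired positions between the partner pairs


def evaluate_hairpin(
    window: PrecursorWindow,
    structure: SecondaryStructure,
    tags: list[TagOnWindow],
    criteria: HairpinCriteria = HairpinCriteria(),
) -> PrecursorCandidate:
    """Measure every hairpin criterion for a folded window and its
    supporting tags and return the candidate with a per-criterion report.

    The precursor is the outermost pair span of the structure subtree that
    contains the top-count tag; a subtree with more than one terminal loop
    fails with reason "not a single hairpin".
    """
    if not tags:
        raise ValueError("at least one supporting tag is required")
    table = structure.pair_table
    pairs = structure.pairs
    mature = max(tags, key=lambda t: (t.count, t.sequence))
    m_span = (mature.offset, mature.offset + len(mature.sequence))
    total_reads = sum(t.count for t in tags)

    def failed(reason: str) -> PrecursorCandidate:
        return PrecursorCandidate(
            window, structure, (0, 0), "", structure.mfe, 0.0, 0.0, 0, 0,
            m_span, "unknown", 0, 0, 0, 0, 0, 0.0, total_reads,
            False, {}, tags, fail_reason=reason,
        )

    if not pairs:
        return failed("no base pairs")
    # forest roots = pairs with no enclosing pair
    children = _direct_children(sorted(pairs))
    enclosed = {p for kids in children.values() for p in kids}
    roots = sorted(p for p in pairs if p not in enclosed)
    root = None
    for a, b in roots:
        if a <= m_span[0] and m_span[1] - 1 <= b:
            root = (a, b)
            break
    if root is None:
        return failed("mature tag not enclosed by a hairpin")

    def subtree(p):
        out = [p]
        for kid in children[p]:
            out.extend(subtree(kid))
        return out

    sub = subtree(root)
    terminal = [p for p in sub if not children[p]]
    if len(terminal) > 1:
        return failed("not a single hairpin")
    a, b = root
    (ti, tj) = terminal[0]
    precursor_seq = structure.sequence[a : b + 1]
    prec_len = b - a + 1
    mfe = score_structure(structure.sequence, sub)
    gc = gc_fraction(precursor_seq)
    mfei = compute_mfei(mfe, prec_len, gc) if gc > 0 else 0.0
    stem_bp = len(sub)
    loop_len = tj - ti - 1
    arm5 = list(range(a, ti + 1))
    arm3 = list(range(tj, b + 1))
    stem_runs = _unpaired_runs(arm5, table) + _unpaired_runs(arm3, table)
    max_stem_bulge = max((r[1] - r[0] + 1 for r in stem_runs), default=0)

    # mature-region measures (positions of the top-count tag)
    m_pos = list(range(m_span[0], m_span[1]))
    mature_errors = sum(1 for p in m_pos if table[p] < 0)
    mature_bp = len(m_pos) - mature_errors
    m_runs = _unpaired_runs(m_pos, table)
    max_m_bulge = max((r[1] - r[0] + 1 for r in m_runs), default=0)
    biased = [r for r in m_runs if _is_biased(r, table, a, b)]
    max_biased = max((r[1] - r[0] + 1 for r in biased), default=0)
    if m_span[1] - 1 <= ti:
        arm = "5p"
    elif m_span[0] >= tj:
        arm = "3p"
    else:
        arm = "unknown"

    # pm: fraction of supporting-tag nucleotides on the stem arms
    arm_set = set(arm5) | set(arm3)
    on_stem = 0
    tag_nt = 0
    for t in tags:
        span = range(t.offset, t.offset + len(t.sequence))
        if span.stop <= a or span.start > b:
            continue
        tag_nt += t.count * len(t.sequence)
        on_stem += t.count * sum(1 for p in span if p in arm_set)
    pm = on_stem / tag_nt if tag_nt else 0.0

    c = criteria
    report = {
        "stem_bp": (stem_bp, ">=", c.min_stem_bp, stem_bp >= c.min_stem_bp),
        "free_energy": (mfe, "<=", c.max_free_energy, mfe <= c.max_free_energy),
        "hairpin_len": (prec_len, ">=", c.min_hairpin_len, prec_len >= c.min_hairpin_len),
        "precursor_min_len": (prec_len, ">=", c.min_precursor_len, prec_len >= c.min_precursor_len),
        "precursor_max_len": (prec_len, "<=", c.max_precursor_len, prec_len <= c.max_precursor_len),
        "terminal_loop": (loop_len, "<=", c.max_terminal_loop, loop_len <= c.max_terminal_loop),
        "stem_bulge": (
            max_stem_bulge, "<=", c.max_errors_one_bulge_stem,
            max_stem_bulge <= c.max_errors_one_bulge_stem,
        ),
        "mature_errors": (
            mature_errors, "<=", c.max_errors_mature,
            mature_errors <= c.max_errors_mature,
        ),
        "mature_bulge": (
            max_m_bulge, "<=", c.max_errors_one_bulge_mature,
            max_m_bulge <= c.max_errors_one_bulge_mature,
        ),
        "mature_biased_bulge": (
            max_biased, "<=", c.max_biased_errors_one_bulge_mature,
            max_biased <= c.max_biased_errors_one_bulge_mature,
        ),
        "mature_biased_bulges_n": (
            len(biased), "<=", c.max_biased_bulges_mature,
            len(biased) <= c.max_biased_bulges_mature,
        ),
        "mature_bp": (mature_bp, ">=", c.min_mature_bp, mature_bp >= c.min_mature_bp),
        "pm": (pm, ">=", c.min_pm_stem_fraction, pm >= c.min_pm_stem_fraction),
        "total_reads": (
            total_reads, ">=", c.min_total_reads, total_reads >= c.min_total_reads,
        ),
        "stringent_mfe": (mfe, "<=", c.stringent_max_mfe, mfe <= c.stringent_max_mfe),
        "mfei": (mfei, ">=", c.min_mfei, mfei >= c.min_mfei),
    }
    passed = all(ok for _, _, _, ok in report.values())
    return PrecursorCandidate(
        window, structure, (a, b + 1), precursor_seq, mfe, gc, mfei,
        stem_bp, loop_len, m_span, arm, mature_errors, max_m_bulge,
        max_biased, len(biased), mature_bp, pm, total_reads, passed, report,
        tags,
    )


def detect_duplex(candidate: PrecursorCandidate) -> MatureDuplex | None:
    """Find the highest-count 5p/3p tag pair whose pairing projection leaves
    exactly 2 unpaired nucleotides at each 3' end; None if no pair
    qualifies (the candidate remains valid miRNA evidence either way)."""
    a, bp1 = candidate.precursor_span
    table = candidate.structure.pair_table
    ti, tj = None, None
    # terminal loop bounds from the evaluator's structure
    sub_pairs = [
        (i, j) for (i, j) in candidate.structure.pairs if a <= i and j < bp1
    ]
    inner = max(sub_pairs, key=lambda p: p[0], default=None)
    if inner is None:
        return None
    ti, tj = inner
    five, three = [], []
    for t in candidate.tags:
        lo, hi = t.offset, t.offset + len(t.sequence) - 1
        if lo >= a and hi <= ti:
            five.append(t)
        elif lo >= tj and hi <= bp1 - 1:
            three.append(t)
    best = None
    for t5 in five:
        for t3 in three:
            p5 = table[t5.offset]
            p3 = table[t3.offset]
            if p5 < 0 or p3 < 0:
                continue
            over3 = (t3.offset + len(t3.sequence) - 1) - int(p5)
            over5 = (t5.offset + len(t5.sequence) - 1) - int(p3)
            if over3 == 2 and over5 == 2:
                key = (t5.count + t3.count, t5.sequence, t3.sequence)
                if best is None or key > best[0]:
                    best = (key, MatureDuplex(t5, t3, over5, over3))
    if best is None:
        return None
    candidate.duplex = best[1]
    return best[1]


def dedup_candidates(accepted: list[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """Collapse overlapping accepted candidates into one representative.

    Candidates whose precursor spans overlap by at least half the shorter
    span (either strand: a near-palindromic hairpin maps its own tags to
    both strands and produces mirror duplicates) form one group; mere
    adjacency does not merge distinct neighbouring loci.  The
    representative is chosen by (duplex evidence, highest supporting-read
    total, lowest MFEI, lowest MFE) so that a two-arm precursor is never
    displaced by a one-arm sub-window."""
    ordered = sorted(
        accepted, key=lambda c: (c.window.chrom, c.genomic_span)
    )

    def _same_locus(a: PrecursorCandidate, b: PrecursorCandidate) -> bool:
        if a.window.chrom != b.window.chrom:
            return False
        (a0, a1), (b0, b1) = a.genomic_span, b.genomic_span
        overlap = min(a1, b1) - max(a0, b0)
        return overlap >= 0.5 * min(a1 - a0, b1 - b0)

    groups: list[list[PrecursorCandidate]] = []
    for cand in ordered:
        placed = False
        for group in groups:
            if any(_same_locus(cand, member) for member in group):
                group.append(cand)
                placed = True
                break
        if not placed:
            groups.append([cand])
    return [
        min(
            g,
            key=lambda c: (
                c.duplex is None,
                -c.total_reads,
                c.mfei,
                c.mfe,
                c.genomic_span,
                c.window.strand,
            ),
        )
        for g in groups
    ]
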