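"""Synthetic genomes and small-RNA libraries with known ground truth.

The generator emulates the four-library (leaf/root x control/NaCl) design:
a random genome carrying planted MIR hairpin loci (precursors 57-264 nt
whose 5p/3p duplex leaves 2-nt 3' overhangs) and structural-ncRNA loci,
plus per-library FASTQ reads of 18-25 nt inserts with 21- and 24-nt length
peaks, a 3' sequencing adaptor, unequal depths, ncRNA contamination and
negative-binomially dispersed counts (variance mu + phi mu^2).  Planted
fold changes between libraries drive the differential-expression truth.

Hairpins are built constructively - arm, A/C loop, near-reverse-complement
arm with optional asymmetric bulges in the lower stem - then validated by
folding under the package's energy model, so every planted locus passes the
hairpin criteria by construction.  Identical seeds give byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp_dna, revcomp_rna, to_dna, to_rna
from .classify import match_reference
from .folding import fold
from .hairpin import (
    HairpinCriteria,
    PrecursorCandidate,
    PrecursorWindow,
    TagOnWindow,
    detect_duplex,
    evaluate_hairpin,
)

DEFAULT_ADAPTOR_3P = "TGGAATTCTCGGGTGCCAAGG"  # common small-RNA kit 3' adaptor
READ_LENGTH = 36
DEFAULT_LENGTH_WEIGHTS = {
    18: 0.04, 19: 0.06, 20: 0.08, 21: 0.38, 22: 0.06, 23: 0.06, 24: 0.26, 25: 0.06,
}
NCRNA_CATEGORIES = ("rRNA", "tRNA", "snoRNA", "snRNA")


@dataclass
class MirLocusTruth:
    locus_id: str
    chrom: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str
    precursor_seq: str  # RNA, 5'->3' on `strand`
    mature_5p: str
    mature_3p: str
    mature_5p_offset: int  # within precursor
    mature_3p_offset: int
    arm_abundance_ratio: float  # 5p reads / 3p reads
    class_truth: str  # conserved / variant / novel
    planted_mismatches: int | None
    reference_match: str | None
    fold_changes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (57 <= len(self.precursor_seq) <= 264):
            raise ValueError("precursor length outside [57, 264]")
        if self.precursor_seq[self.mature_5p_offset :][: len(self.mature_5p)] != self.mature_5p:
            raise ValueError("mature_5p is not at its stated offset")
        if self.precursor_seq[self.mature_3p_offset :][: len(self.mature_3p)] != self.mature_3p:
            raise ValueError("mature_3p is not at its stated offset")


@dataclass
class NcRnaLocus:
    locus_id: str
    category: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str  # forward-strand DNA


@dataclass
class LibraryDesign:
    library_id: str
    depth: int
    adaptor_3p: str = DEFAULT_ADAPTOR_3P
    dispersion: float = 0.04  # NB: var = mu + phi mu^2
    ncrna_fraction: float = 0.2
    length_peak_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if len(self.adaptor_3p) < 6:
            raise ValueError("3' adaptor must be at least 6 nt")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0 <= self.ncrna_fraction <= 1):
            raise ValueError("ncrna_fraction must lie in [0, 1]")
        total = sum(self.length_peak_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("length peak weights must sum to 1")


@dataclass
class SyntheticGenome:
    contigs: dict[str, str]  # DNA, forward strand
    mir_loci: list[MirLocusTruth]
    ncrna_loci: list[NcRnaLocus]
    seed: int

    def ncrna_annotation(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for loc in self.ncrna_loci:
            out.setdefault(loc.category, []).append(to_rna(loc.sequence))
        return out

    def mir_bed(self) -> list[tuple[str, int, int, str, int, str]]:
        return [
            (m.chrom, m.start, m.end, m.locus_id, 0, m.strand)
            for m in self.mir_loci
        ]

    def ncrna_bed(self) -> list[tuple[str, int, int, str, int, str]]:
        return [
            (x.chrom, x.start, x.end, f"{x.category}|{x.locus_id}", 0, x.strand)
            for x in self.ncrna_loci
        ]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _build_hairpin(
    rng: np.random.Generator, mature_5p: str, with_bulge: bool
) -> tuple[str, int, int, str]:
    """Arm + loop + near-reverse-complement arm; returns (precursor RNA,
    5p offset, 3p offset, mature_3p).  The 5p/3p duplex carries 2-nt 3'
    overhangs by construction."""
    l5 = len(mature_5p)
    lower = int(rng.integers(8, 21))
    upper = int(rng.integers(2, 9))
    loop_len = int(rng.integers(8, 26))
    lower_seq = to_rna(_random_seq(rng, lower, 0.6))
    upper_seq = to_rna(_random_seq(rng, upper, 0.6))
    loop = "".join(rng.choice(np.array(list("AC")), size=loop_len))
    arm5 = lower_seq + mature_5p + upper_seq
    p0 = arm5 + loop + revcomp_rna(arm5)
    n0 = len(p0)
    off5 = lower
    off3 = n0 + 2 - off5 - l5  # duplex partner span with 2-nt 3' overhangs
    mature_3p = p0[off3 : off3 + l5]
    if with_bulge:
        bulge_len = int(rng.integers(1, 4))
        lo, hi = off3 + l5 + 2, n0 - 4
        if hi > lo:
            g = int(rng.integers(lo, hi))
            bulge = "".join(rng.choice(np.array(list("AC")), size=bulge_len))
            p0 = p0[:g] + bulge + p0[g:]
    return p0, off5, off3, mature_3p


def _validate_locus(
    precursor: str, off5: int, off3: int, m5: str, m3: str
) -> bool:
    """Fold the precursor and require the full hairpin criteria plus a
    2-nt-overhang duplex (read-support criteria fed with nominal counts)."""
    window = PrecursorWindow("synthetic", 0, len(precursor), "+", precursor)
    structure = fold(precursor)
    tags = [
        TagOnWindow(m5, off5, 10),
        TagOnWindow(m3, off3, 5),
    ]
    cand = evaluate_hairpin(window, structure, tags, HairpinCriteria())
    if not cand.passed:
        return False
    duplex = detect_duplex(cand)
    return duplex is not None and (duplex.overhang_5p_side, duplex.overhang_3p_side) == (2, 2)


def _draw_mature(
    rng: np.random.Generator,
    klass: str,
    reference_set: dict[str, str],
    used_refs: set[str],
) -> tuple[str, int | None, str | None]:
    """Mature 5p sequence with its planted mismatch count and reference."""
    eligible = sorted(
        r for r, s in reference_set.items() if 18 <= len(s) <= 25 and r not in used_refs
    ) or sorted(r for r, s in reference_set.items() if 18 <= len(s) <= 25)
    if klass in ("conserved", "variant") and not eligible:
        raise ValueError("reference set has no usable mature sequences")
    for _ in range(200):
        if klass == "conserved":
            ref = eligible[int(rng.integers(len(eligible)))]
            return to_rna(reference_set[ref]), 0, ref
        if klass == "variant":
            ref = eligible[int(rng.integers(len(eligible)))]
            seq = list(to_rna(reference_set[ref]))
            k = int(rng.integers(1, 3))
            pos = rng.choice(len(seq), size=k, replace=False)
            for p in pos:
                alts = [c for c in "ACGU" if c != seq[p]]
                seq[p] = alts[int(rng.integers(3))]
            mutated = "".join(seq)
            best = match_reference(mutated, reference_set, max_mismatches=2)
            if best is not None and best[1] == k:
                return mutated, k, best[0]
            continue
        # novel: random sequence with no reference counterpart
        seq = to_rna(_random_seq(rng, 21, 0.5))
        if reference_set and match_reference(seq, reference_set, max_mismatches=2) is not None:
            continue
        return seq, None, None
    raise RuntimeError(f"could not draw a {klass} mature sequence")


def generate_genome(
    length: int,
    gc_content: float,
    n_mir: int,
    n_ncrna: int,
    reference_set: dict[str, str] | None = None,
    seed: int = 0,
    chrom: str = "chr1",
    class_cycle: tuple[str, ...] = ("conserved", "variant", "novel"),
    bulge_probability: float = 0.3,
) -> SyntheticGenome:
    """Random genome with planted MIR and ncRNA loci plus truth records.

    Loci are placed on random strands at non-overlapping positions.  Each
    planted precursor is validated by folding: it passes the full hairpin
    criteria and yields a 5p/3p duplex with 2-nt 3' overhangs.
    """
    if not (0 < gc_content < 1):
        raise ValueError("gc_content must lie in (0, 1)")
    needs_ref = n_mir > 0 and any(c in ("conserved", "variant") for c in class_cycle)
    if needs_ref and not reference_set:
        raise ValueError("reference_set required for conserved/variant loci")
    rng = np.random.default_rng(seed)
    reference_set = reference_set or {}

    mir_parts: list[tuple[str, MirLocusTruth]] = []
    used_refs: set[str] = set()
    for i in range(n_mir):
        klass = class_cycle[i % len(class_cycle)]
        for _attempt in range(40):
            m5, mm, ref = _draw_mature(rng, klass, reference_set, used_refs)
            with_bulge = bool(rng.random() < bulge_probability)
            prec, off5, off3, m3 = _build_hairpin(rng, m5, with_bulge)
            if _validate_locus(prec, off5, off3, m5, m3):
                break
        else:  # pragma: no cover - generator failure
            raise RuntimeError(f"failed to build a valid hairpin for locus {i}")
        if ref is not None:
            used_refs.add(ref)
        strand = "+" if rng.random() < 0.5 else "-"
        truth = MirLocusTruth(
            locus_id=f"MIR{i + 1:03d}",
            chrom=chrom, start=-1, end=-1, strand=strand,
            precursor_seq=prec, mature_5p=m5, mature_3p=m3,
            mature_5p_offset=off5, mature_3p_offset=off3,
            arm_abundance_ratio=float(np.round(rng.uniform(2.0, 8.0), 3)),
            class_truth=klass, planted_mismatches=mm, reference_match=ref,
        )
        mir_parts.append((prec, truth))

    nc_parts: list[tuple[str, NcRnaLocus]] = []
    for i in range(n_ncrna):
        cat = NCRNA_CATEGORIES[i % len(NCRNA_CATEGORIES)]
        size = int(rng.integers(80, 201))
        seq = _random_seq(rng, size, gc_content)
        nc_parts.append(
            (seq, NcRnaLocus(f"{cat.lower()}{i + 1:03d}", cat, chrom, -1, -1, "+", seq))
        )

    total_locus = sum(len(p) for p, _ in mir_parts) + sum(len(s) for s, _ in nc_parts)
    if n_mir + n_ncrna and length < 10 * total_locus:
        raise ValueError(
            f"genome length {length} < 10x total planted locus length {total_locus}"
        )

    genome = list(_random_seq(rng, length, gc_content))
    occupied: list[tuple[int, int]] = []

    def place(size: int) -> int:
        for _ in range(1000):
            start = int(rng.integers(0, length - size))
            if all(start >= e + 20 or start + size <= s - 20 for s, e in occupied):
                occupied.append((start, start + size))
                return start
        raise RuntimeError("could not place locus; genome too crowded")

    for prec, truth in mir_parts:
        dna = to_dna(prec)
        start = place(len(dna))
        insert = dna if truth.strand == "+" else revcomp_dna(dna)
        genome[start : start + len(dna)] = list(insert)
        truth.start, truth.end = start, start + len(dna)
    for seq, loc in nc_parts:
        start = place(len(seq))
        genome[start : start + len(seq)] = list(seq)
        loc.start, loc.end = start, start + len(seq)

    return SyntheticGenome(
        {chrom: "".join(genome)},
        [t for _, t in mir_parts],
        [l for _, l in nc_parts],
        seed,
    )


def _nb_draw(rng: np.random.Generator, mu: float, phi: float) -> int:
    if mu <= 0:
        return 0
    if phi == 0:
        return int(math.floor(mu + 0.5))  # deterministic rounding
    r = 1.0 / phi
    p = r / (r + mu)
    return int(rng.negative_binomial(r, p))


def simulate_libraries(
    genome: SyntheticGenome,
    designs: list[LibraryDesign],
    contrasts: dict[str, dict[str, float]] | None = None,
    mirna_fraction: float = 0.35,
    locus_weights: dict[str, float] | None = None,
    read_length: int = READ_LENGTH,
    error_rate: float = 0.0,
    master_seed: int | None = None,
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Simulate FASTQ reads for each library plus an exact truth table.

    * expected miRNA-locus counts scale with depth x fold change (from
      ``contrasts``: locus id -> {library id -> fold change}, default 1);
    * counts are negative-binomial with the design's dispersion
      (var = mu + phi mu^2); dispersion 0 rounds the expectation;
    * a fraction ``ncrna_fraction`` of reads are windows of the planted
      ncRNA loci; the remainder of the depth is unmappable background with
      the design's 18-25 nt length peaks;
    * reads are mature (or window) + 3' adaptor, truncated to 36 nt.

    Returns ``{library: [(read id, sequence, quality), ...]}`` and a truth
    count table (rows: per-arm miRNA sources, ncRNA loci, background;
    columns: libraries) recording exact emissions.
    """
    if not designs:
        raise ValueError("at least one library design is required")
    contrasts = contrasts or {}
    loci = genome.mir_loci
    if locus_weights is None:
        locus_weights = default_locus_weights(
            genome, master_seed if master_seed is not None else designs[0].seed
        )
    fastq: dict[str, list[tuple[str, str, str]]] = {}
    truth_rows: dict[str, dict[str, int]] = {}

    for design in designs:
        rng = np.random.default_rng(design.seed)
        lib_counts = _draw_counts(
            rng, genome, design, contrasts, mirna_fraction, locus_weights
        )
        for source, c in lib_counts.items():
            truth_rows.setdefault(source, {})[design.library_id] = c
        reads: list[tuple[str, str]] = []  # (source, insert DNA)
        for t in loci:
            for arm, mat in (("5p", t.mature_5p), ("3p", t.mature_3p)):
                c = lib_counts[f"{t.locus_id}/{arm}"]
                reads.extend((f"{t.locus_id}/{arm}", to_dna(mat)) for _ in range(c))
        lengths = sorted(design.length_peak_weights)
        probs = np.array([design.length_peak_weights[n] for n in lengths])
        for loc in genome.ncrna_loci:
            for _ in range(lib_counts[f"ncrna/{loc.locus_id}"]):
                n = int(np.array(lengths)[rng.choice(len(lengths), p=probs)])
                n = min(n, len(loc.sequence))
                off = int(rng.integers(0, len(loc.sequence) - n + 1))
                reads.append((f"ncrna/{loc.locus_id}", loc.sequence[off : off + n]))
        n_background = lib_counts["background"]
        for _ in range(n_background):
            n = int(np.array(lengths)[rng.choice(len(lengths), p=probs)])
            reads.append(("background", _random_seq(rng, n, 0.5)))
        # assemble reads: insert + adaptor, truncated; optional substitutions
        order = rng.permutation(len(reads))
        lib_reads: list[tuple[str, str, str]] = []
        for out_idx, idx in enumerate(order):
            source, insert = reads[int(idx)]
            seq = (insert + to_dna(design.adaptor_3p))[:read_length]
            if error_rate > 0:
                seq = _substitute(rng, seq, error_rate)
            lib_reads.append(
                (
                    f"{design.library_id}:{out_idx + 1}:{source}",
                    seq,
                    "I" * len(seq),
                )
            )
        fastq[design.library_id] = lib_reads

    truth = (
        pd.DataFrame.from_dict(truth_rows, orient="index")
        .reindex(columns=[d.library_id for d in designs])
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    truth.index.name = "source"
    return fastq, truth


def default_locus_weights(
    genome: SyntheticGenome, master_seed: int
) -> dict[str, float]:
    """Per-locus relative abundances: normalised lognormal(0, 0.8) draws,
    fixed by the master seed (shared across libraries)."""
    master = np.random.default_rng(master_seed)
    raw = master.lognormal(mean=0.0, sigma=0.8, size=len(genome.mir_loci))
    total = raw.sum()
    return {
        t.locus_id: float(w / total) if total else 0.0
        for t, w in zip(genome.mir_loci, raw)
    }


def _draw_counts(
    rng: np.random.Generator,
    genome: SyntheticGenome,
    design: LibraryDesign,
    contrasts: dict[str, dict[str, float]],
    mirna_fraction: float,
    locus_weights: dict[str, float],
) -> dict[str, int]:
    """One library's per-source counts (the NB draws behind the reads)."""
    counts: dict[str, int] = {}
    total = 0
    for t in genome.mir_loci:
        fc = contrasts.get(t.locus_id, {}).get(design.library_id, 1.0)
        if fc <= 0:
            raise ValueError("fold changes must be positive")
        mu = mirna_fraction * design.depth * locus_weights[t.locus_id] * fc
        r = t.arm_abundance_ratio
        for arm, mu_arm in (("5p", mu * r / (1 + r)), ("3p", mu / (1 + r))):
            c = _nb_draw(rng, mu_arm, design.dispersion)
            counts[f"{t.locus_id}/{arm}"] = c
            total += c
    nc = genome.ncrna_loci
    for loc in nc:
        mu = design.ncrna_fraction * design.depth / max(1, len(nc))
        c = _nb_draw(rng, mu, design.dispersion)
        counts[f"ncrna/{loc.locus_id}"] = c
        total += c
    counts["background"] = max(0, design.depth - total)
    return counts


def simulate_counts(
    genome: SyntheticGenome,
    designs: list[LibraryDesign],
    contrasts: dict[str, dict[str, float]] | None = None,
    mirna_fraction: float = 0.35,
    locus_weights: dict[str, float] | None = None,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Per-source count table only (no reads); identical draws to
    :func:`simulate_libraries` under the same seeds."""
    if not designs:
        raise ValueError("at least one library design is required")
    contrasts = contrasts or {}
    if locus_weights is None:
        locus_weights = default_locus_weights(
            genome, master_seed if master_seed is not None else designs[0].seed
        )
    rows: dict[str, dict[str, int]] = {}
    for design in designs:
        rng = np.random.default_rng(design.seed)
        for source, c in _draw_counts(
            rng, genome, design, contrasts, mirna_fraction, locus_weights
        ).items():
            rows.setdefault(source, {})[design.library_id] = c
    truth = (
        pd.DataFrame.from_dict(rows, orient="index")
        .reindex(columns=[d.library_id for d in designs])
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    truth.index.name = "source"
    return truth


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(4))]
    return "".join(out)


def generate_transcripts(
    genome: SyntheticGenome,
    seed: int = 0,
    n_decoys: int = 5,
    length: int = 600,
) -> tuple[dict[str, str], dict[str, tuple[str, str]]]:
    """Transcripts carrying planted target sites for the planted matures.

    Even-indexed loci get a perfectly complementary site (cleavage truth);
    odd-indexed loci get a single central mismatch at miRNA position 10
    (translational-inhibition truth).  Returns (transcripts, truth) where
    truth maps transcript id -> (locus id, expected mode).
    """
    rng = np.random.default_rng(seed)
    transcripts: dict[str, str] = {}
    truth: dict[str, tuple[str, str]] = {}
    for i, t in enumerate(genome.mir_loci):
        mature = to_dna(t.mature_5p)
        site = revcomp_dna(mature)
        mode = "cleavage"
        if i % 2 == 1:
            # mismatch facing miRNA position 10 (1-based from the 5' end):
            # site position len - 10 in 5'->3' orientation
            pos = len(site) - 10
            cur = site[pos]
            # avoid creating a G:U wobble with the miRNA base
            mir_base = to_rna(mature)[9]
            choices = [
                c for c in "ACGT"
                if c != cur and (to_rna(c), mir_base) not in {("G", "U"), ("U", "G")}
                and (mir_base, to_rna(c)) not in {("G", "U"), ("U", "G")}
            ]
            site = site[:pos] + choices[int(rng.integers(len(choices)))] + site[pos:][1:]
            mode = "translation"
        body = _random_seq(rng, length, 0.45)
        pos = int(rng.integers(50, length - len(site) - 50))
        tx = body[:pos] + site + body[pos + len(site) :]
        tx_id = f"TX_{t.locus_id}"
        transcripts[tx_id] = tx
        truth[tx_id] = (t.locus_id, mode)
    for d in range(n_decoys):
        transcripts[f"TX_decoy{d + 1}"] = _random_seq(rng, length, 0.45)
    return transcripts, truth
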