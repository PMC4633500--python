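"""Ungapped tag-to-genome mapping under a seed-mismatch rule.

Tags (18-25 nt) are aligned to both genome strands without gaps.  At most
one mismatch is tolerated, and only within the first 16 nt of the tag (its
seed); positions 16 and beyond must match exactly.  All qualifying
alignments are reported; a tag with none is "unmapped" and leaves the
analysis.

The index is a plain dictionary over all 16-mers of both strands.  Candidate
placements for a tag are generated by looking up the tag seed and its 48
single-substitution neighbours, then verified against the genome, which is
exhaustive under the one-seed-mismatch rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from ._seq import check_alphabet, revcomp_dna, to_dna

SEED_LENGTH = 16
_ALPHABET = "ACGT"


@dataclass(frozen=True)
class Alignment:
    """One ungapped placement of a tag on the genome."""

    tag: str  # tag sequence, DNA alphabet, as collapsed
    chrom: str
    start: int  # 0-based, on the forward strand
    strand: str  # '+' or '-'
    mismatch_positions: tuple[int, ...]  # 0-based offsets within the tag

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.mismatch_positions) > 1:
            raise ValueError("at most one mismatch is allowed")
        if any(p >= SEED_LENGTH for p in self.mismatch_positions):
            raise ValueError("mismatches outside the 16-nt seed are not allowed")

    @property
    def end(self) -> int:
        return self.start + len(self.tag)


class GenomeIndex:
    """Exact-lookup 16-mer index over both strands of a genome."""

    def __init__(self, contigs: dict[str, str], seed_length: int = SEED_LENGTH):
        if not contigs:
            raise ValueError("empty genome")
        self.seed_length = seed_length
        self.contigs = {name: to_dna(seq) for name, seq in contigs.items()}
        # seed -> list of (chrom, start on forward strand, strand)
        self._seeds: dict[str, list[tuple[str, int, str]]] = {}
        self.n_forward_seeds = 0
        for name, seq in self.contigs.items():
            if len(seq) < seed_length:
                warnings.warn(
                    f"contig {name!r} shorter than seed length {seed_length}; skipped"
                )
                continue
            rc = revcomp_dna(seq)
            for off in range(len(seq) - seed_length + 1):
                self._seeds.setdefault(seq[off : off + seed_length], []).append(
                    (name, off, "+")
                )
                self.n_forward_seeds += 1
                # '-' strand seed at rc offset `off` starts, on the forward
                # strand, at len(seq) - off - seed_length
                self._seeds.setdefault(rc[off : off + seed_length], []).append(
                    (name, off, "-")
                )

    def seed_hits(self, seed: str) -> list[tuple[str, int, str]]:
        return self._seeds.get(seed, [])


def build_index(contigs: dict[str, str], seed_length: int = SEED_LENGTH) -> GenomeIndex:
    """Build a :class:`GenomeIndex` from ``{contig name: sequence}``."""
    return GenomeIndex(contigs, seed_length)


def _verify(tag: str, ref: str, offset: int) -> tuple[int, ...] | None:
    """Mismatch offsets if the placement qualifies, else None."""
    if offset < 0 or offset + len(tag) > len(ref):
        return None
    mismatches = [i for i in range(len(tag)) if tag[i] != ref[offset + i]]
    if len(mismatches) > 1 or any(p >= SEED_LENGTH for p in mismatches):
        return None
    return tuple(mismatches)


def _seed_variants(seed: str) -> list[str]:
    out = [seed]
    for i, c in enumerate(seed):
        for alt in _ALPHABET:
            if alt != c:
                out.append(seed[:i] + alt + seed[i + 1 :])
    return out


def map_tag(tag: str, index: GenomeIndex) -> list[Alignment]:
    """All qualifying alignments of ``tag`` on both strands.

    The tag may be given in RNA or DNA alphabet; reported mismatch offsets
    are within the tag read 5'->3'.
    """
    dna = to_dna(tag)
    check_alphabet(dna, "ACGT")
    if not (18 <= len(dna) <= 25):
        raise ValueError(f"tag length {len(dna)} outside [18, 25]")
    hits: set[tuple[str, int, str]] = set()
    out: list[Alignment] = []
    for strand in "+-":
        query = dna if strand == "+" else revcomp_dna(dna)
        if strand == "+":
            # seed = first 16 nt of the tag
            candidates = {
                (chrom, start, "+")
                for v in _seed_variants(query[:SEED_LENGTH])
                for (chrom, start, s) in index.seed_hits(v)
                if s == "+"
            }
        else:
            # on '-', the tag seed is the *last* 16 nt of the forward-strand
            # query; use the reverse-strand index entries directly
            candidates = set()
            for v in _seed_variants(dna[:SEED_LENGTH]):
                for chrom, off, s in index.seed_hits(v):
                    if s == "-":
                        # '-' seed at rc offset `off` covers tag offsets
                        # [0, 16); forward-strand start of the full tag:
                        start = len(index.contigs[chrom]) - off - len(dna)
                        candidates.add((chrom, start, "-"))
        for chrom, start, _ in candidates:
            key = (chrom, start, strand)
            if key in hits:
                continue
            ref = index.contigs[chrom]
            if strand == "+":
                mm = _verify(query, ref, start)
            else:
                if start < 0 or start + len(dna) > len(ref):
                    continue
                window = revcomp_dna(ref[start : start + len(dna)])
                mismatches = tuple(
                    i for i in range(len(dna)) if dna[i] != window[i]
                )
                mm = (
                    mismatches
                    if len(mismatches) <= 1
                    and all(p < SEED_LENGTH for p in mismatches)
                    else None
                )
            if mm is not None:
                hits.add(key)
                out.append(Alignment(dna, chrom, start, strand, mm))
    out.sort(key=lambda a: (a.chrom, a.start, a.strand))
    return out


def map_tags(
    tags: list[str], index: GenomeIndex
) -> dict[str, list[Alignment]]:
    """Map many tags; returns ``{tag: alignments}`` (empty list = unmapped)."""
    return {t: map_tag(t, index) for t in tags}


def brute_force_map(tag: str, contigs: dict[str, str]) -> list[Alignment]:
    """Positionwise reference scanner used as the mapping oracle."""
    dna = to_dna(tag)
    out = []
    for chrom, seq in contigs.items():
        ref = to_dna(seq)
        for start in range(len(ref) - len(dna) + 1):
            for strand in "+-":
                q = dna if strand == "+" else None
                window = ref[start : start + len(dna)]
                if strand == "-":
                    window = revcomp_dna(window)
                mismatches = tuple(
                    i for i in range(len(dna)) if dna[i] != window[i]
                )
                if len(mismatches) <= 1 and all(
                    p < SEED_LENGTH for p in mismatches
                ):
                    out.append(Alignment(dna, chrom, start, strand, mismatches))
    out.sort(key=lambda a: (a.chrom, a.start, a.strand))
    return out
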