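"""End-to-end orchestration: config, stage drivers, and the run summary.

``run_pipeline`` executes filter -> map -> fold -> classify -> DE -> targets
from a flat YAML config and writes deterministic TSV/BED/GFF outputs plus a
manifest; ``summarize_run`` assembles the per-library read-accounting table
(total reads, reads after filtration, mapped, annotated ncRNA categories,
known/predicted miRNA, no hit; redundant and unique) whose total column is
always the sum of the per-library cells.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import expression as _expression
from . import io as _io
from . import mapping as _mapping
from . import preprocess as _preprocess
from . import synthetic as _synthetic
from . import targets as _targets
from ._seq import to_rna
from .folding import fold
from .hairpin import (
    HairpinCriteria,
    TagOnWindow,
    dedup_candidates,
    detect_duplex,
    evaluate_hairpin,
    extract_candidate_windows,
)

DEFAULT_DEPTHS = {
    "leaf_control": 8_000, "leaf_nacl": 6_600,
    "root_control": 6_200, "root_nacl": 8_000,
}

SUMMARY_ROWS = (
    "total_reads",
    "reads_after_filtration",
    "mapped",
    "known_small_rna",
    "known_mirna",
    "predicted_mirna",
    "rRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
    "no_hit",
)


@dataclass
class PipelineConfig:
    genome: Path
    reads: dict[str, Path]
    ncrna_fasta: Path
    reference_fasta: Path
    outdir: Path
    transcripts_fasta: Path | None = None
    adaptor_3p: str = _synthetic.DEFAULT_ADAPTOR_3P
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    min_mean_quality: float = 20.0
    bcv: float = 0.2
    alpha: float = 0.05
    fdr_alpha: float = 0.05
    variant_max_mismatches: int = 2
    max_expectation: float = 3.0
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        def p(key):
            return (base / raw[key]).resolve() if not Path(raw[key]).is_absolute() else Path(raw[key])
        cfg = cls(
            genome=p("genome"),
            reads={k: (base / v) for k, v in raw["reads"].items()},
            ncrna_fasta=p("ncrna_fasta"),
            reference_fasta=p("reference_fasta"),
            outdir=base / raw.get("outdir", "out"),
            transcripts_fasta=(base / raw["transcripts_fasta"]) if raw.get("transcripts_fasta") else None,
            adaptor_3p=raw.get("adaptor_3p", _synthetic.DEFAULT_ADAPTOR_3P),
            min_overlap=int(raw.get("min_overlap", 6)),
            max_mismatch_rate=float(raw.get("max_mismatch_rate", 0.1)),
            min_mean_quality=float(raw.get("min_mean_quality", 20.0)),
            bcv=float(raw.get("bcv", 0.2)),
            alpha=float(raw.get("alpha", 0.05)),
            fdr_alpha=float(raw.get("fdr_alpha", 0.05)),
            variant_max_mismatches=int(raw.get("variant_max_mismatches", 2)),
            max_expectation=float(raw.get("max_expectation", 3.0)),
            contrasts=[tuple(c) for c in raw.get("contrasts", [])],
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = [
            str(f)
            for f in [self.genome, self.ncrna_fasta, self.reference_fasta,
                      *(self.reads.values()),
                      *( [self.transcripts_fasta] if self.transcripts_fasta else [] )]
            if not Path(f).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if len(set(self.reads)) != len(self.reads) or not self.reads:
            raise ValueError("library ids must be unique and non-empty")


def summarize_run(cells: dict[str, dict[str, dict[str, int]]]) -> pd.DataFrame:
    """Assemble the run-summary table from per-library tallies.

    ``cells[row][kind][library]`` with kind in {redundant, unique}.  The
    output has a (kind, library) column MultiIndex plus a (kind, 'total')
    column that is the row sum of the per-library cells.
    """
    libraries: list[str] = []
    for row in cells.values():
        for kind in row.values():
            for lib in kind:
                if lib not in libraries:
                    libraries.append(lib)
    data = {}
    for kind in ("redundant", "unique"):
        for lib in libraries:
            data[(kind, lib)] = [
                cells.get(row, {}).get(kind, {}).get(lib, 0) for row in SUMMARY_ROWS
            ]
        data[(kind, "total")] = [
            sum(cells.get(row, {}).get(kind, {}).get(lib, 0) for lib in libraries)
            for row in SUMMARY_ROWS
        ]
    frame = pd.DataFrame(data, index=pd.Index(SUMMARY_ROWS, name="row"))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["kind", "library"])
    return frame


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    tags: list[_preprocess.UniqueTag]
    candidates: list
    annotations: list[_classify.MiRNAAnnotation]
    counts: pd.DataFrame
    de: pd.DataFrame
    target_hits: list[_targets.TargetHit]
    outdir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    libraries = sorted(config.reads)
    genome = _io.read_fasta(config.genome)
    reference = {k: to_rna(v) for k, v in _io.read_fasta(config.reference_fasta).items()}
    ncrna: dict[str, list[str]] = {}
    for name, seq in _io.read_fasta(config.ncrna_fasta).items():
        cat = name.split("|")[0]
        ncrna.setdefault(cat, []).append(to_rna(seq))

    # --- preprocess -------------------------------------------------------
    cells: dict[str, dict[str, dict[str, int]]] = {
        row: {"redundant": {}, "unique": {}} for row in SUMMARY_ROWS
    }
    inserts_per_library: dict[str, list[str]] = {}
    for lib in libraries:
        raw_seqs = []
        trimmed: list[tuple[str, float]] = []
        for _rid, seq, quals in _io.read_fastq(config.reads[lib]):
            raw_seqs.append(seq)
            insert = _preprocess.trim_adaptor(
                seq, config.adaptor_3p, config.min_overlap, config.max_mismatch_rate
            )
            if insert is not None and insert:
                mean_q = sum(quals[: len(insert)]) / len(insert)
                trimmed.append((insert, mean_q))
        kept, _stats = _preprocess.filter_reads(
            trimmed, min_mean_quality=config.min_mean_quality
        )
        inserts_per_library[lib] = kept
        cells["total_reads"]["redundant"][lib] = len(raw_seqs)
        cells["total_reads"]["unique"][lib] = len(set(raw_seqs))
        cells["reads_after_filtration"]["redundant"][lib] = len(kept)
        cells["reads_after_filtration"]["unique"][lib] = len(set(kept))

    tags = _preprocess.collapse(inserts_per_library)
    passed, removed, _tally = _preprocess.filter_annotated(tags, ncrna)
    for cat in _preprocess.NCRNA_PRIORITY:
        for lib in libraries:
            cat_tags = [t for t in removed if t.category == cat]
            cells[cat]["redundant"][lib] = sum(t.counts.get(lib, 0) for t in cat_tags)
            cells[cat]["unique"][lib] = sum(
                1 for t in cat_tags if t.counts.get(lib, 0) > 0
            )

    # --- mapping ----------------------------------------------------------
    index = _mapping.build_index(genome)
    alignments: dict[str, list[_mapping.Alignment]] = {}
    for t in passed:
        alns = _mapping.map_tag(t.sequence, index)
        if alns:
            alignments[t.sequence] = alns
            t.category = "mapped"
        else:
            t.category = "unmapped"
    mapped_tags = [t for t in passed if t.category == "mapped"]
    unmapped_tags = [t for t in passed if t.category == "unmapped"]
    for lib in libraries:
        cells["mapped"]["redundant"][lib] = sum(
            t.counts.get(lib, 0) for t in mapped_tags
        )
        cells["mapped"]["unique"][lib] = sum(
            1 for t in mapped_tags if t.counts.get(lib, 0) > 0
        )
        cells["no_hit"]["redundant"][lib] = sum(
            t.counts.get(lib, 0) for t in unmapped_tags
        )
        cells["no_hit"]["unique"][lib] = sum(
            1 for t in unmapped_tags if t.counts.get(lib, 0) > 0
        )

    # --- hairpin discovery ------------------------------------------------
    tag_by_seq = {t.sequence: t for t in tags}
    placements: list[tuple[str, _mapping.Alignment]] = [
        (seq, a) for seq, alns in sorted(alignments.items()) for a in alns
    ]
    fold_cache: dict[str, object] = {}
    accepted = []
    criteria = HairpinCriteria()
    seen_windows: set[tuple] = set()
    for seq, aln in placements:
        for window in extract_candidate_windows(aln, genome):
            wkey = (window.chrom, window.start, window.end, window.strand)
            if wkey in seen_windows:
                continue
            seen_windows.add(wkey)
            support = []
            for seq2, alns2 in sorted(alignments.items()):
                for a2 in alns2:
                    if a2.chrom != window.chrom or a2.strand != window.strand:
                        continue
                    if a2.start >= window.start and a2.end <= window.end:
                        if window.strand == "+":
                            off = a2.start - window.start
                        else:
                            off = window.end - a2.end
                        support.append(
                            TagOnWindow(to_rna(seq2), off, tag_by_seq[seq2].total)
                        )
            # dedupe identical placements
            support = sorted(
                {(s.sequence, s.offset): s for s in support}.values(),
                key=lambda s: (s.offset, s.sequence),
            )
            if not support:
                continue
            structure = fold_cache.get(window.sequence)
            if structure is None:
                structure = fold(window.sequence)
                fold_cache[window.sequence] = structure
            cand = evaluate_hairpin(window, structure, support, criteria)
            if cand.passed:
                detect_duplex(cand)
                accepted.append(cand)
    candidates = dedup_candidates(accepted)

    # --- classification ---------------------------------------------------
    annotations: list[_classify.MiRNAAnnotation] = []
    counts_rows: dict[str, dict[str, int]] = {}
    serial = 0
    known_tags: set[str] = set()
    novel_tags: set[str] = set()
    seen_matures: set[str] = set()
    for cand in candidates:
        mature_tags = [max(cand.tags, key=lambda t: (t.count, t.sequence))]
        if cand.duplex is not None:
            for t in (cand.duplex.five_p, cand.duplex.three_p):
                if t not in mature_tags:
                    mature_tags.append(t)
        anns_here = []
        for t in mature_tags:
            if t.sequence in seen_matures:
                continue
            a_loop, b_loop = cand.precursor_span
            if cand.duplex is not None and t is cand.duplex.five_p:
                arm = "5p"
            elif cand.duplex is not None and t is cand.duplex.three_p:
                arm = "3p"
            else:
                arm = cand.mature_arm
            utag = tag_by_seq[t.sequence]
            match = _classify.match_reference(
                t.sequence, reference, max_mismatches=config.variant_max_mismatches
            ) if reference else None
            serial += 1
            ann = _classify.classify_mirna(
                t.sequence, utag.total, match, arm=arm, serial=serial,
                variant_max_mismatches=config.variant_max_mismatches,
            )
            if ann is None:
                continue
            if ann.mirna_id in counts_rows:  # same reference hit twice
                ann.mirna_id = f"{ann.mirna_id}-{serial}"
            seen_matures.add(t.sequence)
            ann.precursor_id = f"{cand.window.chrom}:{cand.genomic_span[0]}-{cand.genomic_span[1]}({cand.window.strand})"
            annotations.append(ann)
            anns_here.append(ann)
            counts_rows[ann.mirna_id] = {
                lib: utag.counts.get(lib, 0) for lib in libraries
            }
            (known_tags if ann.klass in ("conserved", "variant") else novel_tags).add(
                t.sequence
            )
        if len(anns_here) == 2:
            anns_here[0].duplex_partner = anns_here[1].mirna_id
            anns_here[1].duplex_partner = anns_here[0].mirna_id

    for lib in libraries:
        for row, seqs in (("known_mirna", known_tags), ("predicted_mirna", novel_tags)):
            cells[row]["redundant"][lib] = sum(
                tag_by_seq[s].counts.get(lib, 0) for s in seqs
            )
            cells[row]["unique"][lib] = sum(
                1 for s in seqs if tag_by_seq[s].counts.get(lib, 0) > 0
            )
        # "known small RNAs": annotated ncRNA categories + known miRNA
        for kind in ("redundant", "unique"):
            cells["known_small_rna"][kind][lib] = (
                sum(cells[cat][kind].get(lib, 0) for cat in _preprocess.NCRNA_PRIORITY)
                + cells["known_mirna"][kind].get(lib, 0)
            )

    summary = summarize_run(cells)

    # --- expression -------------------------------------------------------
    counts = pd.DataFrame.from_dict(counts_rows, orient="index").fillna(0).astype(int)
    counts = counts.reindex(columns=libraries).sort_index()
    counts.index.name = "mirna_id"
    contrasts = list(config.contrasts) or _default_contrasts(libraries)
    try:
        de = _expression.de_table(
            counts, contrasts, bcv=config.bcv,
            alpha=config.alpha, fdr_alpha=config.fdr_alpha,
        )
    except ValueError:
        de = pd.DataFrame()

    # --- targets ----------------------------------------------------------
    target_hits: list[_targets.TargetHit] = []
    if config.transcripts_fasta is not None:
        params = _targets.TargetParams(max_expectation=config.max_expectation)
        transcripts = _io.read_fasta(config.transcripts_fasta)
        for ann in annotations:
            for tx_id in sorted(transcripts):
                target_hits.extend(
                    _targets.scan_transcript(
                        ann.mirna_id, ann.mature_seq, tx_id, transcripts[tx_id], params
                    )
                )

    _write_outputs(
        outdir, config, summary, tags, candidates, annotations, counts, de, target_hits
    )
    return PipelineResult(
        summary, tags, candidates, annotations, counts, de, target_hits, outdir
    )


def _default_contrasts(libraries: list[str]) -> list[tuple[str, str]]:
    pairs = []
    for control, treated in (
        ("leaf_control", "leaf_nacl"),
        ("root_control", "root_nacl"),
    ):
        if control in libraries and treated in libraries:
            pairs.append((control, treated))
    if not pairs and len(libraries) >= 2:
        pairs.append((libraries[0], libraries[1]))
    return pairs


def _write_outputs(
    outdir, config, summary, tags, candidates, annotations, counts, de, hits
) -> None:
    flat = summary.copy()
    flat.columns = [f"{kind}_{lib}" for kind, lib in summary.columns]
    flat.to_csv(outdir / "summary.tsv", sep="\t")
    pd.DataFrame(
        [
            {"sequence": t.sequence, "category": t.category, **t.counts}
            for t in tags
        ]
    ).to_csv(outdir / "tags.tsv", sep="\t", index=False)
    rows = []
    gff = []
    for i, c in enumerate(candidates, 1):
        g0, g1 = c.genomic_span
        rows.append(
            {
                "candidate_id": f"cand{i:03d}",
                "chrom": c.window.chrom, "start": g0, "end": g1,
                "strand": c.window.strand, "length": len(c.precursor_seq),
                "mfe": c.mfe, "gc": round(c.gc_fraction, 4),
                "mfei": round(c.mfei, 4), "stem_bp": c.stem_bp_count,
                "terminal_loop": c.terminal_loop_len,
                "total_reads": c.total_reads, "passed": c.passed,
                "has_duplex": c.duplex is not None,
                "precursor": c.precursor_seq,
                "dot_bracket": c.structure.dot_bracket[
                    c.precursor_span[0] : c.precursor_span[1]
                ],
            }
        )
        gff.append(
            (
                c.window.chrom, "palmirna", "miRNA_primary_transcript",
                g0 + 1, g1, ".", c.window.strand, f"ID=cand{i:03d}",
            )
        )
    pd.DataFrame(rows).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    _io.write_gff3(outdir / "candidates.gff3", gff)
    pd.DataFrame(
        [
            {
                "mirna_id": a.mirna_id, "sequence": a.mature_seq, "arm": a.arm,
                "class": a.klass, "reference": a.reference_match or "",
                "mismatches": "" if a.mismatches is None else a.mismatches,
                "family": a.family or "", "duplex_partner": a.duplex_partner or "",
                "precursor": a.precursor_id or "",
            }
            for a in annotations
        ]
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    de.to_csv(outdir / "de.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "mirna_id": h.mirna_id, "transcript_id": h.transcript_id,
                "start": h.start, "end": h.end,
                "expectation": h.expectation, "mode": h.mode,
            }
            for h in hits
        ]
    ).to_csv(outdir / "targets.tsv", sep="\t", index=False)
    manifest = {
        "seed": config.seed, "adaptor_3p": config.adaptor_3p,
        "bcv": config.bcv, "alpha": config.alpha, "fdr_alpha": config.fdr_alpha,
        "variant_max_mismatches": config.variant_max_mismatches,
        "max_expectation": config.max_expectation,
        "libraries": ",".join(sorted(config.reads)),
    }
    with open(outdir / "manifest.tsv", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}\t{v}\n")


def de_recovery_mc(
    genome: "_synthetic.SyntheticGenome",
    contrasts_fc: dict[str, dict[str, float]],
    depths: dict[str, int],
    master_seed: int,
    n_seeds: int = 200,
    seed_base: int = 100_000,
    bcv: float = 0.2,
    min_mean: float = 100.0,
) -> dict[str, float]:
    """Monte-Carlo DE recovery under the fixture design.

    For ``n_seeds`` fresh library simulations (counts only) the exact test
    plus BH is run on the planted miRNA arm rows; returns the call rate of
    planted >= 4-fold 5p arms whose expected control-side count is at least
    ``min_mean``, and the false-call rate of fold-change-1 rows.
    """
    pairs = [
        (c, t)
        for c, t in (("leaf_control", "leaf_nacl"), ("root_control", "root_nacl"))
        if c in depths and t in depths
    ]
    # expected control-side 5p counts (locus weights are fixed by master_seed)
    weights = _synthetic.default_locus_weights(genome, master_seed)
    hits = checks = null_calls = null_total = 0
    for s in range(n_seeds):
        designs = [
            _synthetic.LibraryDesign(lib, depth, seed=seed_base + s * 10 + i,
                                     dispersion=bcv**2)
            for i, (lib, depth) in enumerate(sorted(depths.items()))
        ]
        counts = _synthetic.simulate_counts(
            genome, designs, contrasts_fc, master_seed=master_seed
        )
        mir = counts.loc[[i for i in counts.index if "/" in i and not i.startswith("ncrna")]]
        de = _expression.de_table(mir, pairs, bcv=bcv).set_index(
            ["mirna_id", "contrast"]
        )
        for t in genome.mir_loci:
            for control, treated in pairs:
                fc = contrasts_fc.get(t.locus_id, {}).get(treated, 1.0)
                contrast = f"{treated}_vs_{control}"
                mu_control = (
                    0.35 * depths[control] * weights[t.locus_id]
                    * t.arm_abundance_ratio / (1 + t.arm_abundance_ratio)
                )
                for arm in ("5p", "3p"):
                    key = (f"{t.locus_id}/{arm}", contrast)
                    if key not in de.index:
                        continue
                    sig = bool(de.loc[key, "significant"])
                    if fc >= 4.0 and arm == "5p" and mu_control >= min_mean:
                        checks += 1
                        hits += int(sig)
                    elif fc == 1.0:
                        null_total += 1
                        null_calls += int(sig)
    return {
        "power": hits / checks if checks else float("nan"),
        "null_rate": null_calls / null_total if null_total else float("nan"),
        "n_power_checks": checks,
        "n_null_checks": null_total,
    }


def checksum_outputs(outdir: str | Path) -> dict[str, str]:
    """SHA-256 of every regular file in a run directory (re-run equality)."""
    out = {}
    for p in sorted(Path(outdir).glob("*")):
        if p.is_file():
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def make_fixtures(
    outdir: str | Path,
    seed: int = 7,
    genome_length: int = 50_000,
    gc_content: float = 0.45,
    n_mir: int = 10,
    n_ncrna: int = 5,
    depths: dict[str, int] | None = None,
    planted_fold_changes: dict[str, dict[str, float]] | None = None,
) -> tuple[Path, _synthetic.SyntheticGenome, pd.DataFrame]:
    """Write a complete synthetic input bundle plus its config.yaml.

    Default design: four libraries of unequal depth, 20% ncRNA
    contamination, ten planted MIR loci cycling conserved/variant/novel,
    fold changes of 4 (up) and 1/4 (down) planted on the first two loci in
    the NaCl libraries.
    """
    from .published import REFERENCE_MATURE_MIRNAS

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    depths = depths or dict(DEFAULT_DEPTHS)
    genome = _synthetic.generate_genome(
        genome_length, gc_content, n_mir, n_ncrna,
        REFERENCE_MATURE_MIRNAS, seed=seed,
    )
    if planted_fold_changes is None:
        # plant the salt responses on the most abundant loci so the
        # differential loci sit at comfortable read depth (mean >> 100)
        weights = _synthetic.default_locus_weights(genome, seed)
        ids = sorted(weights, key=lambda k: -weights[k])
        planted_fold_changes = {}
        if len(ids) >= 1:
            planted_fold_changes[ids[0]] = {"leaf_nacl": 4.0, "root_nacl": 4.0}
        if len(ids) >= 2:
            planted_fold_changes[ids[1]] = {"leaf_nacl": 0.25}
    for t in genome.mir_loci:
        t.fold_changes = planted_fold_changes.get(t.locus_id, {})
    designs = [
        _synthetic.LibraryDesign(lib, depth, seed=seed * 1000 + i)
        for i, (lib, depth) in enumerate(sorted(depths.items()))
    ]
    fastq, truth = _synthetic.simulate_libraries(
        genome, designs, planted_fold_changes, master_seed=seed
    )
    transcripts, tx_truth = _synthetic.generate_transcripts(genome, seed=seed)

    _io.write_fasta(outdir / "genome.fa", genome.contigs)
    _io.write_fasta(
        outdir / "ncrna.fa",
        {f"{l.category}|{l.locus_id}": l.sequence for l in genome.ncrna_loci},
    )
    _io.write_fasta(outdir / "reference.fa", REFERENCE_MATURE_MIRNAS)
    _io.write_fasta(outdir / "transcripts.fa", transcripts)
    _io.write_bed6(outdir / "mir_truth.bed", genome.mir_bed())
    _io.write_bed6(outdir / "ncrna.bed", genome.ncrna_bed())
    truth.to_csv(outdir / "truth_counts.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "locus_id": t.locus_id, "class": t.class_truth,
                "mismatches": "" if t.planted_mismatches is None else t.planted_mismatches,
                "reference": t.reference_match or "",
                "mature_5p": t.mature_5p, "mature_3p": t.mature_3p,
                "precursor_len": len(t.precursor_seq),
                "fold_changes": ";".join(
                    f"{k}={v}" for k, v in sorted(t.fold_changes.items())
                ),
            }
            for t in genome.mir_loci
        ]
    ).to_csv(outdir / "mir_truth.tsv", sep="\t", index=False)
    for lib, reads in fastq.items():
        _io.write_fastq(outdir / f"reads_{lib}.fastq", reads)
    config = {
        "genome": "genome.fa",
        "reads": {lib: f"reads_{lib}.fastq" for lib in depths},
        "ncrna_fasta": "ncrna.fa",
        "reference_fasta": "reference.fa",
        "transcripts_fasta": "transcripts.fa",
        "adaptor_3p": _synthetic.DEFAULT_ADAPTOR_3P,
        "contrasts": [["leaf_control", "leaf_nacl"], ["root_control", "root_nacl"]],
        "seed": seed,
        "outdir": "out",
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return outdir / "config.yaml", genome, truth
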