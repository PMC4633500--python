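"""Plant miRNA target scanning by complementarity scoring.

Each placement of a miRNA against a transcript window is scored 5'->3' on
the miRNA versus the site read 3'->5': Watson-Crick pairs cost 0, G:U
wobbles 0.5, mismatches 1 and gaps 2, with all penalties doubled at miRNA
positions 2-13 (1-based; the seed-proximal core).  The penalty total is the
*expectation*; sites with expectation <= 3 are reported.  A hit whose
central window (miRNA positions 9-11) contains any non-Watson-Crick
position is classed as translational inhibition, otherwise as cleavage.

Target-site accessibility (UPE) is recorded in the parameter set but not
computed; hits are never filtered on it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._seq import to_rna

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class TargetParams:
    max_expectation: float = 3.0
    hsp_size: int = 20
    flank_up: int = 17  # nt of transcript context upstream of the site
    flank_down: int = 13
    central_window: tuple[int, int] = (9, 11)  # 1-based miRNA positions
    upe_max: float = 25.0  # recorded; accessibility is not computed
    seed_band: tuple[int, int] = (2, 13)  # doubled-penalty positions
    gu_penalty: float = 0.5
    mismatch_penalty: float = 1.0
    gap_penalty: float = 2.0

    def __post_init__(self) -> None:
        if self.max_expectation < 0:
            raise ValueError("max_expectation must be >= 0")


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open site span on the transcript
    end: int
    expectation: float
    mode: str  # 'cleavage' or 'translation'
    alignment: str  # rendering, miRNA 5'->3' over site 3'->5'
    context: str = ""


def score_site(
    mirna: str, site: str, params: TargetParams = TargetParams()
) -> tuple[float, str, list[str]]:
    """Score one miRNA/site placement.

    ``site`` is the transcript subsequence 5'->3'; it is read back-to-front
    so target position i faces miRNA position i.  Returns (expectation,
    mode, per-position states) where states are 'WC', 'GU', 'mismatch' or
    'gap'.  Site length may differ from the miRNA by up to 4 nt; the
    overhanging positions are scored as gaps.
    """
    m = to_rna(mirna)
    s = to_rna(site)
    if not m or not s:
        raise ValueError("empty sequence")
    if abs(len(m) - len(s)) > 4:
        raise ValueError("site length must be within 4 nt of the miRNA")
    t = s[::-1]  # target read 3'->5', aligned to miRNA 5'->3'
    n = max(len(m), len(t))
    states: list[str] = []
    expectation = 0.0
    lo, hi = params.seed_band
    for i in range(n):
        pos = i + 1
        double = lo <= pos <= hi
        if i >= len(m) or i >= len(t):
            penalty, state = params.gap_penalty, "gap"
        else:
            duo = (m[i], t[i])
            if duo in _WC:
                penalty, state = 0.0, "WC"
            elif duo in _WOBBLE:
                penalty, state = params.gu_penalty, "GU"
            else:
                penalty, state = params.mismatch_penalty, "mismatch"
        expectation += penalty * (2.0 if double else 1.0)
        states.append(state)
    clo, chi = params.central_window
    central = states[clo - 1 : chi]
    mode = "translation" if any(st != "WC" for st in central) else "cleavage"
    return expectation, mode, states


def _render(mirna: str, site: str, states: list[str]) -> str:
    marks = {"WC": "|", "GU": "o", "mismatch": " ", "gap": "-"}
    m = to_rna(mirna)
    t = to_rna(site)[::-1]
    n = max(len(m), len(t))
    top = m.ljust(n, "-")
    bottom = t.ljust(n, "-")
    mid = "".join(marks[s] for s in states)
    return f"miRNA 5' {top} 3'\n         {mid}\ntarget 3' {bottom} 5'"


def scan_transcript(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    params: TargetParams = TargetParams(),
) -> list[TargetHit]:
    """All non-overlapping target sites of one miRNA on one transcript.

    Every window of miRNA length is scored; windows at or under the
    expectation cut-off are kept greedily by ascending expectation (ties:
    leftmost site), discarding overlaps.  The stored context is the site
    plus 17 nt upstream and 13 nt downstream, clipped to bounds.
    """
    m = to_rna(mirna)
    tx = to_rna(transcript)
    if len(tx) < len(m):
        raise ValueError("transcript shorter than the miRNA")
    L = len(m)
    scored: list[tuple[float, int, str, list[str]]] = []
    for s0 in range(len(tx) - L + 1):
        site = tx[s0 : s0 + L]
        e, mode, states = score_site(m, site, params)
        if e <= params.max_expectation:
            scored.append((e, s0, mode, states))
    scored.sort(key=lambda r: (r[0], r[1]))
    hits: list[TargetHit] = []
    taken: list[tuple[int, int]] = []
    for e, s0, mode, states in scored:
        span = (s0, s0 + L)
        if any(span[0] < b and a < span[1] for a, b in taken):
            continue
        taken.append(span)
        site = tx[s0 : s0 + L]
        ctx = tx[max(0, s0 - params.flank_up) : min(len(tx), s0 + L + params.flank_down)]
        hits.append(
            TargetHit(
                mirna_id, transcript_id, s0, s0 + L, e, mode,
                _render(m, site, states), ctx,
            )
        )
    hits.sort(key=lambda h: h.start)
    return hits


def summarize_targets(hits: list[TargetHit]) -> dict:
    """Per-mode counts/percentages plus per-miRNA and per-transcript
    multiplicity tables (percentages to one decimal)."""
    n = len(hits)
    modes = Counter(h.mode for h in hits)
    per_mirna = Counter(h.mirna_id for h in hits)
    per_transcript = Counter(h.transcript_id for h in hits)
    pct = {
        mode: round(100.0 * c / n, 1) if n else 0.0 for mode, c in modes.items()
    }
    return {
        "n_hits": n,
        "mode_counts": dict(modes),
        "mode_percent": pct,
        "per_mirna": pd.Series(per_mirna, dtype=int).sort_index(),
        "per_transcript": pd.Series(per_transcript, dtype=int).sort_index(),
    }


def mode_percentages(n_hits: int, n_cleavage: int) -> dict[str, float]:
    """Cleavage/translation percentages from plain tallies (one decimal)."""
    if n_hits <= 0:
        raise ValueError("n_hits must be positive")
    return {
        "cleavage": round(100.0 * n_cleavage / n_hits, 1),
        "translation": round(100.0 * (n_hits - n_cleavage) / n_hits, 1),
    }
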