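"""Independent brute-force oracles the test-suite checks the package against.

Each oracle re-derives its quantity from the definition alone (enumeration,
direct formula coding, exhaustive scan) without calling the implementation
path it is used to verify.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from palmirna.folding import score_structure

PAIRABLE = {
    ("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")
}


def enumerate_structures(seq: str) -> list[list[tuple[int, int]]]:
    """All non-crossing pair sets with hairpin loops >= 3 nt."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def gen(i: int, j: int) -> tuple:
        if i >= j:
            return ([],)
        out = [s for s in gen(i + 1, j)]
        for k in range(i + 4, j + 1):
            if (seq[i], seq[k]) in PAIRABLE:
                for inside in gen(i + 1, k - 1):
                    for outside in gen(k + 1, j):
                        out.append([(i, k)] + inside + outside)
        return tuple(out)

    return [list(s) for s in gen(0, n - 1)]


def min_energy_enumeration(seq: str) -> float:
    """Exhaustive minimum of the energy model over all structures."""
    return min(score_structure(seq, pairs) for pairs in enumerate_structures(seq))


def bh_stepup(p_values) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adjusted[idx] = running
    return adjusted


def size_factors_direct(matrix: np.ndarray) -> np.ndarray:
    """Direct coding of s_j = median_i [ c_ij / (prod_k c_ik)^(1/m) ]."""
    c = np.asarray(matrix, dtype=float)
    m = c.shape[1]
    rows = [i for i in range(c.shape[0]) if all(c[i, k] > 0 for k in range(m))]
    s = []
    for j in range(m):
        ratios = []
        for i in rows:
            geo = 1.0
            for k in range(m):
                geo *= c[i, k] ** (1.0 / m)
            ratios.append(c[i, j] / geo)
        s.append(float(np.median(ratios)))
    return np.array(s)


def _nb_logpmf_direct(k: int, mu: float, phi: float) -> float:
    if phi == 0.0:
        return k * math.log(mu) - mu - math.lgamma(k + 1)
    r = 1.0 / phi
    p = r / (r + mu)
    return (
        math.lgamma(k + r)
        - math.lgamma(r)
        - math.lgamma(k + 1)
        + r * math.log(p)
        + k * math.log1p(-p)
    )


def nb_exact_p_enumeration(ya: int, yb: int, phi: float) -> float:
    """Two-sided conditional exact p-value by full enumeration of the
    splits of n = ya + yb, with log-pmfs coded from the NB definition."""
    n = ya + yb
    mu = n / 2.0
    logs = [
        _nb_logpmf_direct(k, mu, phi) + _nb_logpmf_direct(n - k, mu, phi)
        for k in range(n + 1)
    ]
    mx = max(logs)
    probs = [math.exp(v - mx) for v in logs]
    total = sum(probs)
    obs = probs[ya]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-12)) / total)


_COMP = str.maketrans("ACGT", "TGCA")


def map_oracle(tag: str, contigs: dict[str, str], seed_len: int = 16):
    """Positionwise numpy scan: all ungapped placements on both strands
    with <= 1 mismatch, all mismatches before `seed_len`."""
    hits = []
    t = np.frombuffer(tag.encode(), dtype="S1")
    L = len(tag)
    for chrom, seq in contigs.items():
        g = np.frombuffer(seq.encode(), dtype="S1")
        if len(g) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(g, L)
        for strand in "+-":
            if strand == "+":
                q = t
                mism = windows != q
            else:
                rc = tag.translate(_COMP)[::-1]
                q = np.frombuffer(rc.encode(), dtype="S1")
                mism = windows != q
            counts = mism.sum(axis=1)
            for start in np.nonzero(counts <= 1)[0]:
                pos = np.nonzero(mism[start])[0]
                if strand == "-":
                    pos = (L - 1) - pos  # offsets within the tag itself
                if all(p < seed_len for p in pos):
                    hits.append((chrom, int(start), strand, tuple(int(p) for p in sorted(pos))))
    return sorted(hits)


def complete_linkage_bruteforce(points: np.ndarray):
    """Naive agglomeration recomputing the max pairwise member distance at
    every step; ties broken by the smallest original member index."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    clusters = {i: [i] for i in range(n)}
    merges = []
    label = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                dist = max(d[i, j] for i in clusters[a] for j in clusters[b])
                key = (dist, min(clusters[a] + clusters[b]), a, b)
                if best is None or key < best:
                    best = key
        dist, _, a, b = best
        merges.append((a, b, float(dist)))
        clusters[label] = clusters.pop(a) + clusters.pop(b)
        label += 1
    return merges


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def site_expectation_oracle(mirna: str, site: str) -> tuple[float, str]:
    """Independent coding of the complementarity expectation and mode."""
    m = mirna.upper().replace("T", "U")
    t = site.upper().replace("T", "U")[::-1]
    total = 0.0
    central_bad = False
    for i in range(max(len(m), len(t))):
        if i >= len(m) or i >= len(t):
            pen = 2.0
            wc = False
        else:
            pair = (m[i], t[i])
            if pair in _WC:
                pen, wc = 0.0, True
            elif pair in _GU:
                pen, wc = 0.5, False
            else:
                pen, wc = 1.0, False
        if 2 <= i + 1 <= 13:
            pen *= 2.0
        if 9 <= i + 1 <= 11 and not wc:
            central_bad = True
        total += pen
    return total, ("translation" if central_bad else "cleavage")
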