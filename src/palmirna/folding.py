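"""RNA secondary-structure prediction under a compact surrogate energy model.

The pipeline needs minimum-free-energy (MFE) hairpin structures for candidate
precursor windows.  Rather than wrapping an external thermodynamic engine,
the package ships a small, fully specified nearest-neighbour-flavoured model
that is deterministic and cheap enough to verify against exhaustive structure
enumeration:

* base-pair energies: G:C -3.0, A:U -2.0, G:U -1.0 kcal/mol;
* a stacking bonus of -0.5 for every pair whose directly enclosed neighbour
  ``(i+1, j-1)`` is also paired;
* loop penalties per occurrence: hairpin loop +3.0, bulge/internal loop +1.0,
  multibranch loop +3.0;
* hairpin loops span at least 3 unpaired nucleotides; pseudoknots are
  excluded (structures are non-crossing).

The total energy of a structure is the sum of its pair energies plus its
loop terms; the exterior loop is free.  :func:`score_structure` is the
normative definition of the model; :func:`fold` finds the minimising
structure by dynamic programming and is checked against brute-force
enumeration in the test-suite.

A real folding engine can be swapped in through the ``backend`` argument
(``"vienna"`` uses ViennaRNA when its Python bindings are importable); the
built-in model remains the default and the only one the tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._seq import check_alphabet, encode_rna, to_rna

INF = 1e30
MIN_HAIRPIN_LOOP = 3
#: max unpaired nucleotides per side of a bulge/internal loop considered by
#: the DP (the flat +1.0 penalty makes larger loops almost never optimal)
MAX_LOOP_SIDE = 30

HAIRPIN_PENALTY = 3.0
INTERNAL_PENALTY = 1.0
MULTI_PENALTY = 3.0
STACK_BONUS = -0.5

# pair energy matrix indexed by (code_i, code_j); A=0 C=1 G=2 U=3
_PAIR_E = np.full((4, 4), INF, dtype=np.float64)
_PAIR_E[2, 1] = _PAIR_E[1, 2] = -3.0  # G:C
_PAIR_E[0, 3] = _PAIR_E[3, 0] = -2.0  # A:U
_PAIR_E[2, 3] = _PAIR_E[3, 2] = -1.0  # G:U

_EPS = 1e-6


@dataclass(frozen=True)
class SecondaryStructure:
    """A folded sequence: dot-bracket string, MFE and a pair table."""

    sequence: str
    dot_bracket: str
    mfe: float
    pair_table: np.ndarray = field(repr=False)  # partner index or -1

    def __post_init__(self) -> None:
        if len(self.dot_bracket) != len(self.sequence):
            raise ValueError("dot_bracket length != sequence length")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [
            (i, int(j)) for i, j in enumerate(self.pair_table) if j > i
        ]


@njit(cache=True)
def _fill(codes):  # pragma: no cover - exercised through fold()
    n = codes.shape[0]
    V = np.full((n, n), INF)
    M1 = np.full((n, n), INF)
    pair_e = np.full((4, 4), INF)
    pair_e[2, 1] = -3.0
    pair_e[1, 2] = -3.0
    pair_e[0, 3] = -2.0
    pair_e[3, 0] = -2.0
    pair_e[2, 3] = -1.0
    pair_e[3, 2] = -1.0

    for d in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - d):
            j = i + d
            e = pair_e[codes[i], codes[j]]
            if e < INF:
                best = HAIRPIN_PENALTY  # hairpin loop closed by (i, j)
                # stack on (i+1, j-1)
                if V[i + 1, j - 1] < INF:
                    v = V[i + 1, j - 1] + STACK_BONUS
                    if v < best:
                        best = v
                # bulge / internal loop to inner pair (k, l)
                kmax = min(i + 1 + MAX_LOOP_SIDE, j - 1)
                for k in range(i + 1, kmax + 1):
                    lmin = max(k + MIN_HAIRPIN_LOOP + 1, j - 1 - MAX_LOOP_SIDE)
                    for l in range(lmin, j):
                        if k == i + 1 and l == j - 1:
                            continue
                        if V[k, l] < INF:
                            v = V[k, l] + INTERNAL_PENALTY
                            if v < best:
                                best = v
                # multibranch: >= 2 branches inside (i, j)
                for m in range(i + 2, j - 1):
                    if M1[i + 1, m] < INF and M1[m + 1, j - 1] < INF:
                        v = M1[i + 1, m] + M1[m + 1, j - 1] + MULTI_PENALTY
                        if v < best:
                            best = v
                V[i, j] = e + best
            # M1: >= 1 branch in [i, j], unpaired positions free
            best_m = M1[i + 1, j] if i + 1 <= j else INF
            for q in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if V[i, q] < INF:
                    rest = 0.0
                    if q + 1 <= j and M1[q + 1, j] < 0.0:
                        rest = M1[q + 1, j]
                    v = V[i, q] + rest
                    if v < best_m:
                        best_m = v
            M1[i, j] = best_m
    # exterior
    W = np.zeros(n + 1)
    for j in range(n):
        best = W[j]  # leave j unpaired  (W indexed with +1 offset)
        for i in range(0, j - MIN_HAIRPIN_LOOP):
            if V[i, j] < INF:
                v = W[i] + V[i, j]
                if v < best:
                    best = v
        W[j + 1] = best
    return V, M1, W


def _trace(codes: np.ndarray, V, M1, W) -> list[tuple[int, int]]:
    """Deterministic traceback: prefer stacking (longest helix), then the
    smallest 5' index among equal-energy alternatives."""
    n = len(codes)
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = [("W", 0, n - 1)]
    while stack:
        kind, i, j = stack.pop()
        if kind == "W":
            # W[j+1] over suffix handled iteratively right-to-left
            jj = j
            while jj >= i:
                if abs(W[jj + 1] - W[jj]) < _EPS:
                    jj -= 1
                    continue
                found = False
                for a in range(i, jj - MIN_HAIRPIN_LOOP):
                    if V[a, jj] < INF and abs(W[jj + 1] - (W[a] + V[a, jj])) < _EPS:
                        stack.append(("V", a, jj))
                        jj = a - 1
                        found = True
                        break
                if not found:  # pragma: no cover - defensive
                    jj -= 1
        elif kind == "V":
            pairs.append((i, j))
            e = _PAIR_E[codes[i], codes[j]]
            target = V[i, j] - e
            if (
                i + 1 < j - 1
                and V[i + 1, j - 1] < INF
                and abs(target - (V[i + 1, j - 1] + STACK_BONUS)) < _EPS
            ):
                stack.append(("V", i + 1, j - 1))
                continue
            if abs(target - HAIRPIN_PENALTY) < _EPS:
                continue
            done = False
            kmax = min(i + 1 + MAX_LOOP_SIDE, j - 1)
            for k in range(i + 1, kmax + 1):
                lmin = max(k + MIN_HAIRPIN_LOOP + 1, j - 1 - MAX_LOOP_SIDE)
                for l in range(j - 1, lmin - 1, -1):
                    if k == i + 1 and l == j - 1:
                        continue
                    if V[k, l] < INF and abs(target - (V[k, l] + INTERNAL_PENALTY)) < _EPS:
                        stack.append(("V", k, l))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            for m in range(i + 2, j - 1):
                if (
                    M1[i + 1, m] < INF
                    and M1[m + 1, j - 1] < INF
                    and abs(target - (M1[i + 1, m] + M1[m + 1, j - 1] + MULTI_PENALTY)) < _EPS
                ):
                    stack.append(("M1", i + 1, m))
                    stack.append(("M1", m + 1, j - 1))
                    done = True
                    break
            if not done:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed at V")
        else:  # M1
            ii = i
            while ii <= j:
                if ii + 1 <= j and abs(M1[ii, j] - M1[ii + 1, j]) < _EPS:
                    ii += 1
                    continue
                found = False
                for q in range(ii + MIN_HAIRPIN_LOOP + 1, j + 1):
                    if V[ii, q] >= INF:
                        continue
                    rest = 0.0
                    if q + 1 <= j and M1[q + 1, j] < 0.0:
                        rest = M1[q + 1, j]
                    if abs(M1[ii, j] - (V[ii, q] + rest)) < _EPS:
                        stack.append(("V", ii, q))
                        if rest < 0.0:
                            stack.append(("M1", q + 1, j))
                        found = True
                        break
                if found:
                    break
                ii += 1  # pragma: no cover - defensive
            continue
    return pairs


def pairs_to_dotbracket(pairs: list[tuple[int, int]], n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def pairs_to_table(pairs: list[tuple[int, int]], n: int) -> np.ndarray:
    table = np.full(n, -1, dtype=np.int64)
    for i, j in pairs:
        table[i] = j
        table[j] = i
    return table


def fold(sequence: str, backend: str = "builtin") -> SecondaryStructure:
    """Fold an RNA sequence into its MFE non-crossing structure.

    ``backend="builtin"`` (default) uses the surrogate model above;
    ``backend="vienna"`` delegates to ViennaRNA if importable.
    """
    rna = to_rna(sequence)
    if not rna:
        raise ValueError("cannot fold an empty sequence")
    check_alphabet(rna, "ACGU")
    if backend == "vienna":
        return _fold_vienna(rna)
    if backend != "builtin":
        raise ValueError(f"unknown folding backend {backend!r}")
    codes = encode_rna(rna)
    n = len(codes)
    if n <= MIN_HAIRPIN_LOOP + 1:
        return SecondaryStructure(rna, "." * n, 0.0, pairs_to_table([], n))
    V, M1, W = _fill(codes)
    mfe = float(W[n])
    if mfe >= 0.0 - _EPS and mfe <= 0.0 + _EPS:
        # mfe == 0 iff the structure has no pairs; never keep a
        # zero-energy paired structure
        return SecondaryStructure(rna, "." * n, 0.0, pairs_to_table([], n))
    pairs = _trace(codes, V, M1, W)
    return SecondaryStructure(
        rna, pairs_to_dotbracket(pairs, n), round(mfe, 6), pairs_to_table(pairs, n)
    )


def _fold_vienna(rna: str) -> SecondaryStructure:  # pragma: no cover - optional
    import RNA

    db, mfe = RNA.fold(rna)
    pairs = dotbracket_to_pairs(db)
    return SecondaryStructure(rna, db, float(mfe), pairs_to_table(pairs, len(rna)))


def dotbracket_to_pairs(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket symbol {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def score_structure(sequence: str, pairs: list[tuple[int, int]]) -> float:
    """Energy of a given structure under the built-in model.

    This function *defines* the model: :func:`fold` minimises it.  Raises on
    invalid structures (crossing pairs, unpairable bases, hairpin loop < 3).
    """
    rna = to_rna(sequence)
    codes = encode_rna(rna)
    n = len(codes)
    seen: set[int] = set()
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ValueError(f"pair out of range: {(i, j)}")
        if i in seen or j in seen:
            raise ValueError("position paired twice")
        seen.update((i, j))
        if _PAIR_E[codes[i], codes[j]] >= INF:
            raise ValueError(f"unpairable bases at {(i, j)}")
    ordered = sorted(pairs)
    for a in range(len(ordered)):
        for b in range(a + 1, len(ordered)):
            i, j = ordered[a]
            k, l = ordered[b]
            if i < k < j < l:
                raise ValueError("crossing pairs (pseudoknot)")
    energy = 0.0
    children = _direct_children(ordered)
    for (i, j), kids in children.items():
        energy += float(_PAIR_E[codes[i], codes[j]])
        if not kids:
            if j - i - 1 < MIN_HAIRPIN_LOOP:
                raise ValueError(f"hairpin loop shorter than {MIN_HAIRPIN_LOOP}")
            energy += HAIRPIN_PENALTY
        elif len(kids) == 1:
            k, l = kids[0]
            energy += STACK_BONUS if (k == i + 1 and l == j - 1) else INTERNAL_PENALTY
        else:
            energy += MULTI_PENALTY
    return round(energy, 6)


def _direct_children(
    ordered: list[tuple[int, int]],
) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Map each pair to the pairs it directly encloses (nested forest)."""
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in ordered}
    stack: list[tuple[int, int]] = []
    for p in ordered:  # sorted by opening position
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        if stack:
            children[stack[-1]].append(p)
        stack.append(p)
    return children


def hairpin_loops(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Innermost pairs (those closing hairpin loops), sorted by position."""
    kids = _direct_children(sorted(pairs))
    return sorted(p for p, c in kids.items() if not c)
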