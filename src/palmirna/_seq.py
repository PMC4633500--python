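"""Small nucleic-acid string helpers shared across the package.

Sequences move between a DNA alphabet (reads, genome) and an RNA alphabet
(mature miRNAs, precursors).  All comparisons inside the package are done
after normalising to one alphabet with :func:`to_rna` / :func:`to_dna`.
"""

from __future__ import annotations

import numpy as np

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")

#: integer encoding used by the folding dynamic programme
ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


def to_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and convert U -> T."""
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1].upper()


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1].upper()


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    if not s:
        return 0.0
    return (s.count("G") + s.count("C")) / len(s)


def encode_rna(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 codes (A=0, C=1, G=2, U/T=3)."""
    try:
        return np.array([ENCODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from exc


def check_alphabet(seq: str, alphabet: str = "ACGUT") -> None:
    bad = set(seq.upper()) - set(alphabet)
    if bad:
        raise ValueError(f"sequence contains invalid symbols: {sorted(bad)}")
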