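"""Nucleotide-sequence helpers shared across the package.

Sequences are plain upper-case strings over ``ACGTN`` (IUPAC degenerate
codes are allowed in motif and enzyme patterns only).  ``N`` is treated
as an unknown base: it never matches anything, including another ``N``.
"""

from __future__ import annotations

import re
from typing import Iterator

import numpy as np

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: IUPAC nucleotide codes -> the set of concrete bases each stands for.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware (``R``<->``Y`` etc.)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_sequence(seq: str, *, name: str = "sequence", allow_empty: bool = False) -> str:
    """Upper-case ``seq`` and check it is over ``ACGTN``."""
    if not isinstance(seq, str):
        raise TypeError(f"{name} must be a string, got {type(seq).__name__}")
    seq = seq.upper()
    if not seq and not allow_empty:
        raise ValueError(f"{name} is empty")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"{name} contains non-nucleotide characters: {sorted(bad)}")
    return seq


def validate_iupac(pattern: str, *, name: str = "pattern") -> str:
    pattern = pattern.upper()
    if not pattern:
        raise ValueError(f"{name} is empty")
    bad = set(pattern) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in {name} {pattern!r}")
    return pattern


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a regex over concrete bases.

    Degenerate codes become character classes of concrete bases, so an
    ``N`` *in the scanned sequence* can never satisfy any pattern
    position.
    """
    pattern = validate_iupac(pattern)
    parts = []
    for code in pattern:
        bases = IUPAC_CODES[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def iter_iupac_matches(seq: str, pattern: str) -> Iterator[int]:
    """Yield every start offset where ``pattern`` matches ``seq``.

    Overlapping occurrences are all reported (lookahead scan).
    """
    rx = re.compile(f"(?={iupac_regex(pattern)})")
    for m in rx.finditer(seq):
        yield m.start()


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random sequence over ACGT."""
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator,
                    protected: set[int] | None = None) -> str:
    """Substitute each site with probability ``rate`` to one of the other
    three bases (Jukes-Cantor-like, equal probabilities).

    Sites in ``protected`` are never mutated.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"substitution rate must be in [0,1], got {rate}")
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = rng.random(len(seq)) < rate
    if protected:
        idx = np.fromiter(protected, dtype=int)
        hits[idx] = False
    for i in np.nonzero(hits)[0]:
        others = DNA_ALPHABET.replace(seq[i], "")
        arr[i] = rng.choice(list(others)).encode()
    return arr.tobytes().decode()


def cpg_positions(seq: str) -> list[int]:
    """0-based start positions of every CpG dinucleotide on the top strand."""
    return [m.start() for m in re.finditer("(?=CG)", seq)]
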