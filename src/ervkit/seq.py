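"""Small DNA-string utilities shared across modules."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a DNA string with the standard nuclear code ('*' for stops).

    Trailing bases that do not fill a codon are ignored.
    """
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def check_dna(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{what} is empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")


def random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    """Random DNA with i.i.d. bases at the given GC fraction."""
    if n <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = rng.choice(bases, size=n, p=probs)
    return arr.tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Apply independent substitutions at the given per-site rate.

    Each selected site is replaced by one of the three other bases, uniformly.
    Returns the mutated string and the number of sites changed (every drawn
    substitution changes the base, so this equals the Hamming distance to the
    input).
    """
    if not 0 <= rate < 0.5:
        raise ValueError("substitution rate must be in [0, 0.5)")
    if rate == 0 or not seq:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    idx = np.nonzero(rng.random(arr.size) < rate)[0]
    if idx.size == 0:
        return seq, 0
    code = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    new = (code[arr[idx]] + rng.integers(1, 4, size=idx.size)) % 4
    arr[idx] = lut[new]
    return arr.tobytes().decode("ascii"), int(idx.size)
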