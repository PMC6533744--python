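"""Small DNA-string helpers shared across the pipeline.

Sequences are plain upper-case Python strings over A/C/G/T (N allowed in
read data, never in enzyme motifs). Coordinates are 0-based half-open.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte values of the four bases, used for fast random-sequence generation
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of *seq* (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Strand-invariant representative: lexicographic min of seq and its
    reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random A/C/G/T string of *length* drawn from *rng*."""
    return _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def validate_motif(motif: str, name: str = "motif") -> str:
    """Enzyme recognition motifs must be non-empty and strictly A/C/G/T."""
    if not motif or any(c not in "ACGT" for c in motif):
        raise ValidationError(f"{name} must be a non-empty A/C/G/T string, got {motif!r}")
    return motif


def validate_dna(seq: str, name: str = "sequence", allow_n: bool = True) -> str:
    """Check *seq* is non-empty upper-case DNA (optionally with N)."""
    alphabet = "ACGTN" if allow_n else "ACGT"
    if not seq:
        raise ValidationError(f"{name} must be non-empty")
    if any(c not in alphabet for c in seq):
        bad = sorted({c for c in seq if c not in alphabet})
        raise ValidationError(f"{name} contains non-DNA characters {bad}")
    return seq


def find_occurrences(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) start offsets of *motif* in *seq*."""
    out: list[int] = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValidationError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
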