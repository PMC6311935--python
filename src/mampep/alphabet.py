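"""Canonical amino-acid alphabet and integer encoding.

The 20 one-letter codes in alphabetical order define the fixed row order of
the embedding table, synthetic-allele weight matrices and position frequency
matrices throughout the package.
"""

from __future__ import annotations

import numpy as np

AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ALPHABET)}

# Ambiguity/rare codes are rejected outright: motif statistics over a
# 20-letter alphabet must not be contaminated by B/J/O/U/X/Z residues.
NON_CANONICAL = frozenset("BJOUXZ")


class SequenceError(ValueError):
    """Raised when a peptide contains a non-canonical residue."""


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and verify every character is a canonical residue.

    Raises
    ------
    SequenceError
        Naming the first offending character and its 1-based position.
    """
    s = str(seq).strip().upper()
    for pos, ch in enumerate(s, start=1):
        if ch not in AA_INDEX:
            raise SequenceError(
                f"non-canonical residue {ch!r} at position {pos} in {s!r}"
            )
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a peptide into integer indices over the fixed alphabet order."""
    s = normalize_sequence(seq)
    return np.fromiter((AA_INDEX[c] for c in s), dtype=np.int64, count=len(s))


def decode(indices: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join(AA_ALPHABET[int(i)] for i in indices)
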