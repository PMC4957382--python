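"""Small sequence utilities shared across the pipeline.

All sequences are handled internally as uppercase DNA (``U`` converted to
``T``); coordinates are 0-based half-open unless a file format dictates
otherwise (GFF3 export converts to 1-based inclusive).
"""

from __future__ import annotations

DNA_ALPHABET = frozenset("ACGT")
RNA_OK = frozenset("ACGTU")

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def u_to_t(sequence: str) -> str:
    """Normalize an RNA/DNA string to the DNA alphabet (uppercase, U->T)."""
    return sequence.upper().replace("U", "T")


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA/RNA string (returned in DNA alphabet)."""
    return u_to_t(sequence).translate(_COMPLEMENT)[::-1]


def check_alphabet(sequence: str, allow_u: bool = True) -> None:
    allowed = RNA_OK if allow_u else DNA_ALPHABET
    bad = set(sequence.upper()) - allowed
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
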