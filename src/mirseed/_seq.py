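"""Small sequence helpers shared across modules.

All genomic sequences are handled in DNA space (A/C/G/T); RNA input
(U instead of T) is normalized on entry. Coordinates are 0-based,
half-open, strand '+'/'-'.
"""

from __future__ import annotations

_DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def to_dna(seq: str) -> str:
    """Uppercase and convert U->T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and convert T->U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction of a sequence (0 for the empty string)."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def au_fraction(seq: str) -> float:
    """A+U (A+T in DNA space) fraction of a sequence."""
    if not seq:
        return 0.0
    s = to_dna(seq)
    return (s.count("A") + s.count("T")) / len(s)
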