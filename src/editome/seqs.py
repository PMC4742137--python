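"""Small sequence helpers shared across modules."""

from __future__ import annotations

from Bio.Seq import Seq

BASES = ("A", "C", "G", "T")
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: The 12 possible single-base substitution types, e.g. "A-to-G".
SUBSTITUTION_TYPES = tuple(
    f"{r}-to-{a}" for r in BASES for a in BASES if r != a
)

#: ADAR- and APOBEC-mediated substitutions; everything else is non-canonical.
CANONICAL_TYPES = ("A-to-G", "C-to-T")


def complement(base: str) -> str:
    """Complement of a single base (involution on {A,C,G,T})."""
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence."""
    return seq.translate(_COMP)[::-1]


def rna_to_dna(seq: str) -> str:
    """Normalize an RNA sequence (U) to its DNA alphabet (T), uppercased."""
    return seq.upper().replace("U", "T")


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code ('*' marks stops)."""
    return str(Seq(cds).translate())


def substitution_label(ref: str, alt: str) -> str:
    """Format a substitution as the field-standard 'X-to-Y' string."""
    return f"{ref}-to-{alt}"
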