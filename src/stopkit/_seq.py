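"""Small DNA sequence utilities shared across modules.

Thin wrappers around :mod:`Bio.Seq` plus IUPAC motif matching. All coordinates
in this package are 0-based, half-open unless a docstring says otherwise.
"""

from __future__ import annotations

from Bio.Seq import Seq

DNA_BASES = "ACGT"

#: IUPAC nucleotide code -> set of concrete bases it matches.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class DnaInputError(ValueError):
    """Raised when a sequence contains characters outside A/C/G/T/N."""


def clean_dna(seq: str, allow_n: bool = True) -> str:
    """Uppercase ``seq`` and validate its alphabet.

    Raises :class:`DnaInputError` on anything other than A/C/G/T (and N when
    ``allow_n``).
    """
    s = seq.upper()
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(s) - allowed
    if bad:
        raise DnaInputError(f"non-DNA characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement (N-safe)."""
    return str(Seq(seq).reverse_complement())


def complement_base(base: str) -> str:
    return str(Seq(base).complement())


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code ('*' for stops)."""
    return str(Seq(cds).translate())


def iupac_match(pattern: str, site: str) -> bool:
    """True if ``site`` (concrete bases) matches the IUPAC ``pattern``.

    A site containing N never matches: candidate discovery must not report
    sites resting on unknown bases.
    """
    if len(pattern) != len(site):
        return False
    for p, s in zip(pattern, site):
        if s not in IUPAC[p]:
            return False
    return True
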