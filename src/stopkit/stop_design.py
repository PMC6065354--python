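"""Design of stop-codon-introducing C>T base edits.

Scans a coding sequence for cytosines that (i) sit inside the deaminase
editing window, a fixed span of positions 5' of a PAM on the PAM-bearing
strand, and (ii) create a premature stop codon (TAA/TAG/TGA) when converted
to thymine. Sense-strand candidates arise from CAA/CAG/CGA codons (C at codon
position 1); antisense candidates are G>A changes on the coding strand inside
a TGG (Trp) codon.

Position convention: PAM-relative position -1 is the base immediately 5' of
the PAM's first base on the PAM-bearing strand; the editing window defaults
to -20..-16. Coordinates are 0-based half-open internally; reports use
1-based "c." numbering within the coding sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._seq import (
    IUPAC,
    STOP_CODONS,
    DnaInputError,
    clean_dna,
    iupac_match,
    revcomp,
)

logger = logging.getLogger(__name__)

SENSE = "sense"
ANTISENSE = "antisense"

#: Percent deamination efficiency by PAM-relative position (nCas9-PmCDA1 in
#: yeast, the profile used to rank candidates): roughly 5/25/45/35/5 % at
#: positions -20..-16.
DEFAULT_WEIGHTS = {-20: 5.0, -19: 25.0, -18: 45.0, -17: 35.0, -16: 5.0}

DEFAULT_WINDOW = (-20, -16)
DEFAULT_SPACER_LEN = 18


class BoundaryError(ValueError):
    """A requested region runs off the sequence record."""


class FrameError(ValueError):
    """CDS offsets do not describe an in-frame coding region."""


@dataclass(frozen=True)
class CodingSequence:
    """A sequence record with explicit CDS offsets.

    ``seq`` is the sense (coding) strand as given; ``cds_start`` is the
    0-based offset of the first base of the start codon, ``cds_end`` one past
    the last base of the stop codon (half-open). Introns/flanks are simply the
    parts of ``seq`` outside [cds_start, cds_end) — no case parsing.
    """

    id: str
    seq: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", clean_dna(self.seq))
        n = self.cds_end - self.cds_start
        if n <= 0 or n % 3 != 0:
            raise FrameError(
                f"{self.id}: CDS span {n} is not a positive multiple of 3"
            )
        if self.cds_start < 0 or self.cds_end > len(self.seq):
            raise FrameError(f"{self.id}: CDS offsets outside record")

    @property
    def cds(self) -> str:
        return self.seq[self.cds_start : self.cds_end]


@dataclass(frozen=True)
class PamSpec:
    """PAM motifs to scan for (IUPAC), canonical NGG by default."""

    patterns: tuple[str, ...] = ("NGG",)
    pam_len: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "patterns", tuple(p.upper() for p in self.patterns)
        )
        for p in self.patterns:
            if len(p) != self.pam_len:
                raise ValueError(f"PAM pattern {p!r} is not length {self.pam_len}")
            bad = set(p) - set(IUPAC)
            if bad:
                raise ValueError(f"PAM pattern {p!r}: non-IUPAC codes {sorted(bad)}")

    def matches(self, site: str) -> bool:
        return any(iupac_match(p, site) for p in self.patterns)


@dataclass(frozen=True)
class EfficiencyProfile:
    """Percent deamination rate by PAM-relative position; 0 elsewhere."""

    weights: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        for pos, w in self.weights.items():
            if not 0.0 <= w <= 100.0:
                raise ValueError(f"weight at {pos} outside [0, 100]: {w}")

    def score(self, pam_relative_pos: int) -> float:
        return float(self.weights.get(pam_relative_pos, 0.0))


def score_position(pos: int, profile: EfficiencyProfile | None = None) -> float:
    """Expected percent deamination at PAM-relative position ``pos``."""
    return (profile or EfficiencyProfile()).score(pos)


@dataclass(frozen=True)
class CandidateStopEdit:
    """One editable cytosine whose C>T conversion yields a stop codon.

    ``strand`` is "sense" when the target C is on the coding strand and
    "antisense" when the C lies on the reverse complement (a G>A change as
    seen on the coding strand). ``score`` is the profile percent at
    ``pam_relative_pos``; ``other_window_cytosines`` lists PAM-relative
    positions of bystander Cs in the same window (reported, never filtered).
    """

    locus_id: str
    c_pos_in_record: int
    cds_c_number: int
    pam_relative_pos: int
    strand: str
    codon_before: str
    codon_after: str
    spacer_seq: str
    pam_seq: str
    score: float
    other_window_cytosines: tuple[int, ...]
    pam_start_in_record: int

    TSV_COLUMNS = (
        "locus_id", "c_pos_in_record", "cds_c_number", "pam_relative_pos",
        "strand", "codon_before", "codon_after", "spacer_seq", "pam_seq",
        "score", "other_window_cytosines", "pam_start_in_record",
    )


def _window_record_index(pam_start: int, strand: str, pos: int, pam_len: int = 3) -> int:
    """Record index of PAM-relative position ``pos`` (negative, 5' of PAM).

    Sense: -k maps to pam_start - k. Antisense: the PAM is read on the
    reverse complement with its first base at record index pam_start +
    pam_len - 1, so -k maps to pam_start + pam_len - 1 + k.
    """
    if strand == SENSE:
        return pam_start + pos
    return pam_start + pam_len - 1 - pos


def find_pam_sites(
    seq: str, pam: PamSpec | None = None, both_strands: bool = True
) -> list[tuple[int, str]]:
    """Every (pam_start, strand) where a PAM motif occurs.

    ``pam_start`` is the 0-based record index of the leftmost base the PAM
    occupies on either strand; for antisense hits the motif matches the
    reverse complement of ``seq[pam_start:pam_start+pam_len]``. Output is
    deterministic: ascending by position, sense before antisense.
    """
    pam = pam or PamSpec()
    s = clean_dna(seq)
    hits: list[tuple[int, str]] = []
    for i in range(len(s) - pam.pam_len + 1):
        site = s[i : i + pam.pam_len]
        if "N" in site:
            continue
        if pam.matches(site):
            hits.append((i, SENSE))
        if both_strands and pam.matches(revcomp(site)):
            hits.append((i, ANTISENSE))
    hits.sort(key=lambda h: (h[0], h[1] != SENSE))
    return hits


def spacer_for(
    pam_start: int,
    strand: str,
    record_seq: str,
    spacer_len: int = DEFAULT_SPACER_LEN,
    pam_len: int = 3,
) -> str:
    """The ``spacer_len`` bases immediately 5' of the PAM, 5'->3' on the
    PAM-bearing strand.

    Note a target C at -19/-20 lies outside an 18-nt spacer; that is legal —
    the editing window extends past the spacer's 5' end.
    """
    if strand == SENSE:
        lo, hi = pam_start - spacer_len, pam_start
        if lo < 0:
            raise BoundaryError("spacer runs off the 5' end of the record")
        return record_seq[lo:hi]
    lo, hi = pam_start + pam_len, pam_start + pam_len + spacer_len
    if hi > len(record_seq):
        raise BoundaryError("spacer runs off the 3' end of the record")
    return revcomp(record_seq[lo:hi])


def enumerate_stop_edits(
    cds: CodingSequence,
    pam: PamSpec | None = None,
    profile: EfficiencyProfile | None = None,
    window: tuple[int, int] = DEFAULT_WINDOW,
    spacer_len: int = DEFAULT_SPACER_LEN,
    sense_only: bool = False,
) -> list[CandidateStopEdit]:
    """All (C position, PAM) pairs whose C>T edit creates a premature stop.

    Every PAM generates independent candidates — the same C reachable from
    two PAMs is reported twice with its two scores. Windows or codons
    touching an N are skipped (counted in the log). Candidates are sorted by
    ``cds_c_number`` then score descending.
    """
    pam = pam or PamSpec()
    profile = profile or EfficiencyProfile()
    lo, hi = min(window), max(window)
    seq = cds.seq
    n_skipped_n = 0
    out: list[CandidateStopEdit] = []

    for pam_start, strand in find_pam_sites(seq, pam, both_strands=not sense_only):
        if sense_only and strand != SENSE:
            continue
        window_idx = {
            p: _window_record_index(pam_start, strand, p, pam.pam_len)
            for p in range(lo, hi + 1)
        }
        if any(i < 0 or i >= len(seq) for i in window_idx.values()):
            continue
        if any(seq[i] == "N" for i in window_idx.values()):
            n_skipped_n += 1
            continue
        # Base identity of a window C as seen on the coding strand.
        c_on_record = "C" if strand == SENSE else "G"
        edited_base = "T" if strand == SENSE else "A"
        for p, i in window_idx.items():
            if seq[i] != c_on_record:
                continue
            if not (cds.cds_start <= i < cds.cds_end):
                continue
            cds_c_number = i - cds.cds_start + 1
            codon_idx = (cds_c_number - 1) // 3
            codon_off = (cds_c_number - 1) % 3
            cstart = cds.cds_start + 3 * codon_idx
            codon_before = seq[cstart : cstart + 3]
            if "N" in codon_before:
                n_skipped_n += 1
                continue
            if codon_before in STOP_CODONS:
                continue  # editing an existing stop creates nothing new
            codon_after = (
                codon_before[:codon_off] + edited_base + codon_before[codon_off + 1 :]
            )
            if codon_after not in STOP_CODONS:
                continue
            try:
                spacer = spacer_for(pam_start, strand, seq, spacer_len, pam.pam_len)
            except BoundaryError:
                continue
            pam_site = seq[pam_start : pam_start + pam.pam_len]
            pam_seq = pam_site if strand == SENSE else revcomp(pam_site)
            bystanders = tuple(
                q
                for q, j in sorted(window_idx.items())
                if q != p and seq[j] == c_on_record
            )
            out.append(
                CandidateStopEdit(
                    locus_id=cds.id,
                    c_pos_in_record=i,
                    cds_c_number=cds_c_number,
                    pam_relative_pos=p,
                    strand=strand,
                    codon_before=codon_before,
                    codon_after=codon_after,
                    spacer_seq=spacer,
                    pam_seq=pam_seq,
                    score=profile.score(p),
                    other_window_cytosines=bystanders,
                    pam_start_in_record=pam_start,
                )
            )
    if n_skipped_n:
        logger.info("skipped %d window/codon contexts containing N", n_skipped_n)
    out.sort(key=lambda c: (c.cds_c_number, -c.score, c.pam_start_in_record, c.strand))
    return out


def apply_edit(cds: CodingSequence, cand: CandidateStopEdit) -> str:
    """The record sequence after applying the candidate's single-base edit."""
    base = "T" if cand.strand == SENSE else "A"
    i = cand.c_pos_in_record
    return cds.seq[:i] + base + cds.seq[i + 1 :]
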