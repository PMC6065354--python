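"""Off-target candidate enumeration for a spacer sequence.

Exhaustive scan of subject sequences on both strands for protospacer-length
sites adjacent to a PAM (canonical NGG, optionally non-canonical NAG) within
a bounded Hamming distance of the spacer. No bulges: mismatch counting only.

Ranking is by mismatch count; ties are broken by how PAM-proximal the
mismatches are — sites whose mismatches crowd the seed region next to the
PAM are less likely to be cleaved and rank later.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from ._seq import clean_dna, revcomp
from .stop_design import ANTISENSE, SENSE, PamSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OffTargetHit:
    """One candidate site: where it is, and how it differs from the spacer.

    ``pam_start`` is the 0-based index of the leftmost subject base the PAM
    occupies (for antisense hits the motif reads on the reverse complement).
    ``mismatch_positions`` are PAM-relative (-1 adjacent to the PAM).
    ``site_seq`` is the protospacer-length subject sequence on the PAM-bearing
    strand, 5'->3'.
    """

    subject_id: str
    pam_start: int
    strand: str
    mismatch_count: int
    mismatch_positions: tuple[int, ...]
    pam_seq: str
    site_seq: str

    TSV_COLUMNS = (
        "subject_id", "pam_start", "strand", "mismatch_count",
        "mismatch_positions", "pam_seq", "site_seq",
    )


def _seed_penalty(positions: Iterable[int]) -> float:
    """Larger when mismatches sit closer to the PAM (position -1)."""
    return sum(1.0 / -p for p in positions)


def scan_offtargets(
    spacer: str,
    subjects: Mapping[str, str],
    pam: PamSpec | None = None,
    max_mismatches: int = 4,
) -> list[OffTargetHit]:
    """Enumerate candidate off-target sites of ``spacer`` in ``subjects``.

    ``subjects`` maps sequence id -> sequence. Both strands of every subject
    are scanned; a hit is any PAM match whose upstream protospacer-length
    site has at most ``max_mismatches`` Hamming mismatches to the spacer.
    The true target, if present, appears with mismatch_count 0. Subjects too
    short to host the spacer are skipped with a log message.
    """
    pam = pam or PamSpec()
    sp = clean_dna(spacer, allow_n=False)
    L = len(sp)
    if not 15 <= L <= 25:
        raise ValueError(f"implausible spacer length {L}")

    hits: list[OffTargetHit] = []
    for sid, subject in subjects.items():
        s = clean_dna(subject)
        if len(s) < L + pam.pam_len:
            logger.warning("subject %s shorter than spacer+PAM; skipped", sid)
            continue
        for pam_start in range(len(s) - pam.pam_len + 1):
            pam_site = s[pam_start : pam_start + pam.pam_len]
            if "N" in pam_site:
                continue
            # sense: protospacer occupies [pam_start-L, pam_start)
            if pam.matches(pam_site) and pam_start - L >= 0:
                site = s[pam_start - L : pam_start]
                hit = _compare(sp, site, sid, pam_start, SENSE, pam_site, max_mismatches)
                if hit:
                    hits.append(hit)
            # antisense: PAM reads on revcomp; protospacer occupies
            # [pam_start+pam_len, pam_start+pam_len+L) and reads right-to-left
            rc_pam = revcomp(pam_site)
            if pam.matches(rc_pam) and pam_start + pam.pam_len + L <= len(s):
                site = revcomp(s[pam_start + pam.pam_len : pam_start + pam.pam_len + L])
                hit = _compare(sp, site, sid, pam_start, ANTISENSE, rc_pam, max_mismatches)
                if hit:
                    hits.append(hit)
    hits.sort(
        key=lambda h: (
            h.mismatch_count,
            _seed_penalty(h.mismatch_positions),
            h.subject_id,
            h.pam_start,
            h.strand != SENSE,
        )
    )
    return hits


def _compare(
    spacer: str,
    site: str,
    sid: str,
    pam_start: int,
    strand: str,
    pam_seq: str,
    max_mm: int,
) -> OffTargetHit | None:
    if "N" in site:
        return None
    L = len(spacer)
    # spacer index j is PAM-relative position j - L (so the last base is -1)
    mm = tuple(j - L for j in range(L) if spacer[j] != site[j])
    if len(mm) > max_mm:
        return None
    return OffTargetHit(
        subject_id=sid,
        pam_start=pam_start,
        strand=strand,
        mismatch_count=len(mm),
        mismatch_positions=mm,
        pam_seq=pam_seq,
        site_seq=site,
    )
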