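"""Quantification of base-editing outcomes from amplicon deep sequencing.

Pipeline: semi-global alignment of each read to the amplicon reference with
fixed edit costs (mismatch 2, insertion 3, deletion 3 per base), read-level
filtering on aligned length fraction and identity, a fragment-aware pileup
(paired mates count once per covered position, first mate wins in the
overlap), variant filtering on coverage/count/frequency, and finally
re-indexing to PAM-relative coordinates to produce the per-position mutation
spectrum, the per-read indel frequency, and the substitution:indel ratio —
the standard purity measure for a base editor.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _align
from ._seq import DnaInputError, clean_dna, revcomp

logger = logging.getLogger(__name__)

_OP_CHAR = {_align.OP_M: "M", _align.OP_I: "I", _align.OP_D: "D"}
_OP_CODE = {v: k for k, v in _OP_CHAR.items()}

_READ_ENC = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))
_REF_ENC = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 5]))  # ref N matches nothing

_MATE_RE = re.compile(r"(.*?)(?:/([12])| ([12])(?::\S*)?)?$")

DEFAULT_WINDOW = (-22, -1)


@dataclass(frozen=True)
class AlignmentParams:
    """Edit costs and read-level filter fractions for amplicon mapping."""

    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    length_fraction: float = 0.5
    similarity_fraction: float = 0.8

    def __post_init__(self) -> None:
        if min(self.mismatch_cost, self.insertion_cost, self.deletion_cost) <= 0:
            raise ValueError("alignment costs must be positive")
        for f in (self.length_fraction, self.similarity_fraction):
            if not 0.0 < f <= 1.0:
                raise ValueError("filter fractions must lie in (0, 1]")


@dataclass(frozen=True)
class VariantFilter:
    """Coverage / count / frequency gates for reporting a variant."""

    min_coverage: int = 10
    min_count: int = 2
    min_frequency_percent: float = 0.5

    def __post_init__(self) -> None:
        if self.min_coverage < 0 or self.min_count < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_frequency_percent <= 100.0:
            raise ValueError("min_frequency_percent must lie in [0, 100]")


@dataclass(frozen=True, slots=True)
class AmpliconAlignment:
    """One read's semi-global alignment to the amplicon reference.

    ``ops`` is a run-length op list (op in M/I/D, length); M covers both
    matches and mismatches. ``aligned_fraction`` is the fraction of read
    bases in M columns; ``identity`` is matches over all alignment columns.
    """

    read_id: str
    read: str
    ref_start: int
    ops: tuple[tuple[str, int], ...]
    cost: int
    n_match: int
    aligned_fraction: float
    identity: float
    passed_filters: bool
    reverse_complemented: bool = False

    @property
    def has_indel(self) -> bool:
        return any(op in "ID" for op, _ in self.ops)

    @property
    def ref_span(self) -> int:
        return sum(ln for op, ln in self.ops if op in "MD")


def _rle(op_codes: np.ndarray) -> tuple[tuple[str, int], ...]:
    out: list[tuple[str, int]] = []
    for code in op_codes:
        ch = _OP_CHAR[int(code)]
        if out and out[-1][0] == ch:
            out[-1] = (ch, out[-1][1] + 1)
        else:
            out.append((ch, 1))
    return tuple(out)


def _encode(seq: str, table: bytes) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii").translate(table), dtype=np.uint8)


def align_read(
    read: str,
    ref: str,
    params: AlignmentParams | None = None,
    read_id: str = "read",
) -> AmpliconAlignment:
    """Minimum-cost semi-global alignment of one read against ``ref``.

    The read aligns end-to-end; the reference contributes a free internal
    span (no penalty for unaligned reference ends). Cost = mismatch_cost per
    mismatch + insertion_cost per inserted base + deletion_cost per deleted
    base. Ties prefer a mismatch over a gap, then deletions, from the
    leftmost minimum-cost end column — fully deterministic.
    """
    params = params or AlignmentParams()
    if not read or not ref:
        raise DnaInputError("read and reference must be non-empty")
    r = clean_dna(read)
    cost, ref_start, n_steps, op_codes, n_match = _align.dp_align(
        _encode(r, _READ_ENC),
        _encode(clean_dna(ref), _REF_ENC),
        params.mismatch_cost,
        params.insertion_cost,
        params.deletion_cost,
    )
    ops = _rle(op_codes[:n_steps])
    n_m = sum(ln for op, ln in ops if op == "M")
    n_cols = sum(ln for _, ln in ops)
    aligned_fraction = n_m / len(r)
    identity = n_match / n_cols if n_cols else 0.0
    passed = (
        aligned_fraction >= params.length_fraction
        and identity >= params.similarity_fraction
    )
    return AmpliconAlignment(
        read_id=read_id,
        read=r,
        ref_start=int(ref_start),
        ops=ops,
        cost=int(cost),
        n_match=int(n_match),
        aligned_fraction=aligned_fraction,
        identity=identity,
        passed_filters=passed,
    )


def align_reads(
    reads: Iterable[tuple[str, str]],
    ref: str,
    params: AlignmentParams | None = None,
) -> list[AmpliconAlignment]:
    """Align many (read_id, sequence) pairs to one reference.

    Each read is aligned in both orientations and the cheaper alignment kept
    (ties keep the given orientation); reverse-strand mates are stored in
    reference orientation with ``reverse_complemented=True``. Amplicon read
    sets are highly redundant, so alignments are memoized on the read
    sequence (alignment is a pure function of read and reference).
    """
    params = params or AlignmentParams()
    cache: dict[str, AmpliconAlignment] = {}
    out: list[AmpliconAlignment] = []
    for rid, seq in reads:
        seq = seq.upper()
        hit = cache.get(seq)
        if hit is None:
            fwd = align_read(seq, ref, params, read_id=rid)
            hit = fwd
            if fwd.cost > 0:
                rc = align_read(revcomp(seq), ref, params, read_id=rid)
                if rc.cost < fwd.cost:
                    hit = _replace_alignment(rc, rid, reverse_complemented=True)
            cache[seq] = hit
        if hit.read_id != rid:
            hit = _replace_alignment(hit, rid, hit.reverse_complemented)
        out.append(hit)
    return out


def _replace_alignment(
    a: AmpliconAlignment, rid: str, reverse_complemented: bool
) -> AmpliconAlignment:
    return AmpliconAlignment(
        read_id=rid,
        read=a.read,
        ref_start=a.ref_start,
        ops=a.ops,
        cost=a.cost,
        n_match=a.n_match,
        aligned_fraction=a.aligned_fraction,
        identity=a.identity,
        passed_filters=a.passed_filters,
        reverse_complemented=reverse_complemented,
    )


def _fragment_key(read_id: str) -> tuple[str, int]:
    """Fragment id and mate rank (0 wins overlaps) from a read name."""
    m = _MATE_RE.match(read_id)
    if m and (m.group(2) or m.group(3)):
        mate = int(m.group(2) or m.group(3))
        return m.group(1), 0 if mate == 1 else 1
    return read_id, 0


@dataclass
class PileupTable:
    """Per-position observation counts and the filtered variant calls.

    ``counts`` is indexed by 0-based reference position with columns
    A/C/G/T/del plus ref_base and coverage (all classes sum to coverage).
    ``variants`` lists every non-reference observation with its frequency
    and a ``reported`` flag applying the coverage/count/frequency gates;
    sub-threshold rows are retained with ``reported=False``.
    """

    ref: str
    counts: pd.DataFrame
    variants: pd.DataFrame
    n_fragments_passing: int
    n_fragments_with_indel: int
    filter: VariantFilter = field(default_factory=VariantFilter)


def pileup_and_filter(
    alignments: Sequence[AmpliconAlignment],
    ref: str,
    vfilter: VariantFilter | None = None,
    indel_window: tuple[int, int] | None = None,
) -> PileupTable:
    """Tabulate per-position base/deletion counts from passing reads.

    Paired mates (read ids ending ``/1``/``/2`` or ``name 1``/``name 2``)
    are merged so each sequenced fragment contributes once per covered
    position; mate 1 wins where both cover. A fragment counts as
    indel-containing when any of its passing mates has an insertion or
    deletion op overlapping ``indel_window`` (default: whole reference).
    """
    vfilter = vfilter or VariantFilter()
    ref = clean_dna(ref)
    n = len(ref)
    w0, w1 = indel_window if indel_window is not None else (0, n)

    passing = [a for a in alignments if a.passed_filters]
    frag_of: dict[str, int] = {}
    mates: list[tuple[int, int, AmpliconAlignment]] = []
    for a in passing:
        fid, rank = _fragment_key(a.read_id)
        f = frag_of.setdefault(fid, len(frag_of))
        mates.append((f, rank, a))
    nf = len(frag_of)
    counts = np.zeros((n, 5), dtype=np.int64)
    frag_indel = np.zeros(nf, dtype=np.bool_)

    if not mates:
        logger.warning("no reads passed the alignment filters; empty pileup")
    else:
        mates.sort(key=lambda t: (t[0], t[1]))
        nm = len(mates)
        mate_frag = np.empty(nm, dtype=np.int64)
        mate_start = np.empty(nm, dtype=np.int64)
        read_off = np.zeros(nm + 1, dtype=np.int64)
        ops_off = np.zeros(nm + 1, dtype=np.int64)
        read_chunks: list[np.ndarray] = []
        ops_chunks: list[int] = []
        for k, (f, _rank, a) in enumerate(mates):
            mate_frag[k] = f
            mate_start[k] = a.ref_start
            codes = _encode(a.read, _READ_ENC)
            read_chunks.append(codes)
            read_off[k + 1] = read_off[k] + codes.shape[0]
            ops_off[k + 1] = ops_off[k] + len(a.ops)
            for op, ln in a.ops:
                ops_chunks.append(_OP_CODE[op])
                ops_chunks.append(ln)
        read_flat = np.concatenate(read_chunks)
        ops_flat = np.asarray(ops_chunks, dtype=np.int64)
        _align.accumulate_pileup(
            n, mate_frag, mate_start, read_flat, read_off,
            ops_flat, ops_off, counts, frag_indel, w0, w1,
        )

    count_df = pd.DataFrame(
        counts, columns=["A", "C", "G", "T", "del"],
        index=pd.RangeIndex(n, name="pos"),
    )
    count_df.insert(0, "ref_base", list(ref))
    count_df["coverage"] = counts.sum(axis=1)

    rows = []
    for pos in range(n):
        cov = int(count_df.at[pos, "coverage"])
        for alt in ("A", "C", "G", "T", "del"):
            if alt == ref[pos]:
                continue
            cnt = int(count_df.at[pos, alt])
            if cnt == 0:
                continue
            freq = 100.0 * cnt / cov if cov else 0.0
            rows.append(
                {
                    "pos": pos,
                    "ref": ref[pos],
                    "alt": alt,
                    "count": cnt,
                    "coverage": cov,
                    "frequency_percent": freq,
                    "reported": (
                        cov >= vfilter.min_coverage
                        and cnt >= vfilter.min_count
                        and freq >= vfilter.min_frequency_percent
                    ),
                }
            )
    variants = pd.DataFrame(
        rows,
        columns=["pos", "ref", "alt", "count", "coverage",
                 "frequency_percent", "reported"],
    )
    return PileupTable(
        ref=ref,
        counts=count_df,
        variants=variants,
        n_fragments_passing=nf,
        n_fragments_with_indel=int(frag_indel.sum()),
        filter=vfilter,
    )


@dataclass
class MutationSpectrum:
    """PAM-relative per-position mutation frequencies for one locus.

    ``table`` is indexed by PAM-relative position (−1 immediately 5' of the
    PAM) with the reference base, coverage, percent frequency of each
    substitution class and of deletion. ``indel_frequency_percent`` is the
    fraction of passing fragments whose alignment contains at least one
    insertion or deletion op.
    """

    locus_id: str
    table: pd.DataFrame
    indel_frequency_percent: float
    n_reads_passing: int

    def freq(self, pam_relative_pos: int, alt: str) -> float:
        """Percent frequency of ``alt`` ('A'/'C'/'G'/'T'/'del') at a position."""
        return float(self.table.at[pam_relative_pos, alt])


def spectrum(
    pileup: PileupTable,
    pam_start: int,
    window: tuple[int, int] = DEFAULT_WINDOW,
    locus_id: str = "",
) -> MutationSpectrum:
    """Re-index a pileup to PAM-relative coordinates.

    ``pam_start`` is the 0-based reference index of the PAM's first base on
    the PAM-bearing strand (the reference orientation); PAM-relative
    position p maps to reference index ``pam_start + p``.
    """
    lo, hi = min(window), max(window)
    n = len(pileup.ref)
    if pam_start + lo < 0 or pam_start + hi >= n:
        raise IndexError(
            f"window {lo}..{hi} around pam_start={pam_start} exceeds the amplicon"
        )
    rows = []
    for p in range(lo, hi + 1):
        idx = pam_start + p
        cov = int(pileup.counts.at[idx, "coverage"])
        row = {"pam_relative_pos": p, "ref_base": pileup.ref[idx], "coverage": cov}
        for alt in ("A", "C", "G", "T", "del"):
            if alt == pileup.ref[idx]:
                row[alt] = 0.0
            else:
                row[alt] = 100.0 * int(pileup.counts.at[idx, alt]) / cov if cov else 0.0
        rows.append(row)
    table = pd.DataFrame(rows).set_index("pam_relative_pos")
    nf = pileup.n_fragments_passing
    indel_pct = 100.0 * pileup.n_fragments_with_indel / nf if nf else 0.0
    return MutationSpectrum(
        locus_id=locus_id,
        table=table,
        indel_frequency_percent=indel_pct,
        n_reads_passing=nf,
    )


def substitution_indel_ratio(
    spec: MutationSpectrum, target_positions: Sequence[int]
) -> float:
    """Targeted C>T frequency summed over ``target_positions``, divided by
    the indel frequency — the editing-purity ratio. Infinite when no indels
    were observed. Rounded to 2 decimals, as reported.
    """
    num = sum(spec.freq(p, "T") for p in target_positions)
    return ratio_from_frequencies(num, spec.indel_frequency_percent)


def ratio_from_frequencies(sub_percent: float, indel_percent: float) -> float:
    """Substitution:indel ratio from already-computed percent frequencies."""
    if indel_percent == 0:
        logger.warning("zero indel frequency: substitution:indel ratio is infinite")
        return math.inf
    return round(sub_percent / indel_percent, 2)


def orient_reference(ref: str, pam_start: int, strand: str) -> tuple[str, int]:
    """Return (reference, pam_start) on the PAM-bearing strand.

    ``strand`` '+' leaves the input untouched; '-' means the PAM reads on
    the reverse complement at the given leftmost index, so the reference is
    flipped and the coordinate remapped.
    """
    if strand == "+":
        return clean_dna(ref), pam_start
    if strand == "-":
        r = clean_dna(ref)
        return revcomp(r), len(r) - pam_start - 3
    raise ValueError("strand must be '+' or '-'")


def run_spectrum_pipeline(
    reads: Iterable[tuple[str, str]],
    ref: str,
    pam_start: int,
    strand: str = "+",
    params: AlignmentParams | None = None,
    vfilter: VariantFilter | None = None,
    window: tuple[int, int] = DEFAULT_WINDOW,
    indel_window: tuple[int, int] | None = None,
    locus_id: str = "",
) -> MutationSpectrum:
    """Align reads, pile up, filter and tabulate in one call."""
    oref, opam = orient_reference(ref, pam_start, strand)
    alns = align_reads(reads, oref, params)
    pile = pileup_and_filter(alns, oref, vfilter, indel_window)
    return spectrum(pile, opam, window, locus_id=locus_id)
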