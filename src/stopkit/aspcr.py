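"""Allele-specific PCR (ARMS) genotyping design for single-nucleotide edits.

A wild-type and a mutant allele-specific primer differ only in their
3'-terminal base, which sits exactly on the variant; a second, engineered
mismatch two bases in from the 3' end destabilizes extension from the wrong
allele and sharpens discrimination. A shared opposite primer closes the
allele-specific amplicon, and an internal-control pair 800-1400 bp
downstream of the variant guards against amplification failure. Designs are
verified by in-silico PCR that tolerates internal mismatches but rejects any
3'-terminal mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import clean_dna, complement_base, revcomp

FORWARD = "forward"
REVERSE = "reverse"

#: Engineered mismatch position, counted from the 3' end (0 = terminal base).
ENGINEERED_MISMATCH_OFFSET = 2

CONTROL_MIN_DOWNSTREAM = 800
CONTROL_MAX_DOWNSTREAM = 1400


class DesignBoundaryError(ValueError):
    """The variant sits too close to a sequence end for the requested design."""


def wallace_tm(primer: str) -> float:
    """Wallace-rule melting temperature: 2 degC per A/T, 4 degC per G/C."""
    return 2.0 * (primer.count("A") + primer.count("T")) + 4.0 * (
        primer.count("G") + primer.count("C")
    )


@dataclass(frozen=True)
class AsPcrPrimerSet:
    """Primers genotyping one SNV by allele-specific 3' termini.

    ``wild_primer`` and ``mut_primer`` are identical apart from the
    3'-terminal base (reference vs alternate allele on the primer's strand)
    and both carry the same engineered mismatch at
    ``engineered_mismatch_offset`` bases from the 3' end. ``control_pair``
    is None when the reference is too short to host the downstream internal
    control.
    """

    snv: tuple[int, str, str]
    wild_primer: str
    mut_primer: str
    shared_primer: str
    orientation: str
    engineered_mismatch_offset: int
    engineered_mismatch_base: str
    control_pair: tuple[str, str] | None
    product_len: int
    control_product_len: int | None

    @property
    def wild_tm(self) -> float:
        return wallace_tm(self.wild_primer)

    @property
    def mut_tm(self) -> float:
        return wallace_tm(self.mut_primer)


def _engineered_base(normal_base: str) -> str:
    """Pick the engineered-mismatch base on the primer strand.

    The primer base normally complements the template. Prefer T (giving a
    pyrimidine/pyrimidine or T/T clash, as in published ARMS designs); when
    the normal base is already T the template is A, so use A for a
    purine/purine clash — the strongest destabilization class.
    """
    return "T" if normal_base != "T" else "A"


def design_as_primers(
    ref: str,
    snv: tuple[int, str, str],
    primer_len: int = 20,
    orientation: str = FORWARD,
    product_len_target: int = 200,
    control_product_len_target: int = 200,
    strict_control: bool = False,
) -> AsPcrPrimerSet:
    """Design wild/mutant allele-specific primers plus shared and control pairs.

    ``snv`` is (0-based reference index, ref base, alt base); the ref base
    must match the reference. With ``orientation='forward'`` the
    allele-specific primers read the sense strand and end on the variant
    base itself; with ``'reverse'`` they read the antisense strand, so a C>T
    variant yields wild/mutant 3' termini G and A. The internal-control
    amplicon starts 800 bp downstream of the variant; if the reference
    cannot host it the control pair is omitted (or an error raised when
    ``strict_control``).
    """
    r = clean_dna(ref, allow_n=False)
    idx, ref_base, alt_base = snv
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if not 0 <= idx < len(r):
        raise DesignBoundaryError("SNV index outside reference")
    if r[idx] != ref_base:
        raise ValueError(
            f"SNV ref base {ref_base} does not match reference base {r[idx]} at {idx}"
        )
    if orientation not in (FORWARD, REVERSE):
        raise ValueError("orientation must be 'forward' or 'reverse'")
    if primer_len < 15:
        raise ValueError("primer_len must be at least 15")

    if orientation == FORWARD:
        start = idx - primer_len + 1
        if start < 0:
            raise DesignBoundaryError("SNV too close to the 5' end for primer_len")
        core = r[start : idx + 1]
        wild, mut = core[:-1] + ref_base, core[:-1] + alt_base
        # engineered mismatch: primer-strand base at offset 2 from the 3' end
        epos = primer_len - 1 - ENGINEERED_MISMATCH_OFFSET
        ebase = _engineered_base(wild[epos])
        wild = wild[:epos] + ebase + wild[epos + 1 :]
        mut = mut[:epos] + ebase + mut[epos + 1 :]
        # shared reverse primer closing a product near product_len_target
        prod_end = min(start + product_len_target, len(r))
        if prod_end - primer_len <= idx:
            raise DesignBoundaryError("no room for the shared primer downstream")
        shared = revcomp(r[prod_end - primer_len : prod_end])
        product_len = prod_end - start
    else:
        end = idx + primer_len
        if end > len(r):
            raise DesignBoundaryError("SNV too close to the 3' end for primer_len")
        core = revcomp(r[idx:end])
        wild = core[:-1] + complement_base(ref_base)
        mut = core[:-1] + complement_base(alt_base)
        epos = primer_len - 1 - ENGINEERED_MISMATCH_OFFSET
        ebase = _engineered_base(wild[epos])
        wild = wild[:epos] + ebase + wild[epos + 1 :]
        mut = mut[:epos] + ebase + mut[epos + 1 :]
        prod_start = max(end - product_len_target, 0)
        if prod_start + primer_len > idx:
            raise DesignBoundaryError("no room for the shared primer upstream")
        shared = r[prod_start : prod_start + primer_len]
        product_len = end - prod_start

    control_pair = None
    control_product_len = None
    ctrl_start = idx + CONTROL_MIN_DOWNSTREAM
    ctrl_end = ctrl_start + control_product_len_target
    if ctrl_end <= len(r) and ctrl_start - idx <= CONTROL_MAX_DOWNSTREAM:
        control_pair = (
            r[ctrl_start : ctrl_start + primer_len],
            revcomp(r[ctrl_end - primer_len : ctrl_end]),
        )
        control_product_len = ctrl_end - ctrl_start
    elif strict_control:
        raise DesignBoundaryError(
            "reference too short for an internal control 800-1400 bp downstream"
        )

    return AsPcrPrimerSet(
        snv=(idx, ref_base, alt_base),
        wild_primer=wild,
        mut_primer=mut,
        shared_primer=shared,
        orientation=orientation,
        engineered_mismatch_offset=ENGINEERED_MISMATCH_OFFSET,
        engineered_mismatch_base=ebase,
        control_pair=control_pair,
        product_len=product_len,
        control_product_len=control_product_len,
    )


def _binding_sites(
    template: str, primer: str, max_internal_mismatches: int
) -> list[int]:
    """Start indices where ``primer`` anneals to ``template`` (same strand,
    5'->3'), allowing internal mismatches but none at the 3'-terminal base."""
    L = len(primer)
    sites = []
    for i in range(len(template) - L + 1):
        seg = template[i : i + L]
        if seg[-1] != primer[-1]:
            continue
        mm = sum(1 for a, b in zip(seg, primer) if a != b)
        if mm <= max_internal_mismatches:
            sites.append(i)
    return sites


def in_silico_pcr(
    ref: str,
    fwd: str,
    rev: str,
    max_internal_mismatches: int = 3,
    max_product_len: int = 5000,
) -> list[int]:
    """Product lengths from all convergent binding-site pairs.

    A primer binds where it matches the template with at most
    ``max_internal_mismatches`` internal mismatches and an exactly matching
    3'-terminal base — the rule that makes allele-specific primers silent on
    the wrong allele while their engineered internal mismatch is tolerated.
    """
    r = clean_dna(ref, allow_n=False)
    fwd = clean_dna(fwd, allow_n=False)
    rev = clean_dna(rev, allow_n=False)
    if min(len(fwd), len(rev)) < 15:
        raise ValueError("primers must be at least 15 nt")
    fwd_sites = _binding_sites(r, fwd, max_internal_mismatches)
    # reverse primer anneals to the sense strand: its revcomp appears in r,
    # with the primer's 3' end at the left edge of the match
    rc = revcomp(rev)
    rev_sites = _binding_sites_rc(r, rc, max_internal_mismatches)
    products = []
    for i in fwd_sites:
        for j in rev_sites:
            plen = (j + len(rev)) - i
            if plen >= len(fwd) and j >= i and plen <= max_product_len:
                products.append(plen)
    return sorted(products)


def _binding_sites_rc(
    template: str, primer_rc: str, max_internal_mismatches: int
) -> list[int]:
    """Sites of a reverse primer given as its reverse complement; the
    primer's 3'-terminal base corresponds to the first base of the match."""
    L = len(primer_rc)
    sites = []
    for i in range(len(template) - L + 1):
        seg = template[i : i + L]
        if seg[0] != primer_rc[0]:
            continue
        mm = sum(1 for a, b in zip(seg, primer_rc) if a != b)
        if mm <= max_internal_mismatches:
            sites.append(i)
    return sites
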