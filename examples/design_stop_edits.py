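"""Find cytosines whose C>T conversion nonsense-mutates a small ORF.

Builds a toy coding record with one editable CAA codon placed 19 bases
upstream of an NGG PAM, scans it, and prints the resulting design.
"""

from stopkit import CodingSequence, enumerate_stop_edits

record = "ATGCAA" + "A" * 16 + "TGG"  # CAA codon; its C sits at -19 from the PAM
cds = CodingSequence("toy_orf", record, cds_start=0, cds_end=24)

for cand in enumerate_stop_edits(cds):
    print(
        f"c.{cand.cds_c_number}C>T ({cand.strand}) at PAM-relative "
        f"{cand.pam_relative_pos}: codon {cand.codon_before}->{cand.codon_after}, "
        f"expected efficiency {cand.score:.0f}%"
    )
    print(f"  spacer (18 nt, 5'->3' on PAM strand): {cand.spacer_seq}")
    print(f"  bystander window cytosines: {list(cand.other_window_cytosines) or 'none'}")

# Prints one candidate: c.4C>T converting CAA->TAA (a premature stop) at
# window position -19, where the deaminase edits at roughly 25% efficiency.
# Note the target C lies just outside the 18-nt spacer -- by design, the
# editing window reaches past the spacer's 5' end.
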