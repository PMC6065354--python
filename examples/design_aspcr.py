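"""Design allele-specific PCR primers for a C>T edit and verify in silico.

The wild/mutant primers end exactly on the variant base and share one
engineered destabilizing mismatch two bases from the 3' end; in-silico PCR
(zero 3'-terminal mismatches allowed) confirms each primer amplifies only
its own allele.
"""

import numpy as np

from stopkit import design_as_primers, in_silico_pcr

rng = np.random.default_rng(4)
ref = "".join(rng.choice(list("ACGT"), 400))
idx = 200
ref = ref[:idx] + "C" + ref[idx + 1 :]          # wild allele
edited = ref[:idx] + "T" + ref[idx + 1 :]        # edited allele

ps = design_as_primers(ref, (idx, "C", "T"), primer_len=20,
                       orientation="forward", product_len_target=200)
print(f"wild primer : 5'-{ps.wild_primer}-3'  (Tm {ps.wild_tm:.0f} C)")
print(f"mut primer  : 5'-{ps.mut_primer}-3'  (Tm {ps.mut_tm:.0f} C)")
print(f"engineered mismatch: {ps.engineered_mismatch_base} at offset "
      f"{ps.engineered_mismatch_offset} from the 3' end")

for template, name in [(ref, "wild template"), (edited, "edited template")]:
    w = in_silico_pcr(template, ps.wild_primer, ps.shared_primer)
    m = in_silico_pcr(template, ps.mut_primer, ps.shared_primer)
    print(f"{name}: wild-primer products {w}, mut-primer products {m}")

# Each allele-specific primer yields a single product (the designed length)
# on its matching template and nothing on the other -- the 3'-terminal base
# on the variant plus the extra near-terminal mismatch gives the
# discrimination.
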