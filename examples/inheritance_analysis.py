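"""Simulate founder->F1->F2 inheritance and run the analysis stack.

A mosaic founder whose germline carries an edited allele at 30% is
outcrossed; F1 heterozygotes are intercrossed; the pipeline tallies
genotypes, summarises germline transmission, and chi-square-tests the F2
affected fraction against the 25% recessive expectation.
"""

from stopkit import (
    CrossSimConfig,
    segregation_test,
    simulate_cross,
    tally,
    transmission_rate,
)

cfg = CrossSimConfig(
    founder_germline_allele_freqs={"c.232C>T": 0.3, "wild": 0.7},
    n_f1=34,
    f1_intercross_pairs=("c.232C>T",),
    n_f2_per_pair=215,
    seed=11,
)
f1, f2 = simulate_cross(cfg)

f1_tally = tally(list(f1["genotype_class"]), founder_id=cfg.founder_id)
print("F1 genotype frequencies (%):", f1_tally.frequencies)

summary = transmission_rate([f1_tally])
print(f"transmitting founders: {summary.n_transmitting}/{summary.n_founders}")

affected = int((f2["genotype_class"] == "c.232C>T hom").sum())
st = segregation_test(affected, len(f2), expected_fraction=0.25)
print(f"F2 homozygotes: {affected}/{len(f2)} = {st.observed_fraction_percent}%")
print(f"chi-square vs 25% expectation: {st.chi_square:.3f} (p = {st.p_value:.2f})")
print("consistent with recessive Mendelian inheritance" if st.consistent
      else "deviates from the 25% recessive expectation")

# The F1 heterozygote fraction estimates the founder's germline mosaicism
# (30% here); the F2 homozygote fraction scatters binomially around 25%,
# and the 1-df chi-square quantifies the fit to recessive inheritance.
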