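"""Simulate an edited amplicon read set and recover its mutation spectrum.

20,000 paired 151-bp read pairs over a 250-nt amplicon with the targeted
C>T at PAM-relative -19 at 2.19% and per-molecule indels at 0.91% -- then
the full pipeline: alignment, filtering, pileup, PAM-relative spectrum, and
the substitution:indel purity ratio.
"""

from stopkit import (
    ReadSimConfig,
    make_amplicon,
    run_spectrum_pipeline,
    simulate_reads,
    substitution_indel_ratio,
)

ref = make_amplicon(length=250, pam_start=200, target_pos=-19, seed=20)
cfg = ReadSimConfig(
    ref=ref, pam_start=200,
    per_position_sub_rates={(-19, "T"): 0.0219},
    indel_rate=0.0091, seq_error_rate=0.001,
    n_reads=20_000, seed=1,
)
reads, truth = simulate_reads(cfg)
spec = run_spectrum_pipeline(reads, ref, pam_start=200, locus_id="demo")

print(f"passing read pairs: {spec.n_reads_passing}")
print(f"C>T at -19: {spec.freq(-19, 'T'):.2f}%  (simulated at 2.19%)")
print(f"indel frequency: {spec.indel_frequency_percent:.2f}%  (simulated at 0.91%)")
print(f"substitution:indel ratio: {substitution_indel_ratio(spec, [-19])}")

# The estimates track the generative rates to within binomial sampling
# noise (plus ~0.03% background from the 0.1% per-base sequencing error);
# the ratio near 2.4 is the purity signature of a deaminase editor that
# substitutes far more often than it cuts.
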