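# Methods

This note records the models, conventions and parameter choices behind
stopkit, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and conventions

All sequence coordinates are 0-based, half-open. Coding positions are
reported 1-based as "c." numbers (c.232 = 232nd coding base). PAM-relative
position −1 is the base immediately 5′ of the PAM's first base on the
PAM-bearing strand; the editing window and the mutation-spectrum axis are
negative positions on this scale. For antisense PAM hits, `pam_start` is the
leftmost record index the PAM occupies, and the motif reads on the reverse
complement; window position −k then maps to record index `pam_start + 2 + k`.

## Stop-codon design

A candidate is any cytosine on the PAM-bearing strand inside the editing
window (default −20..−16) whose C>T conversion turns its codon into
TAA/TAG/TGA. On the sense strand the genetic code forces the precursor
codons CAA/CAG/CGA with the C at codon position 1; antisense candidates are
G>A changes on the coding strand, forcing the precursor TGG (Trp) with the
edit at codon position 2 or 3. Codons that are already stops are excluded —
the design goal is a *new* premature stop. Antisense candidates are
enumerated by default (a `sense_only` flag restricts to the sense-strand
procedure); each PAM generates independent candidates, so one C reachable
from two PAMs is reported twice with its two scores — no deduplication,
because the two designs are distinct sgRNAs.

Scoring uses a fixed position-efficiency profile: {−20: 5, −19: 25,
−18: 45, −17: 35, −16: 5} percent, the deamination-rate profile measured
for nCas9–PmCDA1; positions outside the profile (including −21/−22) score
0. The score is a pure lookup on `pam_relative_pos`. Spacers default to
18 nt immediately 5′ of the PAM; a target at −19/−20 legitimately lies
outside the spacer, since the deaminase window extends past its 5′ end.
Windows or codons containing N are skipped and counted in the log; bystander
window cytosines are reported (positions only), never filtered, and no
consequence annotation is attempted for them.

## Off-target enumeration

Candidate off-target sites are found by exhaustive scanning of both strands
of every subject for PAM matches (IUPAC-aware; NGG, optionally NAG) whose
adjacent protospacer-length site is within a Hamming-distance budget
(default 4) of the spacer. No DNA/RNA bulges are modeled — mismatch counting
only. Output order is deterministic: ascending mismatch count, then a
PAM-proximity penalty (sum of 1/distance over mismatch positions, so sites
whose mismatches crowd the seed region next to the PAM rank later — the
standard seed-region heuristic, stated explicitly so rankings are
reproducible), then subject and coordinate. No external off-target scoring
formula is reproduced. The scanner is intended for amplicon/contig-scale
subjects; there is no genome-scale index.

## Amplicon alignment and spectrum

Reads are aligned by minimum-cost semi-global dynamic programming: the read
aligns end-to-end, reference ends are free. Cost = 2·mismatches +
3·inserted bases + 3·deleted bases. Ties are resolved deterministically:
the minimum-cost end column with the smallest reference coordinate, and in
traceback match/mismatch is preferred over a gap, then deletion over
insertion — so a single substitution is always called as a mismatch (cost
2), never as a gap pair (cost ≥ 6). Each read is tried in both orientations
and the cheaper kept, which is how reverse-strand mates map. A read passes
when its aligned fraction (read bases in match/mismatch columns ÷ read
length) ≥ 0.5 and identity (matching columns ÷ all alignment columns)
≥ 0.8. The DP and the pileup accumulation are numba-compiled; alignments
are memoized on the read sequence, which amplicon data rewards heavily.

Pileups are fragment-aware: mates sharing a fragment id (`/1`/`/2`
suffixes) contribute at most one observation per covered position, with
mate 1 winning disagreements in the overlap (reads carry no base
qualities — quality strings are constant — so a fixed precedence is the
deterministic choice). At every position, counts of A/C/G/T/deletion sum
exactly to coverage. A variant (position, alt) is *reported* only when
coverage ≥ 10, count ≥ 2 and frequency ≥ 0.5 %; sub-threshold observations
stay in the raw counts flagged unreported, which makes the filter gates
auditable and monotone (loosening any threshold can only add reported
variants).

The spectrum re-indexes reference positions to the PAM-relative −22..−1
axis and reports percent frequencies (2 decimals in written outputs). An
"indel-containing read" is a passing fragment whose alignment has ≥ 1
insertion or deletion op anywhere in the amplicon by default; a restriction
window is available but off, since indel localization conventions vary. The
substitution:indel ratio divides the summed targeted C>T frequencies by the
indel frequency, rounded to 2 decimals; a zero indel frequency yields
infinity with a logged warning. Because `target_positions` is explicit,
either single-position or multi-position numerator conventions can be
computed; published multi-target ratios whose exact numerator convention is
not derivable from the printed per-position frequencies (e.g. a two-C locus
ratio printed as 0.97 where the single positions give 0.89) are therefore
out of scope as fixed expected values.

## Allele-specific PCR design

The wild/mutant primers place their 3′-terminal base exactly on the variant
(forward orientation: the base itself; reverse orientation: its complement,
so a C>T edit reads G/A). One engineered mismatch is added at offset 2 from
the 3′ end (offset 0 = terminal): the primer base is switched to T when the
normal base is not T (giving a pyrimidine/pyrimidine or T/T clash against
the template), else to A (purine/purine clash against the template A) —
preferring the strongest destabilization classes. All other primer bases
match the reference, which the tests verify by direct string comparison.
Melting temperatures use the Wallace rule (2 °C per A/T, 4 °C per G/C);
wild and mutant primers differ by one base and hence by ≤ 2 °C.
Nearest-neighbor thermodynamics, primer-dimer and secondary-structure
checks are out of scope.

In-silico PCR finds binding sites allowing internal mismatches (default
≤ 3, which tolerates the engineered mismatch) but zero 3′-terminal
mismatch — the mechanism of ARMS discrimination — and reports product
lengths of convergent pairs under a size cap. The internal-control pair
amplifies a region starting 800 bp downstream of the variant; references
too short to host it get `control_pair=None` (or an error under
`strict_control`). Published product sizes for specific loci depend on
unpublished primer placements and are not reproduced; designs target
user-specified product lengths.

## Inheritance

Tallies are exact counts with frequencies rounded to 1 decimal. The
segregation test is the textbook 1-df chi-square of (affected, unaffected)
against (f, 1−f)·n, f defaulting to 0.25; Yates continuity correction is
available but off by default, and p-values (from the chi-square survival
function) are informational. A founder transmits iff ≥ 1 non-wild offspring
class is observed; a founder with edited somatic genotype but all-wild
offspring is non-transmitting, which is exactly the germline-mosaicism
case.

## Synthetic data

The read simulator draws, per molecule: position-specific substitutions
(mutually exclusive alternates per position), an indel with per-molecule
probability (insertion/deletion 50:50, length 1 + geometric tail with
p = 0.7, placed uniformly in the protospacer ± 5 bases), then per-base
uniform sequencing error (default 0.1 %) on each read. Fragments span the
whole amplicon by default — in amplicon sequencing the sequenced fragment
*is* the PCR product, and this also makes the per-molecule indel rate
identifiable from reads (a short uniformly placed fragment may simply not
cover the indel); a `fragment_len_range` option restores uniformly placed
sub-fragments when shotgun-like coverage is wanted. Reads are paired 151 bp
from the fragment ends, qualities constant (Phred 30, "?") since the
pipeline ignores them, and every run is deterministic for a fixed
`numpy.random.default_rng` seed. A per-molecule truth table accompanies the
reads so estimated frequencies can be compared with the generative rates.

What the generator does *not* model: per-sample rate variation across
pooled embryos (a jitter hook is deliberately absent by default), PCR
duplicates and chimeras, quality-score error profiles, and polymorphic
backgrounds. Passing recovery tests therefore shows the pipeline is
unbiased under clean amplicon assumptions, not that it is robust to every
artifact of real libraries.

The cross simulator draws each F1 allele from the founder's germline allele
frequencies (outcross to wild type), and F2 genotypes from het×het Mendelian
sampling, with truth labels retained.

## Verification scale and headline run

The acceptance run simulates 200,000 paired 151-bp molecules over a 250-nt
amplicon (targeted C>T at −19 at 2.19 %, indels at 0.91 %, sequencing error
0.1 %) and requires the pipeline estimates to fall within three binomial
standard errors of the generative rates (≈ ±0.10 and ±0.064 percentage
points respectively); the sequencing-error contribution to the C>T class
(≈ +0.03 points) sits well inside that band. Unit-level recovery tests use
50,000 molecules at rates 0.5–5 %. Oracle-equivalence tests run the
alignment DP against an independent pure-Python dynamic program on ≥ 200
random instances, the design scan against an exhaustive C×PAM oracle on
random 300-nt coding sequences, the off-target scanner against a naive
position-by-position scan, and every ASPCR design against in-silico PCR on
both alleles (100 random instances).

## Known limitations

- Alignment gap placement follows the stated deterministic tie-break;
  equal-cost alignments (e.g. indels in repeats) may differ from other
  aligners' leftmost-gap conventions, though costs agree.
- The spectrum pools all reads; per-sample (per-embryo) spectra require
  running the pipeline per sample.
- The off-target scanner is quadratic-by-construction and not meant for
  whole genomes.
- In-silico PCR models primer specificity by mismatch counts only, not
  hybridization thermodynamics.
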