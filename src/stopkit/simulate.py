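"""Synthetic data generation: amplicon read sets and breeding-cross tables.

The read simulator emulates amplicon deep sequencing of a base-edited locus:
each simulated molecule independently receives position-specific
substitutions (e.g. the targeted C>T at a low percent rate), an optional
short indel near the protospacer, and uniform per-base sequencing error;
paired 151-bp reads are then taken from the fragment ends, as in real
amplicon sequencing where the sequenced fragment is the PCR product itself.
A truth table of the edits applied to every molecule is emitted alongside
the reads, so downstream estimates can be checked against the generative
rates.

The cross simulator draws F1 offspring from a mosaic founder's germline
allele frequencies (outcrossed to wild type) and F2 offspring from
heterozygote intercrosses under Mendelian segregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._seq import clean_dna

_COMP = str.maketrans("ACGTN", "TGCAN")

WILD = "wild"


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


class ConfigError(ValueError):
    """Simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class ReadSimConfig:
    """Generative model for one amplicon read set.

    ``per_position_sub_rates`` maps (PAM-relative position, alt base) to a
    per-molecule probability; alternates at one position are mutually
    exclusive. ``indel_rate`` is per molecule; indels are single-base with a
    geometric length tail and placed uniformly within the protospacer plus
    ``indel_margin`` bases each side. ``fragment_len_range`` of None means
    fragments span the whole amplicon (the PCR-product model); a (lo, hi)
    range instead draws uniformly placed fragments of uniform length.
    """

    ref: str
    pam_start: int
    per_position_sub_rates: dict[tuple[int, str], float] = field(default_factory=dict)
    indel_rate: float = 0.0
    indel_geom_p: float = 0.7
    seq_error_rate: float = 0.001
    read_len: int = 151
    paired: bool = True
    n_reads: int = 1000
    seed: int = 0
    spacer_len: int = 18
    indel_margin: int = 5
    fragment_len_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", clean_dna(self.ref, allow_n=False))
        if not 0 <= self.pam_start <= len(self.ref) - 3:
            raise ConfigError("pam_start outside reference")
        if self.read_len > len(self.ref):
            raise ConfigError("read_len exceeds reference length")
        for p in (self.indel_rate, self.seq_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        per_pos: dict[int, float] = {}
        for (pos, alt), rate in self.per_position_sub_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate for ({pos}, {alt}) outside [0, 1]")
            if alt not in "ACGT":
                raise ConfigError(f"alt base {alt!r} is not A/C/G/T")
            per_pos[pos] = per_pos.get(pos, 0.0) + rate
        for pos, total in per_pos.items():
            if total > 1.0:
                raise ConfigError(f"summed substitution rates at {pos} exceed 1")
            if not 0 <= self.pam_start + pos < len(self.ref):
                raise ConfigError(f"PAM-relative position {pos} outside reference")

    @property
    def indel_window(self) -> tuple[int, int]:
        """Reference interval (half-open) where simulated indels land."""
        lo = max(self.pam_start - self.spacer_len - self.indel_margin, 0)
        hi = min(self.pam_start + self.indel_margin, len(self.ref))
        return lo, hi


def simulate_reads(
    cfg: ReadSimConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate an amplicon read set with its per-molecule truth table.

    Returns ``(reads, truth)``: reads as (read_id, sequence) pairs, ids
    carrying ``/1``/``/2`` mate suffixes when paired; truth as one row per
    molecule recording every substitution applied (columns ``sub_<pos>><alt>``),
    the indel (kind, length, reference position) and the fragment placement.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reads
    ref = cfg.ref

    # Per-position substitution draws: one uniform per molecule per position,
    # partitioned by the cumulative alternate rates (mutual exclusivity).
    by_pos: dict[int, list[tuple[str, float]]] = {}
    for (pos, alt), rate in sorted(cfg.per_position_sub_rates.items()):
        by_pos.setdefault(pos, []).append((alt, rate))
    sub_choices: dict[int, np.ndarray] = {}  # pos -> alt index per molecule (-1 none)
    for pos, alts in by_pos.items():
        u = rng.random(n)
        choice = np.full(n, -1, dtype=np.int64)
        lo = 0.0
        for k, (_alt, rate) in enumerate(alts):
            choice[(u >= lo) & (u < lo + rate)] = k
            lo += rate
        sub_choices[pos] = choice

    has_indel = rng.random(n) < cfg.indel_rate
    indel_is_ins = rng.random(n) < 0.5
    indel_extra = rng.geometric(cfg.indel_geom_p, n) - 1
    w0, w1 = cfg.indel_window
    indel_pos = rng.integers(w0, w1, n)
    ins_bases = rng.integers(0, 4, (n, int(indel_extra.max()) + 1))

    if cfg.fragment_len_range is None:
        frag_len = np.full(n, len(ref), dtype=np.int64)
        frag_start = np.zeros(n, dtype=np.int64)
    else:
        flo, fhi = cfg.fragment_len_range
        if not cfg.read_len <= flo <= fhi <= len(ref):
            raise ConfigError("fragment_len_range must lie in [read_len, len(ref)]")
        frag_len = rng.integers(flo, fhi + 1, n)
        frag_start = (rng.random(n) * (len(ref) - frag_len + 1)).astype(np.int64)

    n_mates = 2 if cfg.paired else 1
    err_counts = rng.binomial(cfg.read_len, cfg.seq_error_rate, n * n_mates)

    bases = "ACGT"
    reads: list[tuple[str, str]] = []
    truth_rows = []
    mate_idx = 0
    for i in range(n):
        mol = ref
        row: dict[str, object] = {"fragment": f"frag{i:06d}"}
        for pos, alts in by_pos.items():
            k = int(sub_choices[pos][i])
            applied = k >= 0
            alt = alts[k][0] if applied else ""
            row[f"sub_{pos}>{alts[0][0] if not applied else alt}"] = applied
            if applied:
                j = cfg.pam_start + pos
                mol = mol[:j] + alt + mol[j + 1 :]
        ilen = 0
        kind = ""
        if has_indel[i]:
            ilen = 1 + int(indel_extra[i])
            j = int(indel_pos[i])
            if indel_is_ins[i]:
                kind = "ins"
                ins = "".join(bases[b] for b in ins_bases[i, :ilen])
                mol = mol[:j] + ins + mol[j:]
            else:
                kind = "del"
                mol = mol[:j] + mol[j + ilen :]
        row.update(
            indel=bool(has_indel[i]),
            indel_kind=kind,
            indel_len=ilen if kind else 0,
            indel_pos=int(indel_pos[i]) if kind else -1,
        )

        fl = min(int(frag_len[i]), len(mol))
        fs = min(int(frag_start[i]), len(mol) - fl)
        frag = mol[fs : fs + fl]
        row.update(frag_start=fs, frag_len=fl)
        truth_rows.append(row)

        r1 = frag[: cfg.read_len]
        mate_seqs = [r1]
        if cfg.paired:
            mate_seqs.append(_revcomp(frag)[: cfg.read_len])
        for m, seq in enumerate(mate_seqs, start=1):
            ne = int(err_counts[mate_idx])
            mate_idx += 1
            if ne:
                epos = rng.integers(0, len(seq), ne)
                shift = rng.integers(1, 4, ne)
                s = list(seq)
                for t in range(ne):
                    p = int(epos[t])
                    s[p] = bases[(bases.index(s[p]) + int(shift[t])) % 4]
                seq = "".join(s)
            rid = f"frag{i:06d}/{m}" if cfg.paired else f"frag{i:06d}"
            reads.append((rid, seq))

    # normalise truth substitution columns to one per configured (pos, alt)
    truth = pd.DataFrame(truth_rows)
    for (pos, alt), _rate in cfg.per_position_sub_rates.items():
        col = f"sub_{pos}>{alt}"
        if col not in truth.columns:
            truth[col] = False
        truth[col] = truth[col].astype(object).eq(True)  # NaN (row untouched) -> False
    return reads, truth


def truth_frequencies(cfg: ReadSimConfig, truth: pd.DataFrame) -> dict[str, float]:
    """Percent rates recomputed from a truth table (for consistency checks)."""
    out = {
        f"sub_{pos}>{alt}": 100.0 * truth[f"sub_{pos}>{alt}"].mean()
        for (pos, alt) in cfg.per_position_sub_rates
    }
    out["indel"] = 100.0 * truth["indel"].mean()
    return out


def make_amplicon(
    length: int = 250,
    pam_start: int = 200,
    target_pos: int = -19,
    seed: int = 20,
) -> str:
    """A deterministic synthetic amplicon with an editable target.

    Random sequence with an NGG PAM at ``pam_start`` and a C at the
    PAM-relative ``target_pos`` — the layout of a real base-editing
    amplicon, not any particular genomic locus.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = list("".join(rng.choice(bases, length)))
    seq[pam_start] = "A"
    seq[pam_start + 1] = "G"
    seq[pam_start + 2] = "G"
    seq[pam_start + target_pos] = "C"
    return "".join(seq)


@dataclass(frozen=True)
class CrossSimConfig:
    """Founder-to-F2 breeding scheme under germline mosaicism.

    ``founder_germline_allele_freqs`` gives the founder's germline allele
    composition (labels -> fractions summing to 1, including the wild
    allele); F1 are founder x wild-type outcrosses, F2 come from
    heterozygote intercrosses listed by allele label.
    """

    founder_germline_allele_freqs: dict[str, float]
    n_f1: int = 50
    f1_intercross_pairs: tuple[str, ...] = ()
    n_f2_per_pair: int = 0
    seed: int = 0
    founder_id: str = "G0"

    def __post_init__(self) -> None:
        total = sum(self.founder_germline_allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"allele fractions sum to {total}, not 1")
        if any(v < 0 for v in self.founder_germline_allele_freqs.values()):
            raise ConfigError("allele fractions must be non-negative")


def simulate_cross(cfg: CrossSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw F1 and F2 genotype tables.

    F1 rows: sample_id, founder_id, genotype_class (``wild`` or
    ``<allele> het``) plus the transmitted allele as truth. F2 rows: one per
    embryo per intercross with genotype_class ``wild``/``<allele> het``/
    ``<allele> hom``. Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = list(cfg.founder_germline_allele_freqs)
    probs = np.array([cfg.founder_germline_allele_freqs[k] for k in labels])
    draws = rng.choice(len(labels), cfg.n_f1, p=probs)
    f1_rows = []
    for i, d in enumerate(draws):
        allele = labels[int(d)]
        cls = WILD if allele == WILD else f"{allele} het"
        f1_rows.append(
            {
                "sample_id": f"F1_{i:04d}",
                "founder_id": cfg.founder_id,
                "genotype_class": cls,
                "transmitted_allele": allele,
            }
        )
    f1 = pd.DataFrame(f1_rows)

    f2_rows = []
    for pair_no, allele in enumerate(cfg.f1_intercross_pairs):
        n_mut = rng.binomial(1, 0.5, (cfg.n_f2_per_pair, 2)).sum(axis=1)
        for j, k in enumerate(n_mut):
            cls = (WILD, f"{allele} het", f"{allele} hom")[int(k)]
            f2_rows.append(
                {
                    "sample_id": f"F2_{pair_no}_{j:05d}",
                    "pair_id": f"pair_{pair_no}",
                    "allele": allele,
                    "genotype_class": cls,
                    "n_mutant_alleles": int(k),
                }
            )
    f2 = pd.DataFrame(
        f2_rows,
        columns=["sample_id", "pair_id", "allele", "genotype_class",
                 "n_mutant_alleles"],
    )
    return f1, f2
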