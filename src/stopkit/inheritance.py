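"""Genotype tallies, germline transmission and Mendelian segregation tests.

Operates on genotype class labels produced upstream (free text such as
"wild", "c.232C>T het", "compound het"); it never re-calls genotypes. The
segregation test compares an observed affected fraction against a binomial
expectation (0.25 for a recessive allele from a het-by-het cross) with a
one-degree-of-freedom chi-square.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

WILD_LABELS = frozenset({"wild", "wt", "wild-type", "wildtype", "+/+"})


@dataclass(frozen=True)
class GenotypeTally:
    """Counts and percent frequencies of genotype classes among offspring."""

    class_counts: dict[str, int]
    total: int
    frequencies: dict[str, float]
    founder_id: str | None = None

    def count(self, label: str) -> int:
        return self.class_counts.get(label, 0)


@dataclass(frozen=True)
class SegregationTest:
    """Chi-square comparison of an observed class fraction to expectation."""

    observed_affected: int
    total: int
    expected_fraction: float
    observed_fraction_percent: float
    chi_square: float
    p_value: float
    continuity_corrected: bool
    consistent: bool  # True when p >= alpha used at construction


def tally(genotypes: Sequence[str], founder_id: str | None = None) -> GenotypeTally:
    """Exact class counts with percent frequencies rounded to 1 decimal."""
    if not genotypes:
        raise ValueError("empty genotype list")
    counts = dict(Counter(genotypes))
    total = len(genotypes)
    freqs = {k: round(100.0 * v / total, 1) for k, v in counts.items()}
    return GenotypeTally(
        class_counts=counts, total=total, frequencies=freqs, founder_id=founder_id
    )


def segregation_test(
    affected: int,
    total: int,
    expected_fraction: float = 0.25,
    continuity_correction: bool = False,
    alpha: float = 0.05,
) -> SegregationTest:
    """Chi-square (1 df) test of ``affected/total`` against a Mendelian
    expectation; Yates continuity correction optional, off by default."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= affected <= total:
        raise ValueError("affected must lie in [0, total]")
    exp_aff = expected_fraction * total
    exp_un = (1.0 - expected_fraction) * total
    obs = (affected, total - affected)
    chi = 0.0
    for o, e in zip(obs, (exp_aff, exp_un)):
        d = abs(o - e)
        if continuity_correction:
            d = max(d - 0.5, 0.0)
        chi += d * d / e
    p = float(stats.chi2.sf(chi, df=1))
    return SegregationTest(
        observed_affected=affected,
        total=total,
        expected_fraction=expected_fraction,
        observed_fraction_percent=round(100.0 * affected / total, 1),
        chi_square=chi,
        p_value=p,
        continuity_corrected=continuity_correction,
        consistent=p >= alpha,
    )


@dataclass(frozen=True)
class TransmissionSummary:
    """Germline transmission across founders: who passed a modified allele."""

    n_founders: int
    n_transmitting: int
    per_founder_modified_fraction: dict[str, float]
    transmitting_founders: tuple[str, ...]


def _is_wild(label: str) -> bool:
    return label.strip().lower() in WILD_LABELS


def transmission_rate(
    f1_tallies: Iterable[GenotypeTally],
    wild_labels: frozenset[str] | None = None,
) -> TransmissionSummary:
    """Count founders with at least one non-wild F1 offspring class.

    A founder whose somatic (fin) genotype shows edits but whose F1 are all
    wild-type counts as non-transmitting — germline mosaicism means somatic
    and germline genotypes can disagree.
    """
    labels = wild_labels or WILD_LABELS
    per_founder: dict[str, float] = {}
    transmitting: list[str] = []
    n = 0
    for t in f1_tallies:
        fid = t.founder_id if t.founder_id is not None else f"founder_{n}"
        n += 1
        modified = sum(
            c for lab, c in t.class_counts.items()
            if lab.strip().lower() not in labels
        )
        frac = modified / t.total
        per_founder[fid] = frac
        if modified >= 1:
            transmitting.append(fid)
    return TransmissionSummary(
        n_founders=n,
        n_transmitting=len(transmitting),
        per_founder_modified_fraction=per_founder,
        transmitting_founders=tuple(transmitting),
    )


def tallies_from_table(
    rows: Iterable[Mapping[str, str]],
) -> list[GenotypeTally]:
    """Group (sample_id, founder_id, genotype_class) rows into per-founder
    tallies, preserving founder order of first appearance."""
    by_founder: dict[str, list[str]] = {}
    for row in rows:
        by_founder.setdefault(str(row["founder_id"]), []).append(
            str(row["genotype_class"])
        )
    return [tally(v, founder_id=k) for k, v in by_founder.items()]
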