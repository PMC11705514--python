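"""Codon counting, relative synonymous codon usage and enrichment testing.

RSCU for a codon is its count divided by the mean count over its synonymous
family, so a uniformly used family sits at 1 everywhere and single-codon
families (Met, Trp) are identically 1.  Codon-family enrichment between two
transcript sets (e.g. yolk-protein transcripts against a ribosomal-protein
reference) is a two-sided Fisher's exact test on the 2×2 table of target
versus reference amino-acid codon counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Dict, Iterable, Mapping, Optional, Tuple

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = ["CodonUsageTable", "GENETIC_CODE", "SYNONYMOUS_FAMILIES", "AA_NAMES",
           "count_codons", "rscu", "fisher_exact_two_sided", "enrichment_test"]

_STANDARD = unambiguous_dna_by_id[1]

#: codon (DNA alphabet) → amino acid, stop codons → "*"
GENETIC_CODE: Dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    GENETIC_CODE[_stop] = "*"

ALL_CODONS: Tuple[str, ...] = tuple(sorted(GENETIC_CODE))

#: amino acid → synonymous codon family (stops excluded from RSCU families)
SYNONYMOUS_FAMILIES: Dict[str, Tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    if _aa != "*":
        SYNONYMOUS_FAMILIES.setdefault(_aa, ())
        SYNONYMOUS_FAMILIES[_aa] += (_codon,)

AA_NAMES = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


def _aa_letter(aa: str) -> str:
    if len(aa) == 1:
        return aa.upper()
    try:
        return AA_NAMES[aa.capitalize()]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


@dataclass
class CodonUsageTable:
    """64-codon counts for a set of coding sequences."""

    counts: Dict[str, int] = field(default_factory=lambda: {c: 0 for c in ALL_CODONS})
    label: str = ""
    skipped_codons: int = 0
    truncated_cds: int = 0

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            if codon not in full:
                raise ValueError(f"invalid codon {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon!r}")
            full[codon] = int(n)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> Dict[str, float]:
        """Per-codon fraction of all counted codons (sums to 1)."""
        total = self.total
        if total == 0:
            return {c: 0.0 for c in ALL_CODONS}
        return {c: n / total for c, n in self.counts.items()}

    def family_count(self, aa: str) -> int:
        letter = _aa_letter(aa)
        return sum(self.counts[c] for c in SYNONYMOUS_FAMILIES[letter])

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        merged = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        return CodonUsageTable(
            merged, label=f"{self.label}+{other.label}",
            skipped_codons=self.skipped_codons + other.skipped_codons,
            truncated_cds=self.truncated_cds + other.truncated_cds,
        )

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies()
        table = rscu(self)
        return pd.DataFrame({
            "codon": ALL_CODONS,
            "amino_acid": [GENETIC_CODE[c] for c in ALL_CODONS],
            "count": [self.counts[c] for c in ALL_CODONS],
            "frequency": [freqs[c] for c in ALL_CODONS],
            "rscu": [table.get(c) for c in ALL_CODONS],
        })


def count_codons(sequences: Iterable[str] | Mapping[str, str], label: str = "") -> CodonUsageTable:
    """In-frame triplet counts from position 1 of each CDS.

    U and T are interchangeable; a trailing partial codon is truncated (and
    tallied in ``truncated_cds``); codons containing other characters are
    skipped and tallied in ``skipped_codons``.
    """
    if isinstance(sequences, Mapping):
        sequences = sequences.values()
    table = CodonUsageTable(label=label)
    for seq in sequences:
        s = seq.upper().replace("U", "T")
        if len(s) % 3:
            table.truncated_cds += 1
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if codon in table.counts:
                table.counts[codon] += 1
            else:
                table.skipped_codons += 1
    return table


def rscu(table: CodonUsageTable) -> Dict[str, Optional[float]]:
    """Relative synonymous codon usage per codon.

    RSCU(c) = count(c) / mean count over c's synonymous family.  Families
    with zero total usage are undefined (None); stop codons carry no RSCU.
    Within any used family the values sum to the family size, so the family
    mean is 1.
    """
    out: Dict[str, Optional[float]] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        total = sum(table.counts[c] for c in family)
        if total == 0:
            for c in family:
                out[c] = None
        else:
            mean = total / len(family)
            for c in family:
                out[c] = table.counts[c] / mean
    for stop in _STANDARD.stop_codons:
        out[stop] = None
    return out


#: relative tie tolerance for the two-sided tail definition; the standard
#: convention (shared by R's fisher.test) counts outcomes whose probability
#: exceeds the observed one by less than this as equally extreme
_TIE_REL = 10**7  # tolerance 1/_TIE_REL


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Exact two-sided Fisher test for the 2×2 table [[a, b], [c, d]].

    Enumerates the hypergeometric support in exact integer arithmetic:
    conditional on the margins, outcome k has probability proportional to
    T(k) = C(a+b, k)·C(c+d, n−k) with n = a+c, and the two-sided p-value
    sums T(k) over every k no more probable than the observed a (with the
    standard 1e-7 relative tie tolerance, applied in integers so no
    floating-point rounding enters the tail decision).  Returns the sample
    odds ratio (a·d)/(b·c) and the p-value.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    K = a + b  # row 1 margin
    n = a + c  # column 1 margin
    if K == 0 or c + d == 0 or n == 0 or b + d == 0:
        raise ValueError(f"degenerate 2x2 table [[{a},{b}],[{c},{d}]]: zero marginal")
    lo = max(0, n - (N - K))
    hi = min(K, n)
    t_obs = comb(K, a) * comb(N - K, n - a)
    tail = 0
    for k in range(lo, hi + 1):
        t_k = comb(K, k) * comb(N - K, n - k)
        if t_k * _TIE_REL <= t_obs * (_TIE_REL + 1):
            tail += t_k
    p = tail / comb(N, n)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return odds, min(p, 1.0)


def enrichment_test(
    table_a: CodonUsageTable,
    table_b: CodonUsageTable,
    target_aa: str = "Tyr",
    reference_aa: str = "Ala",
) -> Tuple[float, float]:
    """Two-sided Fisher's exact test of target-vs-reference codon counts in
    set A against set B.

    The 2×2 table is [[Tyr_A, Ala_A], [Tyr_B, Ala_B]] (raw codon counts, the
    only valid input for an exact test).  Returns (odds ratio, p-value).
    """
    return fisher_exact_two_sided(
        table_a.family_count(target_aa),
        table_a.family_count(reference_aa),
        table_b.family_count(target_aa),
        table_b.family_count(reference_aa),
    )
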