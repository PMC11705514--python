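"""In-silico ribonuclease digestion of modified RNA.

Two endoribonucleases are built in.  RNase T1 cleaves 3' of unmodified
guanosine and leaves products with a 3'-linear phosphate.  Cusativin cleaves
3' of cytidine, does not cleave between two consecutive cytidines (the CpC
rule) and leaves 2',3'-cyclic phosphate products.  Both enzymes are blocked
by modification of the cleavage-site residue; the CpC rule applies to the
parent bases regardless of modification status.  Downstream fragments start
with a 5'-OH; the first product inherits the parent's 5' chemistry and the
3'-terminal product inherits the parent's 3' chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List

from .chem import ModifiedSequence

__all__ = ["RNase", "DigestionProduct", "RNASE_T1", "CUSATIVIN", "ENZYMES",
           "digest", "cleavage_sites", "product_uniqueness"]


@dataclass(frozen=True)
class RNase:
    """Endoribonuclease selectivity rules.

    ``cleaves_after``: canonical parent bases 3' of which the backbone is cut.
    ``blocked_by_modification``: a modified residue at the cleavage site
    blocks cleavage.  ``no_cleavage_between_identical``: do not cut a bond
    whose flanking residues share the parent base in ``cleaves_after``
    (cusativin's CpC rule).  ``product_three_prime`` is the 3' chemistry of
    internal products; downstream fragments always get a 5'-OH.
    """

    name: str
    cleaves_after: frozenset = frozenset()
    blocked_by_modification: bool = True
    no_cleavage_between_identical: bool = False
    product_three_prime: str = "p"

    def __post_init__(self) -> None:
        object.__setattr__(self, "cleaves_after", frozenset(self.cleaves_after))
        if not self.cleaves_after:
            raise ValueError("cleaves_after set must be non-empty")
        if self.product_three_prime not in ("p", ">p"):
            raise ValueError("product 3' chemistry must be 'p' or '>p'")


RNASE_T1 = RNase("RNase T1", cleaves_after=frozenset("G"), product_three_prime="p")
CUSATIVIN = RNase(
    "cusativin",
    cleaves_after=frozenset("C"),
    no_cleavage_between_identical=True,
    product_three_prime=">p",
)

ENZYMES: Dict[str, RNase] = {
    "T1": RNASE_T1,
    "RNase T1": RNASE_T1,
    "cusativin": CUSATIVIN,
}


@dataclass(frozen=True)
class DigestionProduct:
    """A contiguous slice of a parent sequence produced by digestion."""

    sequence: ModifiedSequence
    parent_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int
    is_three_prime_terminal: bool

    def __str__(self) -> str:
        return str(self.sequence)


def cleavage_sites(parent: ModifiedSequence, enzyme: RNase) -> List[int]:
    """1-based residue positions i such that the bond between i and i+1 is cut."""
    bases = parent.parent_bases()
    sites = []
    for i in range(1, len(parent)):  # bond after residue i (1-based)
        base = bases[i - 1]
        if base not in enzyme.cleaves_after:
            continue
        if enzyme.blocked_by_modification and parent.is_modified(i):
            continue
        if enzyme.no_cleavage_between_identical and bases[i] == base:
            continue
        sites.append(i)
    return sites


def _product(
    parent: ModifiedSequence,
    parent_id: str,
    enzyme: RNase,
    start: int,
    end: int,
    missed: int,
) -> DigestionProduct:
    n = len(parent)
    five = parent.five_prime if start == 1 else "OH"
    three = parent.three_prime if end == n else enzyme.product_three_prime
    return DigestionProduct(
        parent.slice(start, end, five, three),
        parent_id,
        start,
        end,
        missed,
        is_three_prime_terminal=(end == n),
    )


def digest(
    parent: ModifiedSequence,
    enzyme: RNase,
    max_missed_cleavages: int = 0,
    parent_id: str = "",
) -> List[DigestionProduct]:
    """Enumerate digestion products with 0..max missed cleavages.

    The zero-missed-cleavage products partition the parent: concatenating
    them in order reconstructs its residue string.  Products are returned
    ordered by start position, then missed-cleavage count.
    """
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    sites = cleavage_sites(parent, enzyme)
    # segment boundaries: [1, s1+1, s2+1, ...] .. [s1, s2, ..., n]
    starts = [1] + [s + 1 for s in sites]
    ends = sites + [len(parent)]
    products: List[DigestionProduct] = []
    for i, start in enumerate(starts):
        for missed in range(0, max_missed_cleavages + 1):
            j = i + missed
            if j >= len(ends):
                break
            products.append(_product(parent, parent_id, enzyme, start, ends[j], missed))
    return products


def product_uniqueness(
    db: Iterable[ModifiedSequence] | Dict[str, ModifiedSequence],
    enzyme: RNase,
    product: ModifiedSequence | DigestionProduct,
    max_missed_cleavages: int = 0,
) -> int:
    """Number of database parents whose digest yields the given product.

    Matching is exact on residue string plus terminus chemistry, the same
    uniqueness argument used to assign an anticodon-spanning product to a
    single tRNA species.
    """
    target = product.sequence if isinstance(product, DigestionProduct) else product
    key = (target.residues, target.five_prime, target.three_prime)
    if isinstance(db, dict):
        items = db.items()
    else:
        items = ((str(i), seq) for i, seq in enumerate(db))
    count = 0
    for pid, parent in items:
        for prod in digest(parent, enzyme, max_missed_cleavages, parent_id=pid):
            s = prod.sequence
            if (s.residues, s.five_prime, s.three_prime) == key:
                count += 1
                break
    return count
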