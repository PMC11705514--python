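"""Oligonucleotide neutral masses, charge-state m/z and c/y fragment ions.

Neutral mass is the sum of residue masses (nucleoside-5'-monophosphate −
water) plus a terminal adjustment that books one water for the free ends
and one phosphate per internal linkage plus terminal phosphates:

    5'-OH,  3'-p   : +water          (n phosphates for n residues)
    5'-p,   3'-OH  : +water
    5'-OH,  3'->p  : +0              (cyclization loses the water)
    5'-OH,  3'-OH  : +water − HPO3
    5'-p,   3'-p   : +water + HPO3

Collision-induced dissociation of the phosphodiester backbone yields the
complementary c (5') and y (3') ion series with the identity
c_i + y_{n−i} = M + water.  Negative-mode m/z subtracts one proton per
charge; positive-mode nucleoside adduct m/z can use either the hydrogen-atom
or the proton convention (hydrogen-atom by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional

from .chem import HPO3, HYDROGEN, PROTON, WATER, Monomer, ModifiedSequence, lookup_monomer

__all__ = ["OligoIon", "neutral_mass", "mz", "fragment_series", "nucleoside_mz",
           "match_charge_state"]


@dataclass(frozen=True)
class OligoIon:
    """A charged oligonucleotide species (precursor or backbone fragment)."""

    neutral_mass: float
    charge: int
    polarity: str  # "negative" | "positive"
    mz: float
    series: str  # "precursor" | "c" | "y"
    index: int = 0  # series index; 0 for precursors


def neutral_mass(seq: ModifiedSequence) -> float:
    """Neutral monoisotopic mass (Da) of a sequence with its termini."""
    n = len(seq)
    total = sum(m.residue_mass for m in seq.monomers())
    n_phosphates = (n - 1) + (seq.five_prime == "p") + (seq.three_prime in ("p", ">p"))
    total += WATER + HPO3 * (n_phosphates - n)
    if seq.three_prime == ">p":
        total -= WATER
    return total


def mz(neutral: float, charge: int, polarity: str = "negative") -> float:
    """m/z of an ion at the given charge state.

    Negative mode: (M − |z|·m_proton)/|z|.  Positive mode: (M + |z|·m_proton)/|z|.
    """
    if charge == 0:
        raise ValueError("charge must be non-zero")
    z = abs(charge)
    if polarity == "negative":
        value = (neutral - z * PROTON) / z
    elif polarity == "positive":
        value = (neutral + z * PROTON) / z
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return value


def fragment_series(
    seq: ModifiedSequence,
    series: Literal["c", "y"],
    max_charge: int = 2,
    polarity: str = "negative",
) -> List[OligoIon]:
    """c- or y-series fragment ions for charges 1..max_charge.

    For a parent of n residues, c_i (i = 1..n−1) is the 5' fragment ending in
    a 3'-phosphate after linkage i:  c_i = Σ first i residue masses
    (+HPO3 if the 5' terminus is phosphorylated).  y_j is the complementary
    3' fragment:  y_j = M_parent + water − c_{n−j}.
    """
    n = len(seq)
    if n < 2:
        raise ValueError("fragment series require at least 2 residues")
    if series not in ("c", "y"):
        raise ValueError(f"unsupported series {series!r}")
    residues = [m.residue_mass for m in seq.monomers()]
    five_adj = HPO3 if seq.five_prime == "p" else 0.0
    parent = neutral_mass(seq)
    c_masses = []
    running = five_adj
    for i in range(n - 1):
        running += residues[i]
        c_masses.append(running)  # c_{i+1}
    ions: List[OligoIon] = []
    for idx in range(1, n):
        if series == "c":
            neutral = c_masses[idx - 1]
        else:
            neutral = parent + WATER - c_masses[n - idx - 1]
        for z in range(1, max_charge + 1):
            ions.append(OligoIon(neutral, z, polarity, mz(neutral, z, polarity), series, idx))
    return ions


def nucleoside_mz(
    code: str,
    convention: Literal["hydrogen", "proton"] = "hydrogen",
    registry=None,
) -> float:
    """Positive-mode protonated-nucleoside m/z for a registry code.

    The default hydrogen-atom convention adds 1.007825 to the neutral
    nucleoside mass; the proton convention adds 1.007276.
    """
    mono: Monomer = lookup_monomer(code, registry)
    adduct = HYDROGEN if convention == "hydrogen" else PROTON
    return mono.nucleoside_mass + adduct


def match_charge_state(
    neutral: float,
    observed_mz: float,
    polarity: str = "negative",
    charges=range(1, 6),
    tol: float = 0.5,
) -> Optional[int]:
    """Charge state (1..5 by default) whose m/z is nearest the observation
    within ``tol`` (Da); None if no charge state matches."""
    best = None
    best_err = tol
    for z in charges:
        err = abs(mz(neutral, z, polarity) - observed_mz)
        if err <= best_err:
            best, best_err = z, err
    return best
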