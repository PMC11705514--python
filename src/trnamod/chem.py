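"""Modified-RNA chemistry: atomic masses, the monomer registry and sequences.

The registry carries the canonical ribonucleotides plus the modified
nucleosides observed in mosquito tRNA (queuosine family, pseudouridines,
methylations, anticodon-loop hypermodifications...).  Every entry stores
either a full nucleoside elemental formula or a signed elemental increment
relative to its parent canonical nucleoside, and residue masses (nucleoside
5'-monophosphate minus water) are derived from those, so each mass in the
table is reproducible from atomic masses alone.

Sequences use bracket notation: canonical residues are single characters,
modified residues are enclosed in square brackets (``ACU[manQ]UAGp``), an
optional leading ``p`` marks a 5'-monophosphate and a trailing ``p`` or
``>p`` marks a 3'-linear or 2',3'-cyclic phosphate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

__all__ = [
    "ATOMIC_MASSES",
    "WATER",
    "HPO3",
    "PROTON",
    "HYDROGEN",
    "monoisotopic_mass",
    "parse_formula",
    "Monomer",
    "MonomerRegistry",
    "default_registry",
    "lookup_monomer",
    "ModifiedSequence",
    "parse_sequence",
    "RegistryError",
    "SequenceError",
]

#: Monoisotopic atomic masses (Da) of the elements occurring in nucleosides.
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Se": 79.9165218,
    "Br": 78.9183376,
}

WATER = 2 * ATOMIC_MASSES["H"] + ATOMIC_MASSES["O"]  # 18.010565
HPO3 = ATOMIC_MASSES["H"] + ATOMIC_MASSES["P"] + 3 * ATOMIC_MASSES["O"]  # 79.966331
PROTON = 1.007276
HYDROGEN = ATOMIC_MASSES["H"]


class RegistryError(KeyError):
    """Unknown monomer code or malformed registry entry."""


class SequenceError(ValueError):
    """Malformed sequence text or invalid terminus chemistry."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Dict[str, int]:
    """Parse an elemental formula such as ``C10H13N5O5`` into element counts.

    Signed segments are allowed for increments: ``+C6H10O5``, ``O-N-H``
    (gain one O, lose one N and one H).  Returns a possibly-negative count
    per element; the empty string parses to the empty composition.
    """
    counts: Dict[str, int] = {}
    if not text:
        return counts
    sign = 1
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "+":
            sign = 1
            i += 1
            continue
        if ch == "-":
            sign = -1
            i += 1
            continue
        m = _FORMULA_TOKEN.match(text, i)
        if not m or not m.group(1):
            raise ValueError(f"cannot parse formula {text!r} at position {i}")
        elem = m.group(1)
        if elem not in ATOMIC_MASSES:
            raise ValueError(f"unknown element {elem!r} in formula {text!r}")
        num = m.group(2)
        n = int(num) if num not in ("", "-") else 1
        counts[elem] = counts.get(elem, 0) + sign * n
        i = m.end()
    return counts


def monoisotopic_mass(formula: Mapping[str, int] | str) -> float:
    """Monoisotopic mass (Da) of an elemental composition.

    Accepts either a formula string or an element→count mapping (counts may
    be negative for increments).  The empty composition weighs 0.0.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    mass = 0.0
    for elem, count in formula.items():
        try:
            mass += ATOMIC_MASSES[elem] * count
        except KeyError:
            raise ValueError(f"unknown element {elem!r}") from None
    return mass


# Canonical nucleoside formulas (ribonucleosides).
_CANONICAL_FORMULAS = {
    "A": "C10H13N5O4",  # adenosine
    "C": "C9H13N3O5",  # cytidine
    "G": "C10H13N5O5",  # guanosine
    "U": "C9H12N2O6",  # uridine
}


@dataclass(frozen=True)
class Monomer:
    """One residue type: a canonical ribonucleotide or a modified nucleoside.

    Exactly one of ``formula`` (full nucleoside composition) or ``increment``
    (signed composition relative to the parent nucleoside) is set; the other
    is derived, so stored and formula-derived masses can never disagree.
    """

    code: str
    name: str
    parent: str  # canonical parent base A/C/G/U
    formula: Optional[Dict[str, int]] = None
    increment: Optional[Dict[str, int]] = None

    def __post_init__(self) -> None:
        if (self.formula is None) == (self.increment is None):
            raise RegistryError(
                f"monomer {self.code!r} must define exactly one of formula/increment"
            )
        if self.parent not in _CANONICAL_FORMULAS:
            raise RegistryError(f"monomer {self.code!r}: unknown parent {self.parent!r}")

    @property
    def nucleoside_formula(self) -> Dict[str, int]:
        if self.formula is not None:
            return dict(self.formula)
        base = parse_formula(_CANONICAL_FORMULAS[self.parent])
        for elem, n in self.increment.items():  # type: ignore[union-attr]
            base[elem] = base.get(elem, 0) + n
        return {e: n for e, n in base.items() if n != 0}

    @property
    def nucleoside_mass(self) -> float:
        """Neutral monoisotopic mass of the free nucleoside (Da)."""
        return monoisotopic_mass(self.nucleoside_formula)

    @property
    def residue_mass(self) -> float:
        """Internal residue mass: nucleoside-5'-monophosphate − water (Da)."""
        return self.nucleoside_mass + HPO3 - WATER

    @property
    def mass_increment(self) -> float:
        """Mass difference vs the parent canonical residue (Da)."""
        return self.nucleoside_mass - monoisotopic_mass(_CANONICAL_FORMULAS[self.parent])

    @property
    def is_canonical(self) -> bool:
        return self.code in _CANONICAL_FORMULAS


def _builtin_monomers() -> List[Monomer]:
    def canon(code: str, name: str) -> Monomer:
        return Monomer(code, name, code, formula=parse_formula(_CANONICAL_FORMULAS[code]))

    def mod(code: str, name: str, parent: str, increment: str | Dict[str, int]) -> Monomer:
        inc = parse_formula(increment) if isinstance(increment, str) else dict(increment)
        return Monomer(code, name, parent, increment=inc)

    CH2 = "CH2"  # methylation
    return [
        canon("A", "adenosine"),
        canon("C", "cytidine"),
        canon("G", "guanosine"),
        canon("U", "uridine"),
        # queuosine family (7-deazaguanosine hypermodifications, position 34)
        mod("Q", "queuosine", "G", "C17H23N5O7-C10H13N5O5"),
        mod("manQ", "mannosyl-queuosine", "G", "C17H23N5O7+C6H10O5-C10H13N5O5"),
        mod("galQ", "galactosyl-queuosine", "G", "C17H23N5O7+C6H10O5-C10H13N5O5"),
        mod("oQ", "epoxyqueuosine", "G", "C17H23N5O8-C10H13N5O5"),
        # uridine family
        mod("Ψ", "pseudouridine", "U", ""),
        mod("Ψm", "2'-O-methylpseudouridine", "U", CH2),
        mod("D", "dihydrouridine", "U", "H2"),
        mod("m5U", "5-methyluridine", "U", CH2),
        mod("Um", "2'-O-methyluridine", "U", CH2),
        mod("acp3U", "3-(3-amino-3-carboxypropyl)uridine", "U", "C4H7NO2"),
        mod("acp3D", "3-(3-amino-3-carboxypropyl)dihydrouridine", "U", "C4H7NO2+H2"),
        mod("mcm5U", "5-methoxycarbonylmethyluridine", "U", "C3H4O2"),
        mod("mcm5s2U", "5-methoxycarbonylmethyl-2-thiouridine", "U", "C3H4O2+S-O"),
        # cytidine family
        mod("m3C", "3-methylcytidine", "C", CH2),
        mod("m5C", "5-methylcytidine", "C", CH2),
        mod("Cm", "2'-O-methylcytidine", "C", CH2),
        mod("ac4C", "N4-acetylcytidine", "C", "C2H2O"),
        # guanosine family
        mod("m1G", "1-methylguanosine", "G", CH2),
        mod("m2G", "N2-methylguanosine", "G", CH2),
        mod("m22G", "N2,N2-dimethylguanosine", "G", "C2H4"),
        mod("Gm", "2'-O-methylguanosine", "G", CH2),
        # adenosine family
        mod("m1A", "1-methyladenosine", "A", CH2),
        mod("Am", "2'-O-methyladenosine", "A", CH2),
        mod("I", "inosine", "A", "O-NH"),
        mod("m1I", "1-methylinosine", "A", "O-NH+CH2"),
        mod("i6A", "N6-isopentenyladenosine", "A", "C5H8"),
        mod("ms2i6A", "2-methylthio-N6-isopentenyladenosine", "A", "C5H8+CH2S"),
        mod("t6A", "N6-threonylcarbamoyladenosine", "A", "C5H7NO4"),
        mod("ms2t6A", "2-methylthio-N6-threonylcarbamoyladenosine", "A", "C5H7NO4+CH2S"),
    ]


class MonomerRegistry:
    """Code → :class:`Monomer` lookup, user-extensible via a TSV file."""

    def __init__(self, monomers: Optional[Iterable[Monomer]] = None) -> None:
        self._table: Dict[str, Monomer] = {}
        for mono in monomers if monomers is not None else _builtin_monomers():
            self.add(mono)

    def add(self, monomer: Monomer) -> None:
        self._table[monomer.code] = monomer

    def __contains__(self, code: str) -> bool:
        return code in self._table

    def __iter__(self):
        return iter(self._table.values())

    def __len__(self) -> int:
        return len(self._table)

    def lookup(self, code: str) -> Monomer:
        try:
            return self._table[code]
        except KeyError:
            raise RegistryError(f"unknown monomer code {code!r}") from None

    def codes(self) -> List[str]:
        return list(self._table)

    def load_tsv(self, path: str | Path) -> int:
        """Extend/override from a TSV with columns code, name, parent,
        formula_or_increment.  Values starting with ``+`` or ``-`` are
        increments relative to the parent; others are full nucleoside
        formulas.  Returns the number of entries loaded."""
        n = 0
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "code":
                continue
            if len(parts) != 4:
                raise RegistryError(f"{path}:{lineno}: expected 4 tab-separated fields")
            code, name, parent, fi = (p.strip() for p in parts)
            if fi.startswith(("+", "-")):
                self.add(Monomer(code, name, parent, increment=parse_formula(fi)))
            else:
                self.add(Monomer(code, name, parent, formula=parse_formula(fi)))
            n += 1
        return n


_DEFAULT_REGISTRY: Optional[MonomerRegistry] = None


def default_registry() -> MonomerRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = MonomerRegistry()
    return _DEFAULT_REGISTRY


def lookup_monomer(code: str, registry: Optional[MonomerRegistry] = None) -> Monomer:
    return (registry or default_registry()).lookup(code)


_FIVE_PRIME = ("OH", "p")
_THREE_PRIME = ("OH", "p", ">p")


@dataclass(frozen=True)
class ModifiedSequence:
    """An RNA sequence with named modifications and explicit terminus chemistry.

    Residues are 1-based (``seq[1]`` in domain terms is ``residues[0]``),
    matching tRNA position nomenclature (wobble position 34, position 37).
    """

    residues: Tuple[str, ...]
    five_prime: str = "OH"  # OH | p (monophosphate)
    three_prime: str = "OH"  # OH | p (linear phosphate) | >p (2',3'-cyclic)
    registry: MonomerRegistry = field(
        default_factory=default_registry, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceError("sequence must contain at least one residue")
        if self.five_prime not in _FIVE_PRIME:
            raise SequenceError(f"invalid 5' terminus {self.five_prime!r}")
        if self.three_prime not in _THREE_PRIME:
            raise SequenceError(f"invalid 3' terminus {self.three_prime!r}")
        object.__setattr__(self, "residues", tuple(self.residues))
        for code in self.residues:
            self.registry.lookup(code)  # raises RegistryError on unknown codes

    def __len__(self) -> int:
        return len(self.residues)

    def monomers(self) -> List[Monomer]:
        return [self.registry.lookup(c) for c in self.residues]

    def parent_bases(self) -> Tuple[str, ...]:
        return tuple(m.parent for m in self.monomers())

    def is_modified(self, position: int) -> bool:
        """True if the residue at 1-based ``position`` is non-canonical."""
        return not self.registry.lookup(self.residues[position - 1]).is_canonical

    def slice(self, start: int, end: int, five_prime: str, three_prime: str) -> "ModifiedSequence":
        """Sub-sequence over 1-based inclusive [start, end] with new termini."""
        return ModifiedSequence(
            self.residues[start - 1 : end], five_prime, three_prime, self.registry
        )

    def __str__(self) -> str:
        body = "".join(
            c if c in _CANONICAL_FORMULAS else f"[{c}]" for c in self.residues
        )
        prefix = "p" if self.five_prime == "p" else ""
        suffix = {"OH": "", "p": "p", ">p": ">p"}[self.three_prime]
        return prefix + body + suffix


def parse_sequence(
    text: str, registry: Optional[MonomerRegistry] = None
) -> ModifiedSequence:
    """Parse bracket notation, e.g. ``ACU[manQ]UAGp`` or ``U[manQ]UAGAUCC>p``.

    Terminal chemistry defaults to OH on both ends; a leading ``p`` sets a
    5'-monophosphate, trailing ``p``/``>p`` a 3' linear/cyclic phosphate.
    """
    registry = registry or default_registry()
    if not text:
        raise SequenceError("empty sequence string")
    five = "OH"
    three = "OH"
    if text.startswith("p"):
        five = "p"
        text = text[1:]
    if text.endswith(">p"):
        three = ">p"
        text = text[:-2]
    elif text.endswith("p"):
        three = "p"
        text = text[:-1]
    residues: List[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise SequenceError(f"unterminated '[' at position {i} in {text!r}")
            code = text[i + 1 : j]
            if not code:
                raise SequenceError(f"empty modification brackets at position {i}")
            i = j + 1
        else:
            code = ch
            i += 1
        registry.lookup(code)
        residues.append(code)
    if not residues:
        raise SequenceError(f"no residues parsed from {text!r}")
    return ModifiedSequence(tuple(residues), five, three, registry)
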