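"""Match observed peak lists to predicted digestion products and localize
modifications.

This formalizes the manual interpretation of oligonucleotide MS/MS spectra:
candidates are filtered by precursor m/z over charge states 1−..5−, their
theoretical c/y fragment ions are matched greedily against the observed
peaks (presence/absence, intensity ignored), and a modification is localized
by scoring one candidate per legal placement plus the unmodified sequence.

Default tolerances reflect the instruments that produce such data: 10 ppm
for Orbitrap-class precursor masses and 0.5 Da for ion-trap fragment masses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from pyteomics import mgf as _mgf

from .chem import ModifiedSequence, MonomerRegistry, default_registry
from .digestion import DigestionProduct
from .masses import fragment_series, mz, neutral_mass

__all__ = ["PeakList", "MatchResult", "read_mgf", "read_tsv_peaks",
           "match_precursor", "score_fragments", "localize"]

DEFAULT_PRECURSOR_TOL_PPM = 10.0
DEFAULT_FRAGMENT_TOL_DA = 0.5
PRECURSOR_CHARGES = range(1, 6)
FRAGMENT_CHARGES = (1, 2)


@dataclass(frozen=True)
class PeakList:
    """An MS/MS peak list: optional precursor, fragments as (m/z, intensity)."""

    peaks: Tuple[Tuple[float, float], ...]
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple((float(m), float(i)) for m, i in self.peaks))
        for m, i in self.peaks:
            if m <= 0:
                raise ValueError(f"non-positive fragment m/z {m}")
            if i < 0:
                raise ValueError(f"negative intensity {i}")

    def __len__(self) -> int:
        return len(self.peaks)

    def mzs(self) -> List[float]:
        return [m for m, _ in self.peaks]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of scoring one candidate against one peak list."""

    candidate: object  # DigestionProduct or ModifiedSequence
    sequence: ModifiedSequence
    matched: int
    total: int
    matched_by_series: dict
    score: float
    mean_abs_error: float
    fragment_tol: float
    precursor_error_ppm: Optional[float] = None
    rank: int = 0


def read_mgf(path: str | Path) -> List[PeakList]:
    """Read peak lists from an MGF file (BEGIN IONS/PEPMASS/CHARGE blocks)."""
    out: List[PeakList] = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec.get("params", {})
            pep = params.get("pepmass")
            prec = float(pep[0]) if pep else None
            charge = params.get("charge")
            z = int(charge[0]) if charge else None
            peaks = tuple(zip(spec["m/z array"].tolist(), spec["intensity array"].tolist()))
            out.append(PeakList(peaks, prec, z, source=str(params.get("title", path))))
    return out


def read_tsv_peaks(path: str | Path, source: str = "") -> PeakList:
    """Read a two-column (m/z, intensity) TSV or whitespace-separated file."""
    peaks = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace("\t", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        peaks.append((float(parts[0]), float(parts[1])))
    return PeakList(tuple(peaks), source=source or str(path))


def _candidate_sequence(candidate) -> ModifiedSequence:
    return candidate.sequence if isinstance(candidate, DigestionProduct) else candidate


def match_precursor(
    peaklist: PeakList,
    candidates: Sequence,
    tol: float = DEFAULT_PRECURSOR_TOL_PPM,
    tol_unit: str = "ppm",
    charges=PRECURSOR_CHARGES,
) -> List:
    """Filter candidates whose negative-mode m/z at any charge 1−..5− falls
    within ``tol`` (ppm or Da) of the observed precursor.

    Without a recorded precursor the candidate list passes through unchanged
    (the warning case: fragment evidence only).
    """
    if tol <= 0:
        raise ValueError("tolerance must be > 0")
    if peaklist.precursor_mz is None:
        return list(candidates)
    kept = []
    for cand in candidates:
        M = neutral_mass(_candidate_sequence(cand))
        zs = [abs(peaklist.precursor_charge)] if peaklist.precursor_charge else charges
        for z in zs:
            theo = mz(M, z, "negative")
            err = peaklist.precursor_mz - theo
            limit = tol * theo * 1e-6 if tol_unit == "ppm" else tol
            if abs(err) <= limit:
                kept.append(cand)
                break
    return kept


def _theoretical_ions(seq: ModifiedSequence, charges=FRAGMENT_CHARGES):
    ions = []
    for series in ("c", "y"):
        ions.extend(fragment_series(seq, series, max_charge=max(charges)))
    return [ion for ion in ions if ion.charge in charges]


def score_fragments(
    peaklist: PeakList,
    candidate,
    tol: float = DEFAULT_FRAGMENT_TOL_DA,
    charges=FRAGMENT_CHARGES,
) -> MatchResult:
    """Score a candidate by the fraction of its theoretical c/y ions found.

    Greedy nearest-peak assignment within ``tol`` Da; each observed peak is
    consumed at most once.  Intensity does not enter the score, matching the
    qualitative interpretation of ion-trap oligonucleotide spectra.
    """
    seq = _candidate_sequence(candidate)
    theoretical = _theoretical_ions(seq, charges)
    available = list(peaklist.mzs())
    # assign smallest-error pairs first so each peak is consumed once
    pairs = []
    for t_idx, ion in enumerate(theoretical):
        for p_idx, obs in enumerate(available):
            err = abs(obs - ion.mz)
            if err <= tol:
                pairs.append((err, t_idx, p_idx))
    pairs.sort()
    used_theo: set = set()
    used_peak: set = set()
    matched_by_series: dict = {"c": 0, "y": 0}
    errors: List[float] = []
    for err, t_idx, p_idx in pairs:
        if t_idx in used_theo or p_idx in used_peak:
            continue
        used_theo.add(t_idx)
        used_peak.add(p_idx)
        matched_by_series[theoretical[t_idx].series] += 1
        errors.append(err)
    total = len(theoretical)
    matched = len(used_theo)
    prec_err = None
    if peaklist.precursor_mz is not None:
        M = neutral_mass(seq)
        zs = [abs(peaklist.precursor_charge)] if peaklist.precursor_charge else PRECURSOR_CHARGES
        prec_err = min(
            (peaklist.precursor_mz - mz(M, z, "negative")) / mz(M, z, "negative") * 1e6
            for z in zs
        )
    return MatchResult(
        candidate=candidate,
        sequence=seq,
        matched=matched,
        total=total,
        matched_by_series=matched_by_series,
        score=matched / total if total else 0.0,
        mean_abs_error=sum(errors) / len(errors) if errors else float("inf"),
        fragment_tol=tol,
        precursor_error_ppm=prec_err,
    )


def localize(
    peaklist: PeakList,
    base_sequence: ModifiedSequence,
    modification: str,
    tol: float = DEFAULT_FRAGMENT_TOL_DA,
    registry: Optional[MonomerRegistry] = None,
) -> List[Tuple[Optional[int], MatchResult]]:
    """Rank placements of ``modification`` along ``base_sequence``.

    One candidate per residue whose parent base matches the modification's
    parent, plus the unmodified sequence (placement ``None``).  Ranked by
    score, ties broken by smaller mean absolute fragment error.  Returns
    ``[(placement, MatchResult), ...]`` best first; empty if no residue can
    legally carry the modification.
    """
    registry = registry or default_registry()
    mono = registry.lookup(modification)
    placements: List[Tuple[Optional[int], ModifiedSequence]] = []
    for pos in range(1, len(base_sequence) + 1):
        code = base_sequence.residues[pos - 1]
        if registry.lookup(code).parent == mono.parent and code != modification:
            residues = list(base_sequence.residues)
            residues[pos - 1] = modification
            placements.append(
                (pos, ModifiedSequence(tuple(residues), base_sequence.five_prime,
                                       base_sequence.three_prime, registry))
            )
    if not placements:
        return []
    placements.append((None, base_sequence))
    scored = [(pos, score_fragments(peaklist, seq, tol)) for pos, seq in placements]
    scored.sort(key=lambda item: (-item[1].score, item[1].mean_abs_error))
    return [(pos, replace(res, rank=i + 1)) for i, (pos, res) in enumerate(scored)]
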