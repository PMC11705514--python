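"""Seeded generators for synthetic inputs with the statistical structure the
pipeline stages assume.

These stand in for data that cannot ship with the package: tRNA gene sets
with introns and exact gene copies, oligonucleotide MS/MS peak lists built
from predicted fragment ions plus decoy peaks, nucleoside peak-area tables
with lognormal matrix noise and planted per-time-point fold changes,
probe-level expression matrices, TPM tables, and codon-biased CDS sets.
Every generator is deterministic under a fixed seed and returns a truth
table alongside its data so parameter recovery can be tested stage by stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import ModifiedSequence, default_registry
from .codons import ALL_CODONS, GENETIC_CODE, SYNONYMOUS_FAMILIES
from .digestion import DigestionProduct
from .masses import fragment_series, mz, neutral_mass
from .matching import PeakList
from .quant import CANONICAL, TIME_ORDER

__all__ = ["GeneratorConfig", "make_trna_genes", "make_spectrum",
           "make_peak_area_table", "make_cds_set", "make_microarray",
           "make_tpm_table", "SCAN_RANGE"]

#: acquisition window of the oligonucleotide full scans; decoys fall here
SCAN_RANGE = (600.0, 2000.0)

#: the intron-bearing isoacceptor families
INTRON_FAMILIES = ("Ile-TAT", "Leu-CAA", "Tyr-GTA")

_FAMILIES = (
    "Ala-AGC", "Ala-TGC", "Arg-ACG", "Asn-GTT", "Asp-GTC", "Cys-GCA",
    "Gln-TTG", "Glu-TTC", "Gly-GCC", "His-GTG", "Ile-AAT", "Ile-TAT",
    "Leu-CAA", "Leu-TAA", "Lys-TTT", "Met-CAT", "Phe-GAA", "Pro-TGG",
    "Ser-GCT", "Thr-CGT", "Trp-CCA", "Tyr-GTA", "Val-TAC",
)


@dataclass
class GeneratorConfig:
    """Shared knobs for the generators; defaults mirror the study design:
    three biological replicates per time point, ~10% multiplicative noise on
    peak areas, decoy peaks across the m/z 600–2000 window."""

    seed: int = 0
    n_replicates: int = 3
    peak_area_cv: float = 0.10
    decoy_ratio: float = 0.0
    mz_jitter: float = 0.0
    tpm_dispersion: float = 0.25


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the given CV."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def make_trna_genes(
    n_genes: int = 200,
    n_duplicates: int = 42,
    seed: int = 0,
    gene_length: int = 72,
    intron_length: int = 13,
    intron_position: int = 38,
) -> Tuple[List, pd.DataFrame]:
    """Synthetic tRNA gene set with planted exact duplicates and introns.

    Gene bodies are random sequences (synthetic stand-ins for real tRNA
    genes — they fold into nothing); introns are inserted only in the three
    intron-bearing families.  ``n_genes`` counts total genes including the
    ``n_duplicates`` exact copies of earlier genes.  Returns (genes, truth)
    where truth records per-gene intron spans and duplicate provenance.
    """
    from .reference import TRNAGene  # local import to avoid cycle at module load

    if n_duplicates >= n_genes:
        raise ValueError("n_duplicates must be < n_genes")
    rng = _rng(seed)
    originals = n_genes - n_duplicates
    genes: List[TRNAGene] = []
    truth_rows = []
    counters: Dict[str, int] = {}
    for i in range(originals):
        family = _FAMILIES[int(rng.integers(len(_FAMILIES)))]
        isotype, anticodon = family.split("-")
        body = "".join(rng.choice(list("ACGT"), size=gene_length))
        intron = None
        if family in INTRON_FAMILIES:
            ins = "".join(rng.choice(list("ACGT"), size=intron_length))
            body = body[: intron_position - 1] + ins + body[intron_position - 1 :]
            intron = (intron_position, intron_position + intron_length - 1)
        counters[family] = counters.get(family, 0) + 1
        gid = f"{family}-{counters[family]}-1"
        genes.append(TRNAGene(gid, isotype, anticodon, body, intron))
        truth_rows.append({
            "gene_id": gid, "isotype": isotype, "anticodon": anticodon,
            "has_intron": intron is not None,
            "intron_start": intron[0] if intron else 0,
            "intron_end": intron[1] if intron else 0,
            "duplicate_of": "",
        })
    for j in range(n_duplicates):
        src = genes[int(rng.integers(originals))]
        family = f"{src.isotype}-{src.anticodon}"
        counters[family] = counters.get(family, 0) + 1
        gid = f"{family}-{counters[family]}-1"
        genes.append(TRNAGene(gid, src.isotype, src.anticodon, src.sequence, src.intron))
        truth_rows.append({
            "gene_id": gid, "isotype": src.isotype, "anticodon": src.anticodon,
            "has_intron": src.intron is not None,
            "intron_start": src.intron[0] if src.intron else 0,
            "intron_end": src.intron[1] if src.intron else 0,
            "duplicate_of": src.gene_id,
        })
    return genes, pd.DataFrame(truth_rows)


def make_spectrum(
    product: ModifiedSequence | DigestionProduct,
    seed: int = 0,
    charges: Sequence[int] = (1, 2),
    mz_jitter: float = 0.0,
    decoy_ratio: float = 0.0,
    include_precursor: bool = True,
    precursor_charge: int = 3,
) -> PeakList:
    """Synthetic negative-mode MS/MS peak list for a digestion product.

    All c/y ions at the given charge states with unit intensity, optional
    Gaussian m/z jitter (SD in Da) and uniform decoy peaks over the scan
    window at ``decoy_ratio`` decoys per true peak.
    """
    seq = product.sequence if isinstance(product, DigestionProduct) else product
    rng = _rng(seed)
    peaks: List[Tuple[float, float]] = []
    for series in ("c", "y"):
        for ion in fragment_series(seq, series, max_charge=max(charges)):
            if ion.charge not in charges:
                continue
            value = ion.mz + (rng.normal(0.0, mz_jitter) if mz_jitter > 0 else 0.0)
            peaks.append((max(value, 1e-6), 1.0))
    n_decoys = int(round(decoy_ratio * len(peaks)))
    for _ in range(n_decoys):
        peaks.append((float(rng.uniform(*SCAN_RANGE)), 1.0))
    peaks.sort()
    prec = mz(neutral_mass(seq), precursor_charge, "negative") if include_precursor else None
    return PeakList(
        tuple(peaks), prec, precursor_charge if include_precursor else None,
        source=f"synthetic:{seq}",
    )


_CANONICAL_MEANS = {"A": 3.0e6, "G": 3.4e6, "C": 2.8e6, "U": 2.9e6}


def make_peak_area_table(
    fold_changes: Mapping[str, Mapping[str, float]],
    n_replicates: int = 3,
    cv: float = 0.10,
    baseline_abundance: float = 0.02,
    time_points: Sequence[str] = TIME_ORDER,
    tissue: str = "whole body",
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Nucleoside XIC peak-area table with planted fold changes.

    ``fold_changes`` maps modification code → {time point: true fold change
    vs NBF} (NBF implicitly 1).  Canonical areas are lognormal around fixed
    means; each modification's area is its true normalized abundance ×
    the sample's canonical sum × lognormal noise, so normalization recovers
    the truth up to noise.  Returns (long table, truth table).
    """
    rng = _rng(seed)
    rows = []
    truth_rows = []
    for mod, fcs in fold_changes.items():
        for t in time_points:
            truth_rows.append({
                "nucleoside": mod, "time": t,
                "true_fold_change": 1.0 if t == "NBF" else float(fcs.get(t, 1.0)),
                "true_abundance": baseline_abundance,
            })
    for t in time_points:
        for rep in range(1, n_replicates + 1):
            sample = f"{t}-{rep}"
            scale = float(_lognormal_factor(rng, 0.3))  # sample-to-sample tRNA input
            canon_areas = {}
            for nuc in CANONICAL:
                canon_areas[nuc] = _CANONICAL_MEANS[nuc] * scale * float(
                    _lognormal_factor(rng, cv)
                )
                rows.append({
                    "sample": sample, "time": t, "tissue": tissue,
                    "nucleoside": nuc, "area": canon_areas[nuc],
                })
            canon_sum = sum(canon_areas.values())
            for mod, fcs in fold_changes.items():
                fc = 1.0 if t == "NBF" else float(fcs.get(t, 1.0))
                area = baseline_abundance * fc * canon_sum * float(
                    _lognormal_factor(rng, cv)
                )
                rows.append({
                    "sample": sample, "time": t, "tissue": tissue,
                    "nucleoside": mod, "area": area,
                })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


#: baseline amino-acid codon usage for the CDS generator (fractions of all
#: codons); Tyr at ~3% and Ala at ~8%, the ballpark of insect housekeeping
#: transcripts, remainder spread over the other families.
_BASE_TYR = 0.03
_BASE_ALA = 0.08


def _codon_probabilities(tyr_multiplier: float) -> Dict[str, float]:
    sense = [c for c in ALL_CODONS if GENETIC_CODE[c] != "*"]
    tyr = list(SYNONYMOUS_FAMILIES["Y"])
    ala = list(SYNONYMOUS_FAMILIES["A"])
    other = [c for c in sense if c not in tyr + ala]
    p_tyr = _BASE_TYR * tyr_multiplier
    p_ala = _BASE_ALA
    p_other = 1.0 - p_tyr - p_ala
    if p_other <= 0:
        raise ValueError("tyr_multiplier too large for the baseline composition")
    probs = {c: p_other / len(other) for c in other}
    # preferred-codon split within the families (UAC over UAU, roughly 70:30)
    probs[tyr[0]] = 0.3 * p_tyr if tyr[0] == "TAT" else 0.7 * p_tyr
    probs[tyr[1]] = p_tyr - probs[tyr[0]]
    for c in ala:
        probs[c] = p_ala / len(ala)
    return probs


def make_cds_set(
    n_target: int = 30,
    n_reference: int = 30,
    codons_per_cds: int = 500,
    tyr_multiplier: float = 2.0,
    seed: int = 0,
) -> Tuple[Dict[str, str], Dict[str, str], pd.DataFrame]:
    """Codon-biased CDS sets: a target group with Tyr codon frequency scaled
    by ``tyr_multiplier`` against a reference group at baseline.

    Codons are drawn i.i.d. from the two compositions; each CDS starts with
    ATG and ends with a stop.  Returns (target FASTA dict, reference FASTA
    dict, truth table with the generating frequencies).
    """
    rng = _rng(seed)

    def build(n_seqs: int, mult: float, prefix: str) -> Dict[str, str]:
        probs = _codon_probabilities(mult)
        codons = list(probs)
        p = np.array([probs[c] for c in codons])
        p /= p.sum()
        out = {}
        for i in range(n_seqs):
            draw = rng.choice(codons, size=codons_per_cds - 2, p=p)
            out[f"{prefix}{i + 1}"] = "ATG" + "".join(draw) + "TAA"
        return out

    target = build(n_target, tyr_multiplier, "target_") if n_target else {}
    reference = build(n_reference, 1.0, "ref_") if n_reference else {}
    truth = pd.DataFrame([
        {"group": "target", "tyr_frequency": _BASE_TYR * tyr_multiplier,
         "ala_frequency": _BASE_ALA},
        {"group": "reference", "tyr_frequency": _BASE_TYR, "ala_frequency": _BASE_ALA},
    ])
    return target, reference, truth


def make_microarray(
    n_genes: int = 30,
    n_effects: int = 15,
    effect_fold: float = 2.0,
    n_replicates: int = 3,
    probes_per_gene: int = 2,
    time_points: Sequence[str] = ("NBF", "12H", "24H"),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Probe-level expression matrix with a subset of truly affected genes.

    The first ``n_effects`` genes change by ``effect_fold`` at every
    post-reference time point; probe values get multiplicative Gaussian
    noise on the log scale.  Returns (expression, probe_map, truth).
    """
    rng = _rng(seed)
    expr_rows, map_rows, truth_rows = [], [], []
    for g in range(1, n_genes + 1):
        gene = f"gene{g}"
        affected = g <= n_effects
        base = float(rng.uniform(50, 500))
        truth_rows.append({"gene": gene, "affected": affected,
                           "true_fold": effect_fold if affected else 1.0})
        probes = [f"{gene}_p{k}" for k in range(1, probes_per_gene + 1)]
        for probe in probes:
            map_rows.append({"probe": probe, "gene": gene})
        for t in time_points:
            level = base * (effect_fold if (affected and t != time_points[0]) else 1.0)
            for rep in range(1, n_replicates + 1):
                sample = f"{t}-{rep}"
                for probe in probes:
                    expr_rows.append({
                        "probe": probe, "sample": sample, "time": t,
                        "value": level * float(np.exp(rng.normal(0.0, noise_sd))),
                    })
    return pd.DataFrame(expr_rows), pd.DataFrame(map_rows), pd.DataFrame(truth_rows)


def make_tpm_table(
    n_background: int = 20,
    n_exclusive: int = 8,
    conditions: Sequence[str] = ("NBF", "PBF"),
    exclusive_condition: str = "PBF",
    n_replicates: int = 3,
    dispersion: float = 0.25,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """TPM table with transcripts expressed exclusively in one condition.

    Background transcripts are expressed (TPM well above 1) everywhere;
    exclusive transcripts are expressed only in ``exclusive_condition`` and
    near zero elsewhere.  Returns (tpm table, truth table).
    """
    rng = _rng(seed)
    rows, truth = [], []
    for i in range(1, n_background + 1):
        tid = f"bg{i}"
        truth.append({"transcript": tid, "exclusive_to": ""})
        base = float(rng.uniform(5, 200))
        for cond in conditions:
            for rep in range(1, n_replicates + 1):
                rows.append({"transcript": tid, "condition": cond,
                             "sample": f"{cond}-{rep}",
                             "tpm": base * float(_lognormal_factor(rng, dispersion))})
    for i in range(1, n_exclusive + 1):
        tid = f"excl{i}"
        truth.append({"transcript": tid, "exclusive_to": exclusive_condition})
        base = float(rng.uniform(5, 50))
        for cond in conditions:
            for rep in range(1, n_replicates + 1):
                if cond == exclusive_condition:
                    tpm = base * float(_lognormal_factor(rng, dispersion))
                else:
                    tpm = float(rng.uniform(0.0, 0.2))
                rows.append({"transcript": tid, "condition": cond,
                             "sample": f"{cond}-{rep}", "tpm": tpm})
    return pd.DataFrame(rows), pd.DataFrame(truth)
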