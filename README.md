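# trnamod

Tools for locating and quantifying post-transcriptional tRNA modifications by
mass spectrometry, with supporting reference-building and codon-usage
statistics. The package grew out of a concrete biological question: in the
mosquito *Aedes aegypti*, which hypermodified base sits at the wobble
position (34) of tyrosine tRNA, and how do tRNA modification levels and
transcripts shift across the blood-feeding/vitellogenesis time course? The
same operations apply to any organism's tRNA pool.

It is aimed at RNA mass-spectrometry groups who predict ribonuclease
digestion products of modified RNA, interpret their oligonucleotide MS/MS
spectra, quantify modified nucleosides from extracted-ion-chromatogram (XIC)
peak areas, and relate those measurements to tRNA gene expression and codon
demand.

## What it computes

**In-silico digestion.** RNase T1 cleaves 3′ of unmodified guanosine
(products end in a 3′-linear phosphate, "p"); cusativin cleaves 3′ of
cytidine, skips CpC bonds, and leaves 2′,3′-cyclic phosphates (">p"). Both
are blocked by modification of the cleavage-site residue. Products are
enumerated with configurable missed cleavages, and zero-missed-cleavage
products always partition the parent.

**Oligonucleotide masses.** For a product of residues r₁…rₙ, the neutral
monoisotopic mass is M = Σ m(rᵢ) + terminal adjustment, where m(r) is the
nucleoside-5′-monophosphate residue mass (nucleoside + HPO₃ − H₂O) and the
adjustment books the free-end water and terminal phosphates (zero for a
cyclic phosphate, which loses the water). Negative-mode m/z at charge z is
(M − z·1.007276)/z. Collision-induced dissociation of the backbone gives the
complementary c/y ion series with cᵢ + yₙ₋ᵢ = M + H₂O.

**Spectrum matching and localization.** Observed peak lists (MGF or TSV) are
filtered by precursor m/z over charges 1–5, scored by the fraction of
theoretical c/y ions matched (greedy nearest-peak assignment, each peak
consumed once, intensity ignored), and a modification is localized by
ranking one candidate per legal placement plus the unmodified sequence.

**Nucleoside quantification.** XIC peak areas are normalized per sample by
the summed canonical (A, G, C, U) areas; fold changes are taken against the
non-blood-fed (NBF) mean; per-nucleoside time-course effects use OLS with a
categorical time factor, and modification–enzyme interactions use per-pair
OLS with expression, treatment and time terms (type-II F per term).

**References and codon usage.** tRNAscan-SE 2.0 output plus a genome yields
precursor sequences (exact duplicates collapsed, isodecoders kept) and
mature sequences (intron excised, CCA appended); expression is called at
TPM > 1 (strict). Codon counting gives per-codon frequencies and RSCU
(count over synonymous-family mean), and family enrichment between two
transcript sets is an exact two-sided Fisher test computed by integer
hypergeometric enumeration.

Seeded generators (`trnamod.simulate`) produce synthetic gene sets, spectra,
peak-area tables, expression matrices and codon-biased CDS sets with truth
tables, so every stage is testable without downloads.

## Worked example

```python
from trnamod import parse_sequence, digest, RNASE_T1, neutral_mass, mz
from trnamod.masses import nucleoside_mz

arm = parse_sequence("GGACU[manQ]UAGAUCCUUG")   # Tyr anticodon region
for product in digest(arm, RNASE_T1):
    M = neutral_mass(product.sequence)
    print(f"{str(product.sequence):16s} M={M:9.4f}  m/z(3-)={mz(M, 3):8.4f}")
print(f"manQ nucleoside [M+H]+ = {nucleoside_mz('manQ'):.4f}")
```

prints

```
Gp               M= 363.0580  m/z(3-)=120.0121
Gp               M= 363.0580  m/z(3-)=120.0121
ACU[manQ]UAGp    M=2571.4233  m/z(3-)=856.1338
AUCCUUG          M=2140.3027  m/z(3-)=712.4269
manQ nucleoside [M+H]+ = 572.2204
```

The third product is the anticodon-spanning oligonucleotide: RNase T1 cut
after each unmodified G but not at the mannosyl-queuosine (manQ), and the
resulting m/z 856 at charge 3− is the diagnostic precursor for placing manQ
at the wobble position. The free-nucleoside value 572.2204 is the positive-
mode XIC channel used to quantify manQ.

A command-line interface mirrors the library
(`trnamod digest|mass|match|quantify|build-ref|codon|simulate|run-all`);
`trnamod run-all --seed 11 --outdir out/` exercises the whole pipeline on
synthetic fixtures and is byte-reproducible for a fixed seed.

## Layout

- `trnamod.chem` — atomic masses, modification registry, sequence parsing
- `trnamod.digestion` — ribonuclease rules and product enumeration
- `trnamod.masses` — neutral masses, m/z, c/y fragment series
- `trnamod.matching` — peak lists, precursor/fragment matching, localization
- `trnamod.quant` — normalization, fold changes, linear models
- `trnamod.reference` — tRNAscan-SE parsing, maturation, expression calls
- `trnamod.codons` — codon counts, RSCU, exact Fisher enrichment
- `trnamod.simulate` — seeded synthetic-data generators with truth tables
- `trnamod.cli` — click CLI over all of the above

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical choices.
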