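# Methods

This note records the models, conventions and numerical choices behind
`trnamod`, and what the synthetic-data tests do and do not establish.

## Monomer registry and masses

Residue masses are derived, not tabulated: every registry entry stores
either a full nucleoside elemental formula (the four canonicals, e.g.
guanosine C₁₀H₁₃N₅O₅) or a signed elemental increment against its parent
nucleoside (e.g. mannosyl-queuosine = queuosine C₁₇H₂₃N₅O₇ + one hexose
C₆H₁₀O₅ − guanosine, a +288.12090 Da increment on G). The residue mass is
nucleoside + HPO₃ − H₂O. Atomic monoisotopic masses are the standard NIST
values; only monoisotopic masses are supported (no average masses or
isotope envelopes). Isomers (Ψ/U, manQ/galQ) are mass-identical but remain
distinct codes — the registry distinguishes chemistry the mass spectrometer
cannot. mcm⁵s²U is included although it is frequently below detection in
insect samples; carrying it costs nothing. Users can extend or override the
registry with a four-column TSV (code, name, parent, formula-or-increment;
a leading sign marks an increment).

Positions are 1-based throughout, matching tRNA nomenclature (wobble = 34).

## Digestion rules

"Enzymes generally do not cleave at modifications" is implemented as: any
modification of the cleavage-site residue blocks cleavage; the downstream
residue's modification state is irrelevant. This is the simplest rule
consistent with the observed retained manQ-containing products. The
cusativin CpC rule (no cleavage between consecutive cytidines) is applied
to parent bases regardless of modification status of either C, since the
rule is stated without qualification; whether cusativin cleaves after a
modified C followed by a non-C is not established — under our rule it does
not. RNase T1 products carry 3′-linear phosphates and cusativin products
2′,3′-cyclic phosphates, following the community "p"/">p" notation; an
`RNase` instance with a different `product_three_prime` covers cyclic T1
intermediates if needed. The 3′-terminal product inherits the parent's 3′
chemistry, the first product its 5′ chemistry, and downstream fragments get
5′-OH.

## Mass and fragment conventions

Neutral mass bookkeeping: M = Σ residues + H₂O + HPO₃·(p − n), where p is
the number of phosphates implied by the termini (n−1 internal linkages plus
one per phosphorylated terminus) and a cyclic 3′-phosphate additionally
loses the water. Negative-mode m/z subtracts 1.007276 (a proton) per
charge. Positive-mode nucleoside adducts add 1.007825 (a hydrogen atom) by
default — the convention under which the manQ channel is 572.2204 — with a
`proton` switch for the stricter convention (the two differ by the electron
mass, 0.00055).

Charge states for the reported oligonucleotide integers are not annotated
on the spectra; searching charges 1–5, only 3− reproduces all four printed
values simultaneously, so 3− is used for those checks and the matcher never
assumes a charge. Only the c/y series is computed (the series used to read
oligonucleotide CID spectra); a/w ions are an extension point.

## Matching and localization

Scoring is presence/absence: matched theoretical c/y ions (charges 1−, 2−)
over total, with greedy smallest-error assignment and each observed peak
consumed once. Intensity is deliberately ignored — it mirrors the
qualitative manual reading of ion-trap spectra and makes the score
invariant to peak-list permutation and intensity rescaling. Defaults are
10 ppm precursor tolerance (Orbitrap-class) and 0.5 Da fragment tolerance
(linear ion trap); both are arguments everywhere. Localization scores one
candidate per legal placement (parent base must match) plus the unmodified
sequence, ranking by score with ties broken by smaller mean absolute
fragment error. Duplicate instrument runs are reported per run; no merging
rule is imposed.

## Quantification models

Normalization divides each nucleoside's XIC area by the sample's summed
canonical areas, cancelling input-amount and matrix effects (the role the
internal standard plays on the instrument). Closure is enforced exactly:
the last canonical fraction is set to the correctly rounded complement of
the other three, so the exact sum of the four canonical fractions is 1.0
(a sub-ulp adjustment). A modification absent from a sample is a missing
value, never zero — non-detection is censoring, not absence — and missing
values are excluded from fits.

The per-nucleoside time-course test is OLS with time as a categorical
factor and the overall F-test (a one-way ANOVA); a response with no
variance is reported as F = 0, p = 1. The modification–enzyme interaction
analysis is realized as per-pair univariate OLS of modification level on a
single enzyme's expression plus treatment and time factors, with type-II F
and p per term; uninformative terms (constant expression, single-level
factors) are dropped, so with constant expression and one factor the fit
reduces exactly to the one-way ANOVA. A multivariate formulation would
also be defensible; the per-pair layout is what per-pair, per-term result
tables require. p < 0.05 is the default call with no multiplicity
correction, matching common practice for these screens; a
Benjamini–Hochberg switch is available and off by default. Microarray
probe values are averaged per gene per sample before any fold change or
model. Heatmaps display log2 fold change (display choice only).

## Reference building

tRNAscan-SE 2.0 coordinates are 1-based inclusive; minus-strand genes
(begin > end) are reverse-complemented so stored sequences are transcribed
precursors, and intron bounds (0,0 = none) are converted to sequence-local
coordinates at the parse boundary. Maturation removes the intron and
appends CCA; no other edits (in particular no His 5′-G addition) are
applied. Precursor deduplication is exact-sequence only, keeping the first
id and recording provenance; isodecoders differing by one nucleotide are
kept. TPM exactly 1 is called *not expressed* (the threshold is strictly
greater-than; the boundary case is otherwise unassigned). Condition
exclusivity uses per-condition mean TPM: expressed (mean > 1) in exactly
one condition. Read trimming, quantification and differential expression
are consumed as TPM tables, not reimplemented.

## Codon statistics

RSCU(c) = count(c) / mean count of c's synonymous family; stop codons are
counted but carry no RSCU; unused families are undefined rather than zero.
The enrichment test is a two-sided Fisher exact test on raw codon counts
([[Tyr_A, Ala_A], [Tyr_B, Ala_B]]) — counts, not percentages, because an
exact test is only valid on counts. The p-value is computed by exact
integer hypergeometric enumeration with the standard 1e-7 relative tie
tolerance applied in integer arithmetic, so no floating-point rounding
enters the tail decision; tests cross-check it against an independent
floating-point enumeration over every 2×2 table with all margins ≤ 50
(~1.2 million tables) and against `scipy.stats.fisher_exact` on a random
subsample. U and T are interchangeable in CDS input; trailing partial
codons are truncated with a tally; ambiguous codons are skipped with a
tally.

## Synthetic data: what it emulates, what it does not

Generators are deterministic under a seed and emit truth tables. Peak-area
tables use lognormal multiplicative noise (positive, matrix-effect-like),
parameterized by CV, around fixed canonical means with a lognormal
per-sample input-amount factor; defaults are three replicates per time
point and 10% CV, the scale of careful UHPLC nucleoside work. Planted
per-time-point fold changes act on the true normalized abundance. Spectra
are c/y ions at 1−/2− with optional Gaussian m/z jitter and uniform decoy
peaks across the m/z 600–2000 acquisition window. Gene sets are random
sequence bodies (synthetic — they have no tRNA fold) of 72 nt with 13-nt
introns at position 38 in the three intron-bearing families (Ile-TAT,
Leu-CAA, Tyr-GTA), with planted exact duplicates; the default 200 genes
with 42 duplicates leaves 158 unique precursors, the scale of a mosquito
high-confidence set. CDS sets draw codons i.i.d. with Tyr at 3% baseline
(target set scaled by the enrichment factor, default 2), Ala at 8%, and a
70:30 UAC:UAU split.

Consequently, passing tests establish correctness of the algorithms and
statistics under the stated noise models — they do not establish that real
chromatograms are free of co-elution artefacts, that real spectra contain
only c/y ions, or that real tRNA genes are random sequences. Retention
time, isotope envelopes and vendor raw formats are out of scope.

## Problem sizes and tolerances in the test suite

Mass identities are asserted at 1e-6 Da (fragment complementarity over
1,000 random products), registry self-consistency at 1e-4 Da, and printed
m/z values at their printed precision. The digestion engine is checked
against a brute-force per-bond oracle on 200 random modified 30-mers per
enzyme. Localization is evaluated on 100 random 8–12-mers (noiseless: all
correct; 10:1 decoys at 0.5 Da: ≥95 correct). Fold-change recovery uses
500 simulations at n = 3, CV 10% (planted 0.5× and 2× recovered within
±20% in ≥95%). These sizes keep the full suite under a minute of compute
for the exhaustive Fisher check and a few tens of seconds for everything
else.
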