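"""Mature and precursor tRNA reference construction and expression calls.

tRNA gene predictions (tRNAscan-SE 2.0 tabular output plus the genome) are
turned into two reference sets: precursor sequences (the transcribed gene
body, deduplicated exactly — isodecoders differing by any nucleotide are
kept) and mature sequences (intron excised, ``CCA`` appended to the 3' end).
Expression of a transcript in a small-RNAseq quantification is called from
TPM with the strict threshold TPM > 1; condition-exclusive sets use the
per-condition mean TPM.

Coordinates are 1-based inclusive throughout, matching tRNAscan-SE; on the
minus strand the stored sequence is the reverse complement (the transcribed
precursor) and intron coordinates are converted to sequence-local positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["TRNAGene", "ExpressionCall", "parse_trnascan", "mature_sequence",
           "dedupe_pre", "expression_calls", "exclusive_sets", "write_fasta",
           "read_fasta"]

#: isotypes whose genes carry introns in the mosquito genome
INTRON_ISOTYPES = ("Ile-TAT", "Leu-CAA", "Tyr-GTA")


@dataclass(frozen=True)
class TRNAGene:
    """A predicted tRNA gene with its transcribed precursor sequence."""

    gene_id: str  # isotype-anticodon-locus-copy, e.g. Tyr-GTA-1-1
    isotype: str  # amino acid three-letter name as reported (e.g. Tyr)
    anticodon: str
    sequence: str  # sense-strand precursor body
    intron: Optional[Tuple[int, int]] = None  # 1-based inclusive, sequence-local
    high_confidence: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.intron is not None:
            lo, hi = self.intron
            if not (1 <= lo <= hi <= len(self.sequence)):
                raise ValueError(
                    f"{self.gene_id}: intron span {self.intron} outside 1..{len(self.sequence)}"
                )

    @property
    def has_intron(self) -> bool:
        return self.intron is not None


@dataclass(frozen=True)
class ExpressionCall:
    transcript_id: str
    tpm: float
    expressed: bool  # TPM > 1 (strict)


class TrnascanFormatError(ValueError):
    pass


def _parse_int(value: str, what: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise TrnascanFormatError(f"line {lineno}: bad {what} {value!r}") from None


def parse_trnascan(
    out_path: str | Path,
    genome: Mapping[str, str] | str | Path,
    high_confidence_only: bool = False,
) -> List[TRNAGene]:
    """Parse tRNAscan-SE 2.0 tabular output against a genome.

    Expected columns: sequence name, tRNA#, begin, end, isotype, anticodon,
    intron begin, intron end, score[, ..., note].  The three header lines
    (underlined column titles) are skipped.  ``genome`` is a FASTA path or a
    name→sequence mapping.  Minus-strand genes (begin > end) are reverse
    complemented; intron bounds 0,0 mean no intron.  Genes whose note marks
    them pseudo/truncated lose the high-confidence flag, and are dropped
    entirely when ``high_confidence_only`` is set.
    """
    if not isinstance(genome, Mapping):
        genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")}
    genes: List[TRNAGene] = []
    counters: Dict[str, int] = {}
    for lineno, raw in enumerate(Path(out_path).read_text().splitlines(), 1):
        line = raw.rstrip()
        if not line:
            continue
        low = line.lower()
        if low.startswith(("sequence", "name", "----")) or "trna #" in low:
            continue  # header block
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 9:
            raise TrnascanFormatError(f"line {lineno}: expected >=9 tab-separated columns")
        chrom = fields[0]
        begin = _parse_int(fields[2], "begin", lineno)
        end = _parse_int(fields[3], "end", lineno)
        isotype = fields[4]
        anticodon = fields[5].upper().replace("U", "T")
        ib = _parse_int(fields[6], "intron begin", lineno)
        ie = _parse_int(fields[7], "intron end", lineno)
        note = fields[-1] if len(fields) > 9 else ""
        if chrom not in genome:
            raise TrnascanFormatError(f"line {lineno}: sequence {chrom!r} not in genome")
        chrom_seq = genome[chrom].upper()
        minus = begin > end
        lo, hi = (end, begin) if minus else (begin, end)
        if not (1 <= lo <= hi <= len(chrom_seq)):
            raise TrnascanFormatError(f"line {lineno}: span {begin}-{end} outside {chrom!r}")
        seq = chrom_seq[lo - 1 : hi]
        if minus:
            seq = str(Seq(seq).reverse_complement())
        intron: Optional[Tuple[int, int]] = None
        if not (ib == 0 and ie == 0):
            g_lo, g_hi = min(ib, ie), max(ib, ie)
            if minus:
                local = (hi - g_hi + 1, hi - g_lo + 1)
            else:
                local = (g_lo - lo + 1, g_hi - lo + 1)
            intron = local
        hc = not any(tag in note.lower() for tag in ("pseudo", "trunc"))
        if high_confidence_only and not hc:
            continue
        family = f"{isotype}-{anticodon}"
        counters[family] = counters.get(family, 0) + 1
        gene_id = f"{family}-{counters[family]}-1"
        genes.append(TRNAGene(gene_id, isotype, anticodon, seq, intron, hc, note))
    return genes


def mature_sequence(gene: TRNAGene) -> str:
    """Mature tRNA body: intron excised, ``CCA`` appended to the 3' end.

    Length is precursor − intron + 3.  Operates on gene objects only, so it
    cannot be re-applied to an already-matured sequence by construction.
    """
    seq = gene.sequence
    if gene.intron is not None:
        lo, hi = gene.intron
        seq = seq[: lo - 1] + seq[hi:]
    return seq + "CCA"


def dedupe_pre(genes: Iterable[TRNAGene]) -> Tuple[List[TRNAGene], pd.DataFrame]:
    """Collapse exact precursor-sequence duplicates, keeping the first id.

    Isodecoders (any single-nucleotide difference) are retained.  Returns
    (unique genes, provenance table with columns kept_id, duplicate_id).
    """
    seen: Dict[str, str] = {}
    unique: List[TRNAGene] = []
    dup_rows = []
    for gene in genes:
        kept = seen.get(gene.sequence)
        if kept is None:
            seen[gene.sequence] = gene.gene_id
            unique.append(gene)
        else:
            dup_rows.append({"kept_id": kept, "duplicate_id": gene.gene_id})
    return unique, pd.DataFrame(dup_rows, columns=["kept_id", "duplicate_id"])


def expression_calls(tpm: pd.DataFrame) -> List[ExpressionCall]:
    """Expression calls per (transcript, sample) row: expressed ⇔ TPM > 1.

    ``tpm`` columns: transcript, tpm (sample/condition columns carried
    through by callers that need them).  Negative TPM is rejected.
    """
    if "transcript" not in tpm.columns or "tpm" not in tpm.columns:
        raise ValueError("tpm table needs 'transcript' and 'tpm' columns")
    if (tpm["tpm"] < 0).any():
        bad = tpm.loc[tpm["tpm"] < 0, "transcript"].iloc[0]
        raise ValueError(f"negative TPM for transcript {bad!r}")
    return [
        ExpressionCall(row.transcript, float(row.tpm), float(row.tpm) > 1.0)
        for row in tpm.itertuples()
    ]


def exclusive_sets(tpm: pd.DataFrame) -> Dict[str, List[str]]:
    """Transcripts expressed exclusively in one condition.

    ``tpm`` columns: transcript, condition, tpm (replicates as repeated
    rows).  A transcript is exclusive to condition X when its mean TPM is
    > 1 in X and ≤ 1 in every other condition.
    """
    for col in ("transcript", "condition", "tpm"):
        if col not in tpm.columns:
            raise ValueError(f"tpm table needs a {col!r} column")
    if (tpm["tpm"] < 0).any():
        raise ValueError("negative TPM")
    means = tpm.groupby(["transcript", "condition"])["tpm"].mean().unstack(fill_value=0.0)
    out: Dict[str, List[str]] = {cond: [] for cond in means.columns}
    for transcript, row in means.iterrows():
        expressed = row > 1.0
        if expressed.sum() == 1:
            out[expressed.idxmax()].append(transcript)
    return out


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
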