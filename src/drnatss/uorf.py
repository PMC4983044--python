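"""Upstream ORFs in long 5'-UTRs, peptide pI/MW, small-protein TSS counts,
and the intergenic-concatenation utility.

pI uses the EMBOSS pKa set with a bisection root of the net-charge curve;
MW uses average residue masses (one water added).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

from .classify import ClassifiedTss, PROTEIN_CLASSES
from .genome import GenomeModel

STOP_CODONS = {"TAA", "TAG", "TGA"}
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# EMBOSS pKa values
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_POSITIVE = {"H": 6.5, "K": 10.8, "R": 12.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

LINKER = "TTAATTAATTAA"  # stop codons in all six reading frames


@dataclass(frozen=True)
class UorfRecord:
    parent_tss: str
    start_offset: int      # 0-based, from the UTR 5' end
    peptide: str
    pi: float
    mw: float

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide")
        if self.mw <= 0 or not 0 < self.pi < 14:
            raise ValueError("implausible peptide properties")

    @property
    def length(self) -> int:
        return len(self.peptide)


def _check_peptide(peptide: str) -> None:
    if not peptide:
        raise ValueError("empty peptide")
    bad = set(peptide) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residue(s): {sorted(bad)}")


def peptide_charge(peptide: str, ph: float) -> float:
    """Net charge at a given pH: Henderson-Hasselbalch terms for the
    N-terminus, C-terminus and ionizable side chains."""
    _check_peptide(peptide)
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10 ** (PKA_CTERM - ph))
    for residue, pka in PKA_POSITIVE.items():
        charge += peptide.count(residue) / (1.0 + 10 ** (ph - pka))
    for residue, pka in PKA_NEGATIVE.items():
        charge -= peptide.count(residue) / (1.0 + 10 ** (pka - ph))
    return charge


def peptide_pi(peptide: str, tolerance: float = 1e-3) -> float:
    """Isoelectric point: bisection root of the net charge on [0, 14]."""
    _check_peptide(peptide)
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = (lo + hi) / 2.0
        if peptide_charge(peptide, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def peptide_mw(peptide: str) -> float:
    """Average molecular weight in Da (residue masses plus one water)."""
    _check_peptide(peptide)
    return float(molecular_weight(peptide, seq_type="protein", monoisotopic=False))


def find_uorfs(
    utr_sequence: str,
    parent_tss: str = "",
    min_len: int = 15,
    start_codons: tuple[str, ...] = ("ATG",),
) -> list[UorfRecord]:
    """ATG...in-frame-stop ORFs fully contained in a 5'-UTR (mRNA strand,
    5'->3') with peptide length >= min_len; overlapping ORFs all reported,
    sorted by start offset."""
    utr = utr_sequence.upper()
    records = []
    for start in range(len(utr) - 2):
        if utr[start : start + 3] not in start_codons:
            continue
        for stop in range(start + 3, len(utr) - 2, 3):
            codon = utr[stop : stop + 3]
            if codon in STOP_CODONS:
                peptide = str(Seq(utr[start:stop]).translate(table=11))
                if len(peptide) >= min_len:
                    records.append(
                        UorfRecord(parent_tss, start, peptide,
                                   peptide_pi(peptide), peptide_mw(peptide))
                    )
                break
    return sorted(records, key=lambda r: r.start_offset)


def count_small_protein_tss(
    classified: list[ClassifiedTss], genome: GenomeModel, max_len: int = 100
) -> int:
    """Protein-coding TSSs whose gene encodes <= max_len amino acids
    (CDS length / 3 - 1, excluding the stop codon)."""
    count = 0
    for c in classified:
        if c.primary_class not in PROTEIN_CLASSES:
            continue
        gene = genome.feature_by_id(c.associated_gene)
        if gene.length // 3 - 1 <= max_len:
            count += 1
    return count


def concat_intergenic(
    regions: list[str], chunk_range: tuple[int, int] = (2000, 3000), linker: str = LINKER
) -> list[str]:
    """Concatenate intergenic regions (sorted by length) with a stop-codon
    linker and split into 2-3 kb chunks, never splitting inside a region.

    A chunk exceeds the upper bound only when a single region does; the final
    chunk may fall short of the lower bound.
    """
    if not regions:
        raise ValueError("no regions")
    lo, hi = chunk_range
    chunks: list[str] = []
    current = ""
    for region in sorted(regions, key=len):
        if not current:
            current = region
        elif len(current) >= lo or len(current) + len(linker) + len(region) > hi:
            chunks.append(current)
            current = region
        else:
            current = current + linker + region
    if current:
        chunks.append(current)
    return chunks


def uorf_table(records: list[UorfRecord]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {
            "parent_tss": [r.parent_tss for r in records],
            "start_offset": [r.start_offset for r in records],
            "length_aa": [r.length for r in records],
            "peptide": [r.peptide for r in records],
            "pI": [round(r.pi, 2) for r in records],
            "MW": [round(r.mw, 1) for r in records],
        }
    )


def uorfs_in_long_utrs(
    classified: list[ClassifiedTss],
    genome: GenomeModel,
    min_utr: int = 150,
    max_utr: int = 250,
    min_len: int = 15,
) -> list[UorfRecord]:
    """Scan every leadered TSS with a very long UTR (150-250 nt) for uORFs."""
    records = []
    for c in classified:
        if c.primary_class != "leadered" or not min_utr <= c.utr_length <= max_utr:
            continue
        gene = genome.feature_by_id(c.associated_gene)
        if gene.strand == "+":
            utr = genome.subsequence(c.record.replicon, c.position, gene.start - 1, "+")
        else:
            utr = genome.subsequence(c.record.replicon, gene.end + 1, c.position, "-")
        tss_id = f"{c.record.replicon}:{c.position}:{c.strand}"
        records.extend(find_uorfs(utr, tss_id, min_len=min_len))
    return records
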