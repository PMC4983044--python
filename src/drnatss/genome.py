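"""Genome sequence plus annotated features.

Coordinates are 1-based inclusive throughout (GFF3 convention). A feature's
5' end is its ``start`` on the forward strand and its ``end`` on the reverse
strand; distances between a TSS and a gene are always measured in the
direction of transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import reverse_complement

#: annotation categories for protein-coding genes (transposases encode
#: proteins and obey the same TSS distance rules; the category only matters
#: for the category-overlap counts).
PROTEIN_CODING = frozenset({"CDS", "transposase"})
KNOWN_RNA = "known_rna"

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class Feature:
    """One annotated gene (1-based inclusive coordinates)."""

    feature_id: str
    replicon: str
    start: int
    end: int
    strand: str
    category: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end < self.start:
            raise ValueError(f"{self.feature_id}: end < start")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def is_protein_coding(self) -> bool:
        return self.category in PROTEIN_CODING


@dataclass
class GenomeModel:
    """Replicon sequences and their annotated features."""

    sequences: dict[str, str]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            if f.replicon not in self.sequences:
                raise ValueError(f"{f.feature_id}: unknown replicon {f.replicon}")
            if f.end > len(self.sequences[f.replicon]):
                raise ValueError(f"{f.feature_id}: outside replicon")

    def length(self, replicon: str) -> int:
        return len(self.sequences[replicon])

    @property
    def replicons(self) -> list[str]:
        return list(self.sequences)

    def features_on(self, replicon: str) -> list[Feature]:
        return [f for f in self.features if f.replicon == replicon]

    def feature_by_id(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def subsequence(self, replicon: str, start: int, end: int, strand: str = "+") -> str:
        """On-strand sequence of [start, end] (1-based inclusive)."""
        seq = self.sequences[replicon]
        if start < 1 or end > len(seq):
            raise ValueError(f"[{start}, {end}] outside replicon {replicon}")
        sub = seq[start - 1 : end]
        return sub if strand == "+" else reverse_complement(sub)

    def feature_sequence(self, feature: Feature) -> str:
        """Coding-strand sequence of a feature (start codon first)."""
        return self.subsequence(feature.replicon, feature.start, feature.end, feature.strand)

    def gc_content(self) -> float:
        gc = total = 0
        for seq in self.sequences.values():
            gc += seq.count("G") + seq.count("C")
            total += len(seq)
        if total == 0:
            raise ValueError("empty genome")
        return gc / total


def encode(seq: str) -> np.ndarray:
    """Map an ACGT string to integer codes (ValueError on other letters)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        bad = seq[int(np.argmax(out < 0))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return out
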