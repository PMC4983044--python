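"""Strand-specific 5'-read-start coverage tracks.

A track stores, for one replicon strand of one library, the number of reads
whose 5' end maps to each base. This is what TSS calling consumes; full
read-body coverage is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

MINUS_TEX = "minus_tex"
PLUS_TEX = "plus_tex"


@dataclass
class CoverageTrack:
    replicon: str
    strand: str
    values: np.ndarray
    treatment: str
    replicate: int
    mapped_reads: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.treatment not in (MINUS_TEX, PLUS_TEX):
            raise ValueError(f"bad treatment {self.treatment!r}")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    @property
    def library(self) -> str:
        """Library label, e.g. ``rep1_plus_tex``."""
        return f"rep{self.replicate}_{self.treatment}"

    def scaled(self, factor: float) -> "CoverageTrack":
        return replace(self, values=self.values * factor)

    def value_at(self, position: int) -> float:
        """Coverage at a 1-based position."""
        return float(self.values[position - 1])
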