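"""UTR-length, expression-decile, start-codon and coding-composition analyses."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassifiedTss, PROTEIN_CLASSES
from .genome import GenomeModel

logger = logging.getLogger(__name__)

LEADER_BIN_START = 6
LEADER_BIN_WIDTH = 10
LEADER_MAX = 250


def utr_histograms(classified: list[ClassifiedTss]) -> tuple[pd.Series, pd.Series]:
    """(extension_counts, leader_bins).

    extension_counts[d] counts protein-coding TSSs with UTR length d for
    d = 0..20; leader_bins counts leadered TSSs in 10-nt distance groups
    starting at 6 nt ([6-15], [16-25], ..., [246-250]).
    """
    utrs = [c.utr_length for c in classified if c.primary_class in PROTEIN_CLASSES]
    extension = pd.Series(0, index=range(21), name="count")
    for u in utrs:
        if u <= 20:
            extension[u] += 1

    edges = list(range(LEADER_BIN_START, LEADER_MAX + 2, LEADER_BIN_WIDTH))
    labels = [f"{lo}-{min(lo + LEADER_BIN_WIDTH - 1, LEADER_MAX)}" for lo in edges[:-1]] + [
        f"{edges[-1]}-{LEADER_MAX}"
    ]
    leader = pd.Series(0, index=labels, name="count")
    for c in classified:
        if c.primary_class != "leadered":
            continue
        bin_index = (c.utr_length - LEADER_BIN_START) // LEADER_BIN_WIDTH
        leader.iloc[bin_index] += 1
    return extension, leader


@dataclass
class ExpressionDeciles:
    """Top and bottom 10 % of TSSs by average coverage, with per-class counts."""

    top: list[ClassifiedTss]
    bottom: list[ClassifiedTss]

    def class_counts(self) -> pd.DataFrame:
        rows = []
        for name, group in (("bottom", self.bottom), ("top", self.top)):
            counts = pd.Series([c.primary_class for c in group]).value_counts()
            for cls, n in counts.items():
                rows.append({"decile": name, "primary_class": cls, "count": int(n)})
        return pd.DataFrame(rows, columns=["decile", "primary_class", "count"])


def expression_deciles(classified: list[ClassifiedTss]) -> ExpressionDeciles:
    """Lowest and highest floor(N/10) TSSs by average coverage.

    Ties are broken by (coverage, position) so the split is deterministic.
    """
    n = len(classified)
    if n < 20:
        logger.warning("expression_deciles: only %d TSSs; deciles may overlap", n)
    size = n // 10
    ordered = sorted(classified, key=lambda c: (c.record.average_coverage, c.position))
    return ExpressionDeciles(top=ordered[n - size :], bottom=ordered[:size])


def start_codon_summary(
    classified: list[ClassifiedTss], genome: GenomeModel
) -> tuple[pd.DataFrame, pd.Series]:
    """Start-codon usage of leaderless transcripts.

    Returns (summary, gtg_extensions): per start codon (ATG/GTG/TTG/other)
    the TSS count and mean average coverage, plus the 0-5 nt extension
    distribution of GTG-start leaderless transcripts.
    """
    buckets: dict[str, list[ClassifiedTss]] = {"ATG": [], "GTG": [], "TTG": [], "other": []}
    gtg_ext = pd.Series(0, index=range(6), name="count")
    for c in classified:
        if c.primary_class != "leaderless":
            continue
        gene = genome.feature_by_id(c.associated_gene)
        codon = genome.feature_sequence(gene)[:3]
        key = codon if codon in buckets else "other"
        buckets[key].append(c)
        if codon == "GTG":
            gtg_ext[c.utr_length] += 1
    rows = []
    for codon, group in buckets.items():
        rows.append(
            {
                "start_codon": codon,
                "count": len(group),
                "mean_coverage": float(np.mean([c.record.average_coverage for c in group]))
                if group
                else np.nan,
            }
        )
    return pd.DataFrame(rows), gtg_ext


def codon_position_composition(cds_sequences: list[str]) -> pd.Series:
    """Fraction of codons with A or T at codon positions 1, 2, 3 (plus the
    overall A/T fraction); trailing bases of non-triplet sequences are
    ignored with a warning."""
    at_counts = np.zeros(3)
    total_codons = 0
    at_all = all_bases = 0
    for seq in cds_sequences:
        if len(seq) % 3:
            logger.warning("codon_position_composition: length %d not divisible by 3", len(seq))
        n = len(seq) // 3
        total_codons += n
        for j in range(3):
            at_counts[j] += sum(1 for i in range(n) if seq[3 * i + j] in "AT")
        trimmed = seq[: 3 * n]
        at_all += sum(1 for b in trimmed if b in "AT")
        all_bases += len(trimmed)
    if total_codons == 0:
        raise ValueError("no codons to tally")
    return pd.Series(
        {
            "position_1": at_counts[0] / total_codons,
            "position_2": at_counts[1] / total_codons,
            "position_3": at_counts[2] / total_codons,
            "overall": at_all / all_bases,
        }
    )


def post_start_matrix(
    cds_sequences: list[str], length: int = 97
) -> tuple[np.ndarray, int]:
    """Per-position base-frequency matrix (4 x length) of the first ``length``
    nt after the start codon; sequences too short are excluded and counted."""
    from .genome import BASES

    kept = [s[3 : 3 + length] for s in cds_sequences if len(s) >= 3 + length]
    excluded = len(cds_sequences) - len(kept)
    if not kept:
        raise ValueError("no sequence long enough")
    counts = np.zeros((4, length))
    for s in kept:
        for j, base in enumerate(s):
            counts[BASES.index(base), j] += 1
    return counts / counts.sum(axis=0, keepdims=True), excluded
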