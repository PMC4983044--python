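"""Sense/antisense reciprocity and gene-category overlap analyses."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .classify import ClassifiedTss, PROTEIN_CLASSES
from .genome import GenomeModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SenseAntisensePair:
    antisense_tss: str            # "replicon:position:strand"
    gene_id: str
    antisense_coverage: float
    sense_coverage: float
    sense_detected: bool

    def __post_init__(self) -> None:
        if self.antisense_coverage < 0 or self.sense_coverage < 0:
            raise ValueError("coverages must be >= 0")
        if self.sense_detected != (self.sense_coverage > 0):
            raise ValueError("sense_detected inconsistent with sense coverage")


@dataclass
class ReciprocityStats:
    fraction_sense_undetected: float
    spearman_rho: float | None    # over pairs with both coverages > 0
    axis_fraction: float          # min/max < 0.1 (pairs on or near an axis)
    n_pairs: int


def pair_sense_antisense(classified: list[ClassifiedTss]) -> list[SenseAntisensePair]:
    """One pair per antisense TSS: its coverage against the strongest sense
    TSS (leaderless/leadered) of the overlapped gene, 0 if none detected."""
    sense_by_gene: dict[str, float] = {}
    for c in classified:
        if c.primary_class in PROTEIN_CLASSES and c.associated_gene:
            sense_by_gene[c.associated_gene] = max(
                sense_by_gene.get(c.associated_gene, 0.0), c.record.average_coverage
            )
    pairs = []
    for c in classified:
        if c.primary_class != "antisense":
            continue
        if not c.associated_gene:
            raise ValueError(f"antisense TSS at {c.position} without overlapped gene")
        sense = sense_by_gene.get(c.associated_gene, 0.0)
        pairs.append(
            SenseAntisensePair(
                antisense_tss=f"{c.record.replicon}:{c.position}:{c.strand}",
                gene_id=c.associated_gene,
                antisense_coverage=c.record.average_coverage,
                sense_coverage=sense,
                sense_detected=sense > 0,
            )
        )
    return pairs


def reciprocity_stats(pairs: list[SenseAntisensePair]) -> ReciprocityStats:
    """Fraction of antisense TSSs without a detected sense transcript, the
    rank correlation over doubly-detected pairs, and the fraction of pairs
    lying near an axis of the sense/antisense scatter."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    undetected = np.mean([not p.sense_detected for p in pairs])
    both = [(p.sense_coverage, p.antisense_coverage) for p in pairs if p.sense_coverage > 0 and p.antisense_coverage > 0]
    rho = None
    if len(both) >= 2:
        result = spearmanr([s for s, _ in both], [a for _, a in both])
        rho = None if np.isnan(result.statistic) else float(result.statistic)
    near_axis = [
        min(p.sense_coverage, p.antisense_coverage) / max(p.sense_coverage, p.antisense_coverage) < 0.1
        for p in pairs
        if max(p.sense_coverage, p.antisense_coverage) > 0
    ]
    return ReciprocityStats(
        fraction_sense_undetected=float(undetected),
        spearman_rho=rho,
        axis_fraction=float(np.mean(near_axis)) if near_axis else 0.0,
        n_pairs=len(pairs),
    )


def category_overlap(
    classified: list[ClassifiedTss],
    genome: GenomeModel,
    category: str = "transposase",
    three_prime_fraction: float = 0.2,
) -> dict[str, int]:
    """Counts of internal/antisense TSSs overlapping genes of one annotation
    category; '3-prime-end overlap' means the TSS lies in the 3'-most
    ``three_prime_fraction`` of the gene."""
    known = {f.category for f in genome.features}
    if category not in known:
        logger.warning("category %r absent from the annotation", category)
        return {"internal_overlapping": 0, "internal_three_prime": 0, "antisense_overlapping": 0}
    counts = {"internal_overlapping": 0, "internal_three_prime": 0, "antisense_overlapping": 0}
    for c in classified:
        if c.primary_class not in ("internal", "antisense") or not c.associated_gene:
            continue
        gene = genome.feature_by_id(c.associated_gene)
        if gene.category != category:
            continue
        if c.primary_class == "antisense":
            counts["antisense_overlapping"] += 1
            continue
        counts["internal_overlapping"] += 1
        offset = c.position - gene.start if gene.strand == "+" else gene.end - c.position
        if offset >= gene.length * (1 - three_prime_fraction):
            counts["internal_three_prime"] += 1
    return counts


def pairs_to_frame(pairs: list[SenseAntisensePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "antisense_tss": [p.antisense_tss for p in pairs],
            "gene_id": [p.gene_id for p in pairs],
            "antisense_coverage": [p.antisense_coverage for p in pairs],
            "sense_coverage": [p.sense_coverage for p in pairs],
            "sense_detected": [p.sense_detected for p in pairs],
        }
    )
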