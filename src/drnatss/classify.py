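"""TSS classification by distance to annotated gene starts.

Every TSS gets exactly one class. Distances are measured in transcription
direction: d = (gene 5' start) - (TSS position) on the forward strand and
the reverse on the reverse strand; d = 0 means the TSS sits on the first
base of the start codon.

Precedence when several rules match: sense association with a protein-coding
gene start (leaderless 0 <= d <= 5, then leadered 6 <= d <= 250) beats the
known-RNA rule (-3 <= d <= 250), which beats gene overlap (same strand ->
internal, opposite -> antisense), which beats the intergenic-novel fallback.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import TssRecord
from .genome import KNOWN_RNA, Feature, GenomeModel

LEADERLESS_MAX_UTR = 5
LEADER_MAX_UTR = 250
KNOWN_RNA_RETRACTION = 3
DOWNSTREAM_FLAG_MAX = 250

CLASSES = ("leaderless", "leadered", "known_rna", "intergenic_novel", "internal", "antisense")
PROTEIN_CLASSES = ("leaderless", "leadered")
NOVEL_CLASSES = ("intergenic_novel", "antisense", "internal")


@dataclass(frozen=True)
class ClassifiedTss:
    record: TssRecord
    primary_class: str
    associated_gene: str | None
    utr_length: int | None
    downstream_gene: str | None = None
    downstream_distance: int | None = None

    def __post_init__(self) -> None:
        if self.primary_class not in CLASSES:
            raise ValueError(f"unknown class {self.primary_class!r}")
        has_utr = self.utr_length is not None
        if has_utr != (self.primary_class in PROTEIN_CLASSES):
            raise ValueError("utr_length present iff class is leaderless/leadered")
        if self.primary_class == "leaderless" and not 0 <= self.utr_length <= LEADERLESS_MAX_UTR:
            raise ValueError(f"leaderless UTR out of range: {self.utr_length}")
        if self.primary_class == "leadered" and not (
            LEADERLESS_MAX_UTR < self.utr_length <= LEADER_MAX_UTR
        ):
            raise ValueError(f"leadered UTR out of range: {self.utr_length}")

    @property
    def position(self) -> int:
        return self.record.position

    @property
    def strand(self) -> str:
        return self.record.strand


def _directional_distance(tss_position: int, feature: Feature) -> int:
    """Distance from TSS to the feature's 5' end, measured along the
    feature's direction of transcription (positive = gene start downstream)."""
    if feature.strand == "+":
        return feature.five_prime - tss_position
    return tss_position - feature.five_prime


def classify(tss: TssRecord, genome: GenomeModel) -> ClassifiedTss:
    """Assign one TSS to exactly one class (see module precedence rules)."""
    if tss.position < 1 or tss.position > genome.length(tss.replicon):
        raise ValueError(f"TSS at {tss.position} outside replicon {tss.replicon}")
    features = genome.features_on(tss.replicon)
    same = [f for f in features if f.strand == tss.strand]

    def nearest(candidates: list[tuple[int, Feature]]) -> tuple[int, Feature] | None:
        return min(candidates, key=lambda t: (abs(t[0]), t[1].feature_id), default=None)

    coding = [
        (d, f)
        for f in same
        if f.is_protein_coding
        for d in (_directional_distance(tss.position, f),)
        if 0 <= d <= LEADER_MAX_UTR
    ]
    hit = nearest([(d, f) for d, f in coding if d <= LEADERLESS_MAX_UTR])
    if hit is not None:
        return ClassifiedTss(tss, "leaderless", hit[1].feature_id, hit[0])
    hit = nearest([(d, f) for d, f in coding if d > LEADERLESS_MAX_UTR])
    if hit is not None:
        return ClassifiedTss(tss, "leadered", hit[1].feature_id, hit[0])

    known = [
        (d, f)
        for f in same
        if f.category == KNOWN_RNA
        for d in (_directional_distance(tss.position, f),)
        if -KNOWN_RNA_RETRACTION <= d <= LEADER_MAX_UTR
    ]
    hit = nearest(known)
    if hit is not None:
        return ClassifiedTss(tss, "known_rna", hit[1].feature_id, None)

    overlapping = [f for f in features if f.contains(tss.position)]
    same_overlap = [f for f in overlapping if f.strand == tss.strand]
    if same_overlap:
        cls = ClassifiedTss(tss, "internal", same_overlap[0].feature_id, None)
        return _with_downstream_flag(cls, genome)
    if overlapping:
        cls = ClassifiedTss(tss, "antisense", overlapping[0].feature_id, None)
        return _with_downstream_flag(cls, genome)

    return ClassifiedTss(tss, "intergenic_novel", None, None)


def classify_all(records: list[TssRecord], genome: GenomeModel) -> list[ClassifiedTss]:
    return [classify(r, genome) for r in records]


def flag_downstream_gene(tss: ClassifiedTss, genome: GenomeModel) -> tuple[str, int] | None:
    """For an internal/antisense TSS, the nearest same-strand annotated gene
    start 1-250 nt downstream (None if absent)."""
    if tss.primary_class not in ("internal", "antisense"):
        raise ValueError("downstream-gene flag applies to internal/antisense TSSs only")
    candidates = []
    for f in genome.features_on(tss.record.replicon):
        if f.strand != tss.strand:
            continue
        d = _directional_distance(tss.position, f)
        if 1 <= d <= DOWNSTREAM_FLAG_MAX:
            candidates.append((d, f.feature_id))
    if not candidates:
        return None
    d, gene = min(candidates)
    return gene, d


def _with_downstream_flag(tss: ClassifiedTss, genome: GenomeModel) -> ClassifiedTss:
    flag = flag_downstream_gene(tss, genome)
    if flag is None:
        return tss
    return ClassifiedTss(
        tss.record, tss.primary_class, tss.associated_gene, tss.utr_length, flag[0], flag[1]
    )


def find_multi_tss(classified: list[ClassifiedTss]) -> pd.DataFrame:
    """Protein-coding genes associated with >= 2 TSSs, with the class
    combination (e.g. ``leaderless+leadered`` or ``2xleadered``)."""
    by_gene: dict[str, list[ClassifiedTss]] = defaultdict(list)
    for c in classified:
        if c.primary_class in PROTEIN_CLASSES:
            by_gene[c.associated_gene].append(c)
    rows = []
    for gene, group in sorted(by_gene.items()):
        if len(group) < 2:
            continue
        counts = pd.Series([c.primary_class for c in group]).value_counts()
        parts = [
            (f"{n}x{cls}" if n > 1 else cls)
            for cls, n in sorted(counts.items())
        ]
        rows.append(
            {
                "gene_id": gene,
                "n_tss": len(group),
                "combination": "+".join(parts),
                "positions": ",".join(str(c.position) for c in sorted(group, key=lambda x: x.position)),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_tss", "combination", "positions"])


def decile_distribution(
    classified: list[ClassifiedTss], genome: GenomeModel, which: str
) -> np.ndarray:
    """Counts of internal or antisense TSSs per tenth of their host gene,
    numbered 1..10 along the gene's 5'->3' direction."""
    if which not in ("internal", "antisense"):
        raise ValueError("which must be 'internal' or 'antisense'")
    counts = np.zeros(10, dtype=int)
    for c in classified:
        if c.primary_class != which:
            continue
        gene = genome.feature_by_id(c.associated_gene)
        if not gene.contains(c.position):
            raise ValueError(f"TSS at {c.position} does not overlap {gene.feature_id}")
        offset = c.position - gene.start if gene.strand == "+" else gene.end - c.position
        section = min(9, (10 * offset) // gene.length)
        counts[section] += 1
    return counts


def to_frame(classified: list[ClassifiedTss]) -> pd.DataFrame:
    """Flat table of classified TSSs (one row per TSS)."""
    return pd.DataFrame(
        {
            "replicon": [c.record.replicon for c in classified],
            "position": [c.position for c in classified],
            "strand": [c.strand for c in classified],
            "primary_class": [c.primary_class for c in classified],
            "associated_gene": [c.associated_gene or "" for c in classified],
            "utr_length": [c.utr_length if c.utr_length is not None else -1 for c in classified],
            "support": [c.record.support for c in classified],
            "n_enriched": [len(c.record.enriched_in) for c in classified],
            "average_coverage": [c.record.average_coverage for c in classified],
            "downstream_gene": [c.downstream_gene or "" for c in classified],
            "downstream_distance": [
                c.downstream_distance if c.downstream_distance is not None else -1
                for c in classified
            ],
        }
    )
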