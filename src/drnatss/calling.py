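"""TSS calling from +-TEX 5'-read-start coverage.

The caller normalizes libraries to the shallowest library's depth, flags
positions whose +TEX signal rises sharply above the upstream neighbour and
is enriched over the -TEX library, merges candidates closer than 10 nt, and
forms a replicate-consensus set with detection and enrichment support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import CoverageTrack

MERGE_DISTANCE = 10  # candidates closer than this are one TSS


@dataclass
class CallParams:
    """Caller thresholds.

    min_enrichment is the +TEX/-TEX ratio a primary 5' end must reach
    (inclusive); min_height and step_factor play the role of the height and
    rising-step conditions of dRNA-Seq TSS callers and are bespoke defaults.
    The enrichment ratio uses a one-read pseudocount in the denominator.
    """

    min_height: float = 5.0
    step_factor: float = 2.0
    min_enrichment: float = 2.5
    pseudocount: float = 1.0


@dataclass(frozen=True)
class TssCandidate:
    replicon: str
    position: int
    strand: str
    plus_tex_height: float
    minus_tex_height: float
    enrichment_factor: float
    replicate: int
    enriched: bool

    def __post_init__(self) -> None:
        if self.enrichment_factor < 0:
            raise ValueError("enrichment_factor must be >= 0")


@dataclass(frozen=True)
class TssRecord:
    replicon: str
    position: int
    strand: str
    detected_in: frozenset[int]
    enriched_in: frozenset[int]
    average_coverage: float

    def __post_init__(self) -> None:
        if not self.detected_in:
            raise ValueError("detected_in must be non-empty")
        if not self.enriched_in <= self.detected_in:
            raise ValueError("enriched_in must be a subset of detected_in")

    @property
    def support(self) -> int:
        return len(self.detected_in)


class NormalizationError(ValueError):
    pass


def normalize_coverage(tracks: list[CoverageTrack]) -> list[CoverageTrack]:
    """Scale every track by min(mapped_reads)/mapped_reads of its library.

    The shallowest library is unchanged and within-library ratios are
    preserved, so heights stay on the scale of real read counts.
    """
    if not tracks:
        return []
    for t in tracks:
        if t.mapped_reads <= 0:
            raise NormalizationError(f"{t.library}: mapped_reads must be > 0")
    floor = min(t.mapped_reads for t in tracks)
    return [t.scaled(floor / t.mapped_reads) for t in tracks]


def call_tss(
    minus: CoverageTrack,
    plus: CoverageTrack,
    params: CallParams | None = None,
    keep_unenriched: bool = False,
) -> list[TssCandidate]:
    """Candidate TSSs on one replicon strand of one replicate.

    A position qualifies when the +TEX height reaches ``min_height``, exceeds
    ``step_factor`` times the height one base upstream (in transcription
    direction), and -- unless ``keep_unenriched`` -- the enrichment factor
    +TEX/(-TEX + pseudocount) reaches ``min_enrichment``. Candidates are
    returned in coordinate order.
    """
    params = params or CallParams()
    if (minus.replicon, minus.strand) != (plus.replicon, plus.strand):
        raise ValueError("tracks must share replicon and strand")
    if len(minus.values) != len(plus.values):
        raise ValueError("mismatched track lengths")
    if minus.replicate != plus.replicate:
        raise ValueError("tracks must come from the same replicate")

    p = plus.values
    upstream = np.empty_like(p)
    # the replicon-edge base has no upstream neighbour and is never a step
    if plus.strand == "+":
        upstream[0] = np.inf
        upstream[1:] = p[:-1]
    else:
        upstream[-1] = np.inf
        upstream[:-1] = p[1:]

    enrichment = p / (minus.values + params.pseudocount)
    detected = (p >= params.min_height) & (p >= params.step_factor * upstream)
    enriched = enrichment >= params.min_enrichment
    keep = detected if keep_unenriched else (detected & enriched)

    return [
        TssCandidate(
            replicon=plus.replicon,
            position=int(i) + 1,
            strand=plus.strand,
            plus_tex_height=float(p[i]),
            minus_tex_height=float(minus.values[i]),
            enrichment_factor=float(enrichment[i]),
            replicate=plus.replicate,
            enriched=bool(enriched[i]),
        )
        for i in np.nonzero(keep)[0]
    ]


def _clusters(candidates: list[TssCandidate], min_distance: int) -> list[list[TssCandidate]]:
    """Single-linkage position clustering of coordinate-sorted candidates."""
    ordered = sorted(candidates, key=lambda c: c.position)
    groups: list[list[TssCandidate]] = []
    for cand in ordered:
        if groups and cand.position - groups[-1][-1].position < min_distance:
            groups[-1].append(cand)
        else:
            groups.append([cand])
    return groups


def _representative(cluster: list[TssCandidate]) -> TssCandidate:
    """Highest +TEX member; ties go to the most upstream position in
    transcription direction (left on '+', right on '-')."""
    best = max(c.plus_tex_height for c in cluster)
    tied = [c for c in cluster if c.plus_tex_height == best]
    if cluster[0].strand == "+":
        return min(tied, key=lambda c: c.position)
    return max(tied, key=lambda c: c.position)


def merge_close(
    candidates: list[TssCandidate], min_distance: int = MERGE_DISTANCE
) -> list[TssCandidate]:
    """Collapse same-strand candidates with successive gaps < min_distance."""
    if not candidates:
        return []
    strands = {c.strand for c in candidates}
    replicons = {c.replicon for c in candidates}
    if len(strands) > 1 or len(replicons) > 1:
        raise ValueError("merge_close expects a single replicon strand")
    return [_representative(g) for g in _clusters(candidates, min_distance)]


def replicate_consensus(
    per_replicate: list[list[TssCandidate]], min_distance: int = MERGE_DISTANCE
) -> list[TssRecord]:
    """Collapse within-replicate candidate lists into consensus TssRecords.

    Candidates from different replicates closer than ``min_distance`` on the
    same strand are one TSS, placed at the position of the replicate with the
    highest +TEX height. average_coverage is the mean +TEX height over the
    replicates detecting the TSS (per replicate, its highest member).
    """
    pooled: dict[tuple[str, str], list[TssCandidate]] = {}
    for cands in per_replicate:
        for c in cands:
            pooled.setdefault((c.replicon, c.strand), []).append(c)

    records = []
    for (replicon, strand), cands in sorted(pooled.items()):
        for cluster in _clusters(cands, min_distance):
            rep = _representative(cluster)
            best_by_replicate: dict[int, float] = {}
            enriched_in = set()
            for c in cluster:
                best_by_replicate[c.replicate] = max(
                    best_by_replicate.get(c.replicate, 0.0), c.plus_tex_height
                )
                if c.enriched:
                    enriched_in.add(c.replicate)
            records.append(
                TssRecord(
                    replicon=replicon,
                    position=rep.position,
                    strand=strand,
                    detected_in=frozenset(best_by_replicate),
                    enriched_in=frozenset(enriched_in),
                    average_coverage=float(np.mean(list(best_by_replicate.values()))),
                )
            )
    records.sort(key=lambda r: (r.replicon, r.position, r.strand))
    return records


def support_counts(records: list[TssRecord]) -> dict[str, int]:
    """Counts of TSSs detected in >=1, >=2 and all-3 replicates."""
    return {
        ">=1": sum(1 for r in records if r.support >= 1),
        ">=2": sum(1 for r in records if r.support >= 2),
        "==3": sum(1 for r in records if r.support == 3),
    }
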