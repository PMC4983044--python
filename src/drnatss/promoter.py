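"""Basal-promoter position weight matrix modelling.

The promoter of each TSS is modelled from the 71 bases ending on the first
transcribed base. A 28-column log-odds PWM over the genome background is
refined iteratively: score all 71-mers, keep hits above the exact
p-value-derived threshold whose match offset lies within +-4 nt of the modal
offset, realign, rebuild, and repeat to a fixed point. Score thresholds are
derived from the exact score distribution of a random background window,
computed by dynamic programming over columns with scores discretized
downward to a 0.001 granularity (conservative thresholds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genome import BASES, GenomeModel, encode

logger = logging.getLogger(__name__)

UPSTREAM_LENGTH = 71
PWM_WIDTH = 28
DEFAULT_INIT_ANCHOR = 18   # 3' edge of the initial window, nt upstream of the TSS
DEFAULT_MAX_SHIFT = 4
GRANULARITY = 1e-3
ZERO_FREQ_LOG_ODDS = -30.0  # guard for log2(0) at pseudocount 0


class DegenerateMotifError(RuntimeError):
    """Fewer than two positive sequences remain during refinement."""


@dataclass(frozen=True)
class UpstreamSeq:
    """71-base upstream sequence; the last base is the first transcribed base."""

    tss_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != UPSTREAM_LENGTH:
            raise ValueError(f"{self.tss_id}: upstream sequence must be {UPSTREAM_LENGTH} nt")
        if set(self.sequence) - set(BASES):
            raise ValueError(f"{self.tss_id}: non-ACGT base in upstream sequence")


@dataclass
class Pwm:
    """Count matrix with background and derived log2 odds (4 x width)."""

    counts: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.5
    log_odds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4 or self.background.shape != (4,):
            raise ValueError("counts must be 4 x W and background length 4")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        column_totals = self.counts.sum(axis=0)
        if not np.allclose(column_totals, column_totals[0]):
            raise ValueError("column counts must be equal across columns")
        n = column_totals[0]
        freqs = (self.counts + self.pseudocount) / (n + 4 * self.pseudocount)
        with np.errstate(divide="ignore"):
            lo = np.log2(freqs / self.background[:, None])
        self.log_odds = np.where(np.isneginf(lo), ZERO_FREQ_LOG_ODDS, lo)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))


def genome_background(genome: GenomeModel) -> np.ndarray:
    """Strand-symmetric base composition q over A,C,G,T of the whole genome."""
    counts = np.zeros(4)
    for seq in genome.sequences.values():
        for i, base in enumerate(BASES):
            counts[i] += seq.count(base)
    if counts.sum() == 0:
        raise ValueError("empty genome")
    symmetric = np.array(
        [counts[0] + counts[3], counts[1] + counts[2], counts[2] + counts[1], counts[3] + counts[0]]
    ) / (2 * counts.sum())
    return symmetric


def extract_upstream(genome: GenomeModel, replicon: str, position: int, strand: str
                     ) -> UpstreamSeq | None:
    """The 71-mer ending on the TSS, on the TSS strand; None when the TSS is
    too close to the replicon edge or the window contains a non-ACGT base."""
    length = genome.length(replicon)
    if strand == "+":
        lo, hi = position - UPSTREAM_LENGTH + 1, position
    else:
        lo, hi = position, position + UPSTREAM_LENGTH - 1
    if lo < 1 or hi > length:
        logger.warning("TSS %s:%d%s skipped: <%d nt from replicon edge",
                       replicon, position, strand, UPSTREAM_LENGTH)
        return None
    seq = genome.subsequence(replicon, lo, hi, strand)
    if set(seq) - set(BASES):
        logger.warning("TSS %s:%d%s skipped: ambiguous base upstream", replicon, position, strand)
        return None
    return UpstreamSeq(f"{replicon}:{position}:{strand}", seq)


def build_pwm(windows: list[str], background: np.ndarray, pseudocount: float = 0.5) -> Pwm:
    """Tally aligned equal-width windows into a PWM."""
    if len(windows) < 2:
        raise ValueError("need at least 2 windows")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows must share one width")
    counts = np.zeros((4, width))
    codes = np.stack([encode(w) for w in windows])
    for b in range(4):
        counts[b] = (codes == b).sum(axis=0)
    return Pwm(counts, background, pseudocount)


def score_distribution(pwm: Pwm, granularity: float = GRANULARITY) -> tuple[int, np.ndarray]:
    """Exact distribution of the PWM score of a random background window,
    with per-column scores floored to the granularity grid.

    Returns (base, probs) where probs[i] = P(floored score = (base + i) *
    granularity).
    """
    if (pwm.background <= 0).any():
        raise ValueError("background must be strictly positive")
    grid = np.floor(pwm.log_odds / granularity).astype(np.int64)
    dist = np.ones(1)
    base = 0
    for j in range(pwm.width):
        col = grid[:, j]
        lo = base + int(col.min())
        hi = base + int(col.max()) + len(dist) - 1
        new = np.zeros(hi - lo + 1)
        for b in range(4):
            start = base + int(col[b]) - lo
            new[start : start + len(dist)] += pwm.background[b] * dist
        dist, base = new, lo
    return base, dist


def pvalue_threshold(pwm: Pwm, p: float, granularity: float = GRANULARITY) -> float:
    """Smallest achievable grid score t with P(score >= t) <= p under the
    background (conservative: scores are floored to the grid). When even the
    maximal score has tail probability > p the threshold sits one grid step
    above it and nothing can match."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    base, dist = score_distribution(pwm, granularity)
    tail = np.cumsum(dist[::-1])[::-1]
    tail /= tail[0]  # guard cumulative rounding so P(score >= min) is exactly 1
    passing = np.nonzero((tail <= p * (1 + 1e-12)) & (dist > 0))[0]
    t_index = int(passing[0]) if passing.size else len(dist)
    return (base + t_index) * granularity


def _encode_many(sequences: list[str]) -> np.ndarray:
    return np.stack([encode(s) for s in sequences])


def _scan_matrix(pwm: Pwm, codes: np.ndarray) -> np.ndarray:
    """Score every window offset of every sequence: (n, L-W+1) array."""
    windows = sliding_window_view(codes, pwm.width, axis=1)
    return pwm.log_odds[windows, np.arange(pwm.width)].sum(axis=2)


def scan(pwm: Pwm, sequence: str | UpstreamSeq, threshold: float) -> tuple[float, int] | None:
    """Best-scoring window of one sequence on the given strand only.

    Returns (score, offset) of the highest-scoring window with score >=
    threshold (ties -> smallest offset), or None.
    """
    seq = sequence.sequence if isinstance(sequence, UpstreamSeq) else sequence
    if len(seq) < pwm.width:
        raise ValueError("sequence shorter than the PWM")
    scores = _scan_matrix(pwm, _encode_many([seq]))[0]
    offset = int(np.argmax(scores))
    if scores[offset] >= threshold:
        return float(scores[offset]), offset
    return None


@dataclass
class RefineResult:
    pwm: Pwm
    positives: dict[str, int]      # tss id -> match offset in its 71-mer
    n_iterations: int
    peak_offset: int
    converged: bool
    threshold: float


def refine_pwm(
    upstreams: list[UpstreamSeq],
    background: np.ndarray,
    p: float = 0.001,
    max_shift: int = DEFAULT_MAX_SHIFT,
    max_iter: int = 200,
    pseudocount: float = 0.5,
    width: int = PWM_WIDTH,
    init_anchor: int = DEFAULT_INIT_ANCHOR,
) -> RefineResult:
    """Iterative positional refinement of the promoter PWM.

    Starts from a PWM over the window whose 3' edge sits ``init_anchor`` nt
    upstream of the TSS in every sequence, then alternates: derive the
    p-value score threshold, scan all 71-mers, keep hits whose offset is
    within ``max_shift`` of the modal offset, realign kept windows to their
    match offsets, rebuild. Converged when the positive set (ids and offsets)
    repeats exactly; a two-state oscillation is reported as non-converged.
    """
    if len(upstreams) < 50:
        logger.warning("refine_pwm: only %d upstream sequences (>=50 recommended)", len(upstreams))
    seq_len = UPSTREAM_LENGTH
    init_offset = seq_len - init_anchor - width
    if init_offset < 0:
        raise ValueError("initial window does not fit the upstream sequence")
    codes = _encode_many([u.sequence for u in upstreams])
    ids = [u.tss_id for u in upstreams]

    state: dict[int, int] = {i: init_offset for i in range(len(upstreams))}
    previous: list[frozenset] = [frozenset(state.items())]
    pwm = threshold = None
    peak = init_offset
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        if len(state) < 2:
            raise DegenerateMotifError(f"{len(state)} positives at iteration {iteration}")
        windows = [upstreams[i].sequence[off : off + width] for i, off in state.items()]
        pwm = build_pwm(windows, background, pseudocount)
        threshold = pvalue_threshold(pwm, p)
        scores = _scan_matrix(pwm, codes)
        best_offsets = scores.argmax(axis=1)
        best_scores = scores[np.arange(len(scores)), best_offsets]
        hits = best_scores >= threshold
        if not hits.any():
            raise DegenerateMotifError(f"no hits above threshold at iteration {iteration}")
        offsets, counts = np.unique(best_offsets[hits], return_counts=True)
        peak = int(offsets[np.argmax(counts)])
        new_state = {
            int(i): int(best_offsets[i])
            for i in np.nonzero(hits)[0]
            if abs(int(best_offsets[i]) - peak) <= max_shift
        }
        key = frozenset(new_state.items())
        if key == previous[-1]:
            converged = True
            state = new_state
            break
        if len(previous) >= 2 and key == previous[-2]:
            logger.warning(
                "refine_pwm: oscillation between states of sizes %d and %d",
                len(previous[-1]), len(new_state),
            )
            state = new_state
            break
        previous.append(key)
        state = new_state

    positives = {ids[i]: off for i, off in sorted(state.items())}
    logger.info("refine_pwm: %d positives, peak offset %d, %d iterations, converged=%s",
                len(positives), peak, iteration, converged)
    return RefineResult(pwm, positives, iteration, peak, converged, float(threshold))


@dataclass(frozen=True)
class PromoterCall:
    tss_id: str
    score: float | None
    offset: int | None
    promoter_class: str  # stringent | relaxed | none


def classify_promoters(
    pwm: Pwm,
    upstreams: list[UpstreamSeq],
    p_stringent: float = 0.001,
    p_relaxed: float = 0.01,
) -> tuple[list[PromoterCall], float, float]:
    """Score every upstream 71-mer and call stringent/relaxed/none promoters.

    Returns (calls, stringent threshold, relaxed threshold); the numeric
    cutoffs are derived from the p values, not constants.
    """
    t_stringent = pvalue_threshold(pwm, p_stringent)
    t_relaxed = pvalue_threshold(pwm, p_relaxed)
    calls = []
    for u in upstreams:
        hit = scan(pwm, u, t_relaxed)
        if hit is None:
            calls.append(PromoterCall(u.tss_id, None, None, "none"))
        else:
            score, offset = hit
            cls = "stringent" if score >= t_stringent else "relaxed"
            calls.append(PromoterCall(u.tss_id, score, offset, cls))
    return calls, t_stringent, t_relaxed


def logo_matrix(windows: list[str], background: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relative-entropy logo contributions of aligned windows.

    Returns (contrib, info): contrib[b, j] = f_bj * log2(f_bj / q_b) with
    0*log(0) := 0 (negative letters point down in the rendered logo), and
    info[j] = sum_b contrib[b, j] >= 0 (Kullback-Leibler information).
    """
    width = len(windows[0])
    counts = np.zeros((4, width))
    codes = np.stack([encode(w) for w in windows])
    for b in range(4):
        counts[b] = (codes == b).sum(axis=0)
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(freqs > 0, freqs * np.log2(freqs / np.asarray(background)[:, None]), 0.0)
    return contrib, contrib.sum(axis=0)
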