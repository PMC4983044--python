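"""Synthetic dRNA-Seq study generator.

Emulates the statistical structure a haloarchaeal primary-transcriptome
analysis assumes: a GC-rich (~67 %) single replicon, leaderless-dominant
gene starts, planted BRE+TATA basal promoters upstream of a configurable
fraction of TSSs, TEX enrichment of primary 5' ends, TEX-neutral processed
5' ends as caller decoys, and anti-correlated sense/antisense expression.

The generator is fully deterministic for a fixed master seed; per-replicate
random streams are derived from it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from . import io
from .genome import BASES, Feature, GenomeModel
from .tracks import MINUS_TEX, PLUS_TEX, CoverageTrack

STOP_CODONS = ("TAA", "TAG", "TGA")

#: classification vocabulary shared with tss_classify
CLASSES = ("leaderless", "leadered", "known_rna", "intergenic_novel", "internal", "antisense")


class SizingError(ValueError):
    """The requested annotation does not fit the requested genome length."""


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dRNA-Seq experiment.

    The defaults emulate the class proportions of a haloarchaeal
    primary-transcriptome map (leaderless-dominant protein-coding starts,
    antisense as the largest novel class) scaled to ~575 truth TSSs so a
    full run completes on one CPU in minutes.
    """

    genome_length: int = 3_000_000
    replicon: str = "chr"
    gc_content: float = 0.67

    # truth TSS counts per class (internal/antisense each also create a host gene)
    n_leaderless: int = 160
    n_leadered: int = 64
    n_known_rna: int = 13
    n_intergenic: int = 48
    n_internal: int = 140
    n_antisense: int = 150

    # planted basal promoter: BRE immediately 5' of the TATA box, TATA 3'
    # edge `tata_offset` (+ jitter <= tata_jitter) nt upstream of the TSS
    promoter_fraction_stringent: float = 0.5
    bre: str = "CGAAA"
    tata: str = "TTAT"
    tata_offset: int = 24
    tata_jitter: int = 2

    # expression model: shifted log-normal, well above background
    expr_floor: float = 50.0
    expr_mu: float = math.log(120.0)
    expr_sigma: float = 0.6
    leaderless_expression_factor: float = 4.0
    gtg_fraction: float = 0.09
    gtg_expression_factor: float = 0.5

    # count model
    tex_enrichment: float = 5.0
    dispersion: float = 10.0
    background_rate: float = 5e-5
    decoy_rate: float = 0.5
    n_replicates: int = 3
    depth_factors: tuple[float, ...] = (1.0, 1.25, 0.8)
    reads_per_depth_unit: float = 1_000_000.0

    # antisense structure
    antisense_rho: float = -0.6
    sense_off_fraction: float = 0.6
    transposase_fraction: float = 0.15

    # gene geometry
    cds_codon_range: tuple[int, int] = (80, 300)
    small_protein_fraction: float = 0.15
    small_protein_codon_range: tuple[int, int] = (40, 100)
    utr_long_fraction: float = 0.15
    utr_exp_scale: float = 35.0
    uorf_fraction: float = 0.3
    gap_range: tuple[int, int] = (500, 900)

    seed: int = 0

    def validate(self) -> None:
        for name in (
            "gc_content",
            "promoter_fraction_stringent",
            "gtg_fraction",
            "sense_off_fraction",
            "transposase_fraction",
            "small_protein_fraction",
            "utr_long_fraction",
            "uorf_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.tex_enrichment <= 0 or self.dispersion <= 0:
            raise ValueError("tex_enrichment and dispersion must be positive")
        # planted consensus must fit inside the 28-base promoter window that
        # the motif refinement anchors 18 nt upstream of the TSS
        motif_reach = self.tata_offset + self.tata_jitter + len(self.tata) + len(self.bre) - 1
        if motif_reach > 45 or self.tata_offset - 1 < 18:
            raise ValueError("planted consensus does not fit the 28-base promoter window")
        if self.gap_range[0] < 400:
            raise ValueError("gap_range lower bound must be >= 400 (room for 250-nt UTRs)")


@dataclass(frozen=True)
class TruthTss:
    """Ground-truth TSS planted by the generator."""

    tss_id: str
    replicon: str
    position: int
    strand: str
    true_class: str
    expression_level: float
    has_planted_promoter: bool
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.true_class not in CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")


# ------------------------------------------------------------------ helpers

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    codes = rng.choice(4, size=length, p=_base_probs(gc))
    return "".join(BASES[c] for c in codes)


def _codon_tables(gc: float) -> tuple[list[str], np.ndarray, list[str], np.ndarray]:
    probs = _base_probs(gc)
    codons, weights = [], []
    for triple in itertools.product(range(4), repeat=3):
        codons.append("".join(BASES[i] for i in triple))
        weights.append(probs[triple[0]] * probs[triple[1]] * probs[triple[2]])
    weights = np.array(weights)
    sense = [c for c in codons if c not in STOP_CODONS]
    w_sense = np.array([w for c, w in zip(codons, weights) if c not in STOP_CODONS])
    w_stop = np.array([weights[codons.index(s)] for s in STOP_CODONS])
    return sense, w_sense / w_sense.sum(), list(STOP_CODONS), w_stop / w_stop.sum()


def _coding_sequence(
    rng: np.random.Generator, n_codons: int, start_codon: str, gc: float,
    tables: tuple,
) -> str:
    """CDS of n_codons codons: start codon, interior sense codons, one stop."""
    sense, w_sense, stops, w_stop = tables
    interior = rng.choice(len(sense), size=n_codons - 2, p=w_sense)
    stop = stops[rng.choice(len(stops), p=w_stop)]
    return start_codon + "".join(sense[i] for i in interior) + stop


def sample_sense_antisense(
    n: int, rho: float, rng: np.random.Generator, config: SynthConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (sense, antisense) expression pairs with a Gaussian-copula
    association of ``rho`` between the latent normals.

    The marginals are the generator's shifted log-normals, which are strictly
    monotone in the latent normal, so the rank correlation of the pair equals
    that of the copula: (6/pi)*asin(rho/2).
    """
    cfg = config or SynthConfig()
    z_s = rng.standard_normal(n)
    z_a = rho * z_s + math.sqrt(max(0.0, 1 - rho * rho)) * rng.standard_normal(n)
    sense = (cfg.expr_floor + np.exp(cfg.expr_mu + cfg.expr_sigma * z_s)) * cfg.leaderless_expression_factor
    anti = cfg.expr_floor + np.exp(cfg.expr_mu + cfg.expr_sigma * z_a)
    return sense, anti


def _expr(rng: np.random.Generator, cfg: SynthConfig, n: int = 1) -> np.ndarray:
    return cfg.expr_floor + rng.lognormal(cfg.expr_mu, cfg.expr_sigma, size=n)


# ------------------------------------------------------------------ layout

@dataclass
class _Slot:
    kind: str
    strand: str
    region_length: int
    utr: int = 0
    n_codons: int = 0
    start_codon: str = "ATG"
    category: str = "CDS"
    sense_on: bool = True
    pair_index: int = -1
    # filled during placement
    start: int = 0
    end: int = 0


def _draw_cds_codons(rng: np.random.Generator, cfg: SynthConfig) -> int:
    if rng.random() < cfg.small_protein_fraction:
        lo, hi = cfg.small_protein_codon_range
    else:
        lo, hi = cfg.cds_codon_range
    return int(rng.integers(lo, hi + 1))


def _draw_utr(rng: np.random.Generator, cfg: SynthConfig) -> int:
    if rng.random() < cfg.utr_long_fraction:
        return int(rng.integers(150, 251))
    return 6 + min(143, int(rng.exponential(cfg.utr_exp_scale)))


def _plan_slots(rng: np.random.Generator, cfg: SynthConfig) -> list[_Slot]:
    slots: list[_Slot] = []

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    for _ in range(cfg.n_leaderless):
        n_codons = _draw_cds_codons(rng, cfg)
        start = "GTG" if rng.random() < cfg.gtg_fraction else "ATG"
        slots.append(_Slot("leaderless", strand(), 3 * n_codons, n_codons=n_codons, start_codon=start))
    for _ in range(cfg.n_leadered):
        n_codons = _draw_cds_codons(rng, cfg)
        slots.append(_Slot("leadered", strand(), 3 * n_codons, n_codons=n_codons, utr=_draw_utr(rng, cfg)))
    for _ in range(cfg.n_known_rna):
        slots.append(_Slot("known_rna", strand(), int(rng.integers(80, 201)), category="known_rna"))
    for _ in range(cfg.n_intergenic):
        slots.append(_Slot("intergenic_novel", strand(), 1100))
    for _ in range(cfg.n_internal):
        n_codons = max(60, _draw_cds_codons(rng, cfg))
        cat = "transposase" if rng.random() < cfg.transposase_fraction else "CDS"
        slots.append(_Slot("internal", strand(), 3 * n_codons, n_codons=n_codons, category=cat))
    for i in range(cfg.n_antisense):
        n_codons = max(60, _draw_cds_codons(rng, cfg))
        sense_on = rng.random() >= cfg.sense_off_fraction
        cat = "CDS"
        if not sense_on and rng.random() < 0.25:
            cat = "transposase"
        slots.append(
            _Slot("antisense", strand(), 3 * n_codons, n_codons=n_codons,
                  category=cat, sense_on=sense_on, pair_index=i)
        )
    order = rng.permutation(len(slots))
    return [slots[i] for i in order]


def _place_slots(slots: list[_Slot], rng: np.random.Generator, cfg: SynthConfig) -> None:
    margin = 300
    gaps = [int(rng.integers(cfg.gap_range[0], cfg.gap_range[1] + 1)) for _ in slots]
    content = 2 * margin + sum(gaps) + sum(s.region_length for s in slots)
    extra = cfg.genome_length - content
    if extra < 0:
        raise SizingError(
            f"annotation needs {content} bases but genome_length is {cfg.genome_length}"
        )
    if slots:
        per_gap = extra // len(slots)
        gaps = [g + per_gap for g in gaps]
    cursor = margin
    for slot, gap in zip(slots, gaps):
        cursor += gap
        slot.start = cursor + 1  # 1-based inclusive
        slot.end = cursor + slot.region_length
        cursor += slot.region_length
    span = sum(s.region_length for s in slots if s.kind != "intergenic_novel")
    if cfg.genome_length < 10 * span:
        raise SizingError(
            f"genome_length {cfg.genome_length} < 10 x annotated span {span}"
        )


# ------------------------------------------------------------------ genome

def generate_genome(config: SynthConfig) -> tuple[GenomeModel, list[TruthTss]]:
    """Build the synthetic replicon, its annotation, and the truth TSS set."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    slots = _plan_slots(rng, config)
    _place_slots(slots, rng, config)

    seq = np.array(list(random_sequence(rng, config.genome_length, config.gc_content)))
    tables = _codon_tables(config.gc_content)

    features: list[Feature] = []
    truth: list[TruthTss] = []
    gene_no = tss_no = 0

    # antisense expression pairs share one copula draw
    n_anti = config.n_antisense
    rho = config.antisense_rho
    sense_levels, anti_levels = sample_sense_antisense(max(1, n_anti), rho, rng, config)

    def _write(start: int, end: int, forward_seq: str, strand: str) -> None:
        s = forward_seq if strand == "+" else reverse_complement(forward_seq)
        seq[start - 1 : end] = list(s)

    def add_gene(slot: _Slot) -> Feature:
        nonlocal gene_no
        gene_no += 1
        feat = Feature(f"gene{gene_no:04d}", config.replicon, slot.start, slot.end,
                       slot.strand, slot.category)
        features.append(feat)
        if slot.category != "known_rna":
            cds = _coding_sequence(rng, slot.n_codons, slot.start_codon, config.gc_content, tables)
            _write(slot.start, slot.end, cds, slot.strand)
        return feat

    def add_tss(position: int, strand: str, true_class: str, expr: float,
                gene_id: str | None) -> TruthTss:
        nonlocal tss_no
        tss_no += 1
        rec = TruthTss(f"tss{tss_no:04d}", config.replicon, position, strand,
                       true_class, float(expr), False, gene_id)
        truth.append(rec)
        return rec

    for slot in slots:
        if slot.kind == "intergenic_novel":
            pos = slot.start + slot.region_length // 2
            add_tss(pos, slot.strand, "intergenic_novel", _expr(rng, config)[0], None)
            continue
        feat = add_gene(slot)
        if slot.kind == "leaderless":
            expr = _expr(rng, config)[0] * config.leaderless_expression_factor
            if slot.start_codon == "GTG":
                expr *= config.gtg_expression_factor
            add_tss(feat.five_prime, slot.strand, "leaderless", expr, feat.feature_id)
        elif slot.kind == "leadered":
            pos = feat.five_prime - slot.utr if slot.strand == "+" else feat.five_prime + slot.utr
            add_tss(pos, slot.strand, "leadered", _expr(rng, config)[0], feat.feature_id)
            if slot.utr >= 150 and rng.random() < config.uorf_fraction:
                _plant_uorf(rng, seq, config, feat, pos, slot.utr, tables)
        elif slot.kind == "known_rna":
            expr = _expr(rng, config)[0] * config.leaderless_expression_factor
            add_tss(feat.five_prime, slot.strand, "known_rna", expr, feat.feature_id)
        elif slot.kind == "internal":
            offset = int(rng.integers(50, feat.length - 39))
            pos = feat.start + offset if slot.strand == "+" else feat.end - offset
            add_tss(pos, slot.strand, "internal", _expr(rng, config)[0], feat.feature_id)
        elif slot.kind == "antisense":
            anti_strand = "-" if slot.strand == "+" else "+"
            offset = int(rng.integers(50, feat.length - 39))
            pos = feat.start + offset if slot.strand == "+" else feat.end - offset
            add_tss(pos, anti_strand, "antisense", anti_levels[slot.pair_index], feat.feature_id)
            if slot.sense_on:
                add_tss(feat.five_prime, slot.strand, "leaderless",
                        sense_levels[slot.pair_index], feat.feature_id)

    truth = _plant_promoters(rng, seq, config, truth)
    genome = GenomeModel({config.replicon: "".join(seq)}, sorted(features, key=lambda f: f.start))
    return genome, truth


def _plant_uorf(rng, seq, cfg: SynthConfig, feat: Feature, tss_pos: int, utr: int,
                tables) -> None:
    """Plant an ATG...stop ORF (15-31 aa peptide) fully inside a long UTR."""
    aa = int(rng.integers(15, 32))
    orf = _coding_sequence(rng, aa + 1, "ATG", cfg.gc_content, tables)
    offset = int(rng.integers(5, utr - len(orf) - 4))
    if feat.strand == "+":
        start = tss_pos + offset
        seq[start - 1 : start - 1 + len(orf)] = list(orf)
    else:
        end = tss_pos - offset
        seq[end - len(orf) : end] = list(reverse_complement(orf))


def _plant_promoters(rng, seq, cfg: SynthConfig, truth: list[TruthTss]) -> list[TruthTss]:
    """Overwrite the planted BRE+TATA consensus upstream of a random fraction
    of truth TSSs; returns truth records with the promoter flag set."""
    motif = cfg.bre + cfg.tata
    out = []
    for rec in truth:
        if rng.random() >= cfg.promoter_fraction_stringent:
            out.append(rec)
            continue
        jit = int(rng.integers(0, cfg.tata_jitter + 1))
        edge = cfg.tata_offset + jit  # TATA 3' edge, nt upstream of the TSS
        if rec.strand == "+":
            hi = rec.position - edge            # genomic coord of TATA 3' edge
            lo = hi - len(motif) + 1
            seq[lo - 1 : hi] = list(motif)
        else:
            lo = rec.position + edge
            hi = lo + len(motif) - 1
            seq[lo - 1 : hi] = list(reverse_complement(motif))
        out.append(TruthTss(rec.tss_id, rec.replicon, rec.position, rec.strand,
                            rec.true_class, rec.expression_level, True, rec.gene_id))
    return out


# ------------------------------------------------------------------ coverage

def processed_sites(genome: GenomeModel, truth: list[TruthTss], config: SynthConfig
                    ) -> list[tuple[int, str, float]]:
    """TEX-neutral processed 5' ends: one per expressed truth transcript, at a
    random position in the transcript body, rate ``decoy_rate`` x the primary
    +TEX rate. Deterministic given the master seed."""
    rng = np.random.default_rng([config.seed, 101])
    length = genome.length(config.replicon)
    taken: dict[str, list[int]] = {"+": [], "-": []}
    for rec in truth:
        taken[rec.strand].append(rec.position)
    sites: list[tuple[int, str, float]] = []
    for rec in truth:
        if rec.expression_level <= 0:
            continue
        direction = 1 if rec.strand == "+" else -1
        for _ in range(20):
            d = int(rng.integers(30, 201))
            pos = rec.position + direction * d
            if not 1 <= pos <= length:
                continue
            if all(abs(pos - p) >= 15 for p in taken[rec.strand]):
                sites.append((pos, rec.strand, config.decoy_rate * rec.expression_level))
                taken[rec.strand].append(pos)
                break
    return sites


def simulate_coverage(
    genome: GenomeModel, truth: list[TruthTss], config: SynthConfig, replicate: int
) -> tuple[list[CoverageTrack], list[CoverageTrack]]:
    """Simulate one replicate's -TEX and +TEX read-start tracks (both strands).

    Counts at each site are Poisson given a gamma latent rate shared between
    the two libraries of the replicate (negative-binomial marginals with shape
    ``dispersion``); primary sites have +TEX mean = tex_enrichment x -TEX
    mean, processed sites are TEX-neutral.
    """
    if not 1 <= replicate <= config.n_replicates:
        raise ValueError(f"replicate must be in 1..{config.n_replicates}")
    for rec in truth:
        if not 1 <= rec.position <= genome.length(rec.replicon):
            raise ValueError(f"{rec.tss_id} outside genome")
    rng = np.random.default_rng([config.seed, 7, replicate])
    depth = config.depth_factors[(replicate - 1) % len(config.depth_factors)]
    length = genome.length(config.replicon)
    k = config.dispersion

    arrays = {
        (treatment, strand): np.zeros(length)
        for treatment in (MINUS_TEX, PLUS_TEX)
        for strand in "+-"
    }

    def deposit(pos: int, strand: str, lam_minus: float, lam_plus: float) -> None:
        g = rng.gamma(k, 1.0 / k)
        arrays[(MINUS_TEX, strand)][pos - 1] += rng.poisson(g * lam_minus * depth)
        arrays[(PLUS_TEX, strand)][pos - 1] += rng.poisson(g * lam_plus * depth)

    for rec in truth:
        deposit(rec.position, rec.strand, rec.expression_level / config.tex_enrichment,
                rec.expression_level)
    for pos, strand, rate in processed_sites(genome, truth, config):
        deposit(pos, strand, rate, rate)
    for key, arr in arrays.items():
        n_bg = rng.poisson(config.background_rate * length)
        positions = rng.integers(0, length, size=n_bg)
        np.add.at(arr, positions, 1.0)

    mapped = round(config.reads_per_depth_unit * depth)
    minus = [
        CoverageTrack(config.replicon, strand, arrays[(MINUS_TEX, strand)],
                      MINUS_TEX, replicate, mapped)
        for strand in "+-"
    ]
    plus = [
        CoverageTrack(config.replicon, strand, arrays[(PLUS_TEX, strand)],
                      PLUS_TEX, replicate, mapped)
        for strand in "+-"
    ]
    return minus, plus


# ------------------------------------------------------------------ fixtures

def truth_to_frame(truth: list[TruthTss]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tss_id": [t.tss_id for t in truth],
            "replicon": [t.replicon for t in truth],
            "position": [t.position for t in truth],
            "strand": [t.strand for t in truth],
            "true_class": [t.true_class for t in truth],
            "expression_level": [t.expression_level for t in truth],
            "has_planted_promoter": [t.has_planted_promoter for t in truth],
            "gene_id": [t.gene_id if t.gene_id is not None else "" for t in truth],
        }
    )


def frame_to_truth(df: pd.DataFrame) -> list[TruthTss]:
    return [
        TruthTss(
            tss_id=row.tss_id,
            replicon=row.replicon,
            position=int(row.position),
            strand=row.strand,
            true_class=row.true_class,
            expression_level=float(row.expression_level),
            has_planted_promoter=bool(row.has_planted_promoter),
            gene_id=row.gene_id if isinstance(row.gene_id, str) and row.gene_id else None,
        )
        for row in df.itertuples()
    ]


def write_fixture(
    genome: GenomeModel, truth: list[TruthTss], config: SynthConfig, outdir: str | Path
) -> list[Path]:
    """Write genome.fasta, annotation.gff3, per-replicate wiggle pairs,
    mapped_reads.tsv and truth.tsv; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [outdir / "genome.fasta", outdir / "annotation.gff3"]
    io.write_fasta(genome, paths[0])
    io.write_gff3(genome.features, paths[1])

    mapped: dict[str, float] = {}
    for rep in range(1, config.n_replicates + 1):
        minus, plus = simulate_coverage(genome, truth, config, rep)
        for track in minus + plus:
            mapped[track.library] = track.mapped_reads
            p = outdir / io.track_filename(track)
            io.write_wiggle(track, p)
            paths.append(p)
    p = outdir / "mapped_reads.tsv"
    io.write_mapped_reads(mapped, p)
    paths.append(p)
    p = outdir / "truth.tsv"
    io.write_table(truth_to_frame(truth), p)
    paths.append(p)
    return paths


def read_fixture(outdir: str | Path) -> tuple[GenomeModel, list[TruthTss], list[CoverageTrack]]:
    outdir = Path(outdir)
    sequences = io.read_fasta(outdir / "genome.fasta")
    features = io.read_gff3(outdir / "annotation.gff3")
    genome = GenomeModel(sequences, features)
    truth = frame_to_truth(io.read_table(outdir / "truth.tsv"))
    mapped = io.read_mapped_reads(outdir / "mapped_reads.tsv")
    lengths = {name: len(seq) for name, seq in sequences.items()}
    tracks = io.load_coverage_dir(outdir, lengths, mapped)
    return genome, truth, tracks


# ------------------------------------------------------------------ motif sets

def make_upstream_set(
    n: int,
    planted_fraction: float,
    config: SynthConfig | None = None,
    seed: int = 0,
    jitter_range: int = 2,
) -> tuple[list[str], np.ndarray]:
    """Random 71-mers at the configured GC, a fraction carrying the planted
    BRE+TATA consensus at its canonical offset +- jitter_range nt.

    Returns (sequences, planted mask). Used by the promoter-recovery tests.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng([seed, 3])
    motif = cfg.bre + cfg.tata
    seqs, planted = [], np.zeros(n, dtype=bool)
    for i in range(n):
        s = random_sequence(rng, 71, cfg.gc_content)
        if rng.random() < planted_fraction:
            jit = int(rng.integers(-jitter_range, jitter_range + 1))
            # TATA 3' edge tata_offset nt upstream of the TSS (offset 70)
            end = 70 - cfg.tata_offset + jit        # 0-based inclusive end
            start = end - len(motif) + 1
            s = s[:start] + motif + s[end + 1 :]
            planted[i] = True
        seqs.append(s)
    return seqs, planted
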