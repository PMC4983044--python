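"""Classification summary tables, rounded percentages, and the end-to-end
pipeline (simulate -> call -> classify -> promoter -> analyses -> summary)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dataclass_field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .antisense import (
    category_overlap,
    pair_sense_antisense,
    pairs_to_frame,
    reciprocity_stats,
)
from .calling import CallParams, call_tss, merge_close, normalize_coverage, replicate_consensus
from .classify import (
    ClassifiedTss,
    NOVEL_CLASSES,
    PROTEIN_CLASSES,
    classify_all,
    decile_distribution,
    find_multi_tss,
    to_frame,
)
from .genome import GenomeModel
from .promoter import (
    PromoterCall,
    RefineResult,
    classify_promoters,
    extract_upstream,
    genome_background,
    logo_matrix,
    refine_pwm,
)
from .synthetic import SynthConfig, TruthTss, generate_genome, simulate_coverage
from .tracks import MINUS_TEX, PLUS_TEX, CoverageTrack
from .uorf import uorf_table, uorfs_in_long_utrs
from .utr import expression_deciles, start_codon_summary, utr_histograms

logger = logging.getLogger(__name__)

SUMMARY_ROWS = (
    "all", "forward", "reverse",
    "protein_coding", "leaderless", "leadered",
    "known_rna",
    "novel", "intergenic_novel", "antisense", "internal",
)
_PERCENT_DENOMINATOR = {
    "all": "all", "forward": "all", "reverse": "all",
    "protein_coding": "all", "leaderless": "protein_coding", "leadered": "protein_coding",
    "known_rna": "all",
    "novel": "all", "intergenic_novel": "novel", "antisense": "novel", "internal": "novel",
}


def percent(numerator: float, denominator: float, digits: int = 0) -> float:
    """100 * n/d rounded half-up to ``digits`` decimals (int when digits=0)."""
    if denominator == 0:
        raise ZeroDivisionError("percent: zero denominator")
    quant = Decimal(1).scaleb(-digits)
    numerator, denominator = Decimal(str(numerator)), Decimal(str(denominator))
    value = (Decimal(100) * numerator / denominator).quantize(
        quant, rounding=ROUND_HALF_UP
    )
    return int(value) if digits == 0 else float(value)


def summarize(classified: list[ClassifiedTss], replicons: list[str]) -> pd.DataFrame:
    """Per-replicon classification summary.

    Rows partition three ways: forward + reverse = all; leaderless +
    leadered = protein_coding; intergenic + antisense + internal = novel;
    and protein_coding + known_rna + novel = all. Percent columns use the
    block denominators noted in _PERCENT_DENOMINATOR (0 when empty).
    """
    unknown = {c.record.replicon for c in classified} - set(replicons)
    if unknown:
        raise ValueError(f"classified TSSs on unlisted replicon(s): {sorted(unknown)}")
    counts = pd.DataFrame(0, index=list(SUMMARY_ROWS), columns=replicons + ["total"])
    for c in classified:
        rows = ["all", "forward" if c.strand == "+" else "reverse", c.primary_class]
        if c.primary_class in PROTEIN_CLASSES:
            rows.append("protein_coding")
        if c.primary_class in NOVEL_CLASSES:
            rows.append("novel")
        for row in rows:
            counts.loc[row, c.record.replicon] += 1
            counts.loc[row, "total"] += 1
    counts["percent"] = [
        percent(counts.loc[row, "total"], counts.loc[_PERCENT_DENOMINATOR[row], "total"])
        if counts.loc[_PERCENT_DENOMINATOR[row], "total"] else 0
        for row in SUMMARY_ROWS
    ]
    return counts


def check_partitions(summary: pd.DataFrame) -> dict[str, bool]:
    """The three partition identities of the summary table, per column."""
    cols = [c for c in summary.columns if c != "percent"]
    t = summary[cols]
    return {
        "strand": bool((t.loc["forward"] + t.loc["reverse"] == t.loc["all"]).all()),
        "protein": bool((t.loc["leaderless"] + t.loc["leadered"] == t.loc["protein_coding"]).all()),
        "novel": bool(
            (t.loc["intergenic_novel"] + t.loc["antisense"] + t.loc["internal"] == t.loc["novel"]).all()
        ),
        "classes": bool(
            (t.loc["protein_coding"] + t.loc["known_rna"] + t.loc["novel"] == t.loc["all"]).all()
        ),
    }


# ------------------------------------------------------------------ pipeline

@dataclass
class PipelineConfig:
    synthetic: SynthConfig = dataclass_field(default_factory=SynthConfig)
    calling: CallParams = dataclass_field(default_factory=CallParams)
    p_stringent: float = 0.001
    p_relaxed: float = 0.01
    max_shift: int = 4
    min_utr_for_uorf: int = 150

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        if "synthetic" in data:
            cfg.synthetic = SynthConfig(**data["synthetic"])
        if "calling" in data:
            cfg.calling = CallParams(**data["calling"])
        for key in ("p_stringent", "p_relaxed", "max_shift", "min_utr_for_uorf"):
            if key in data:
                setattr(cfg, key, data[key])
        return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    genome: GenomeModel
    truth: list[TruthTss] | None
    records: list
    classified: list[ClassifiedTss]
    refine: RefineResult
    promoter_calls: list[PromoterCall]
    t_stringent: float
    t_relaxed: float
    summary: pd.DataFrame
    analyses: dict
    n_upstream_skipped: int

    def promoter_class_fractions(self) -> dict[str, float]:
        total = len(self.promoter_calls)
        out = {"stringent": 0.0, "relaxed": 0.0, "none": 0.0}
        if total:
            for call in self.promoter_calls:
                out[call.promoter_class] += 1
            out = {k: v / total for k, v in out.items()}
        return out


def call_consensus_tss(
    tracks: list[CoverageTrack], params: CallParams | None = None
) -> list:
    """Normalize, call per replicate/strand, merge, and form the consensus
    set of TSSs enriched in at least one replicate."""
    params = params or CallParams()
    normalized = normalize_coverage(tracks)
    by_key: dict[tuple, dict[str, CoverageTrack]] = {}
    for t in normalized:
        by_key.setdefault((t.replicate, t.replicon, t.strand), {})[t.treatment] = t
    per_replicate: dict[int, list] = {}
    for (rep, _, _), pair in sorted(by_key.items()):
        if MINUS_TEX not in pair or PLUS_TEX not in pair:
            raise ValueError(f"replicate {rep}: missing -TEX or +TEX track")
        candidates = call_tss(pair[MINUS_TEX], pair[PLUS_TEX], params, keep_unenriched=True)
        per_replicate.setdefault(rep, []).extend(merge_close(candidates))
    records = replicate_consensus([per_replicate[r] for r in sorted(per_replicate)])
    primary = [r for r in records if r.enriched_in]
    logger.info("calling: %d consensus positions, %d enriched (primary)", len(records), len(primary))
    return primary


def analyze_genome(
    genome: GenomeModel,
    tracks: list[CoverageTrack],
    config: PipelineConfig | None = None,
    truth: list[TruthTss] | None = None,
) -> PipelineResult:
    """Run calling -> classification -> promoter modelling -> downstream
    analyses on in-memory inputs."""
    config = config or PipelineConfig()

    records = call_consensus_tss(tracks, config.calling)
    classified = classify_all(records, genome)
    logger.info("classify: %d TSSs", len(classified))

    background = genome_background(genome)
    upstreams, id_to_class = [], {}
    skipped = 0
    for c in classified:
        u = extract_upstream(genome, c.record.replicon, c.position, c.strand)
        if u is None:
            skipped += 1
            continue
        upstreams.append(u)
        id_to_class[u.tss_id] = c
    refine = refine_pwm(upstreams, background, p=config.p_stringent, max_shift=config.max_shift)
    calls, t_stringent, t_relaxed = classify_promoters(
        refine.pwm, upstreams, config.p_stringent, config.p_relaxed
    )
    logger.info("promoter: thresholds stringent=%.3f relaxed=%.3f", t_stringent, t_relaxed)

    extension, leader_bins = utr_histograms(classified)
    protein = [c for c in classified if c.primary_class in PROTEIN_CLASSES]
    novel = [c for c in classified if c.primary_class in NOVEL_CLASSES]
    pairs = pair_sense_antisense(classified)
    analyses = {
        "extension_counts": extension,
        "leader_bins": leader_bins,
        "protein_deciles": expression_deciles(protein) if len(protein) >= 2 else None,
        "novel_deciles": expression_deciles(novel) if len(novel) >= 2 else None,
        "start_codons": start_codon_summary(classified, genome),
        "multi_tss": find_multi_tss(classified),
        "itss_deciles": decile_distribution(classified, genome, "internal"),
        "atss_deciles": decile_distribution(classified, genome, "antisense"),
        "uorfs": uorfs_in_long_utrs(classified, genome, min_utr=config.min_utr_for_uorf),
        "antisense_pairs": pairs,
        "reciprocity": reciprocity_stats(pairs) if len(pairs) >= 2 else None,
        "transposase_overlap": category_overlap(classified, genome, "transposase"),
        "logo": logo_matrix(
            [u.sequence[off : off + refine.pwm.width] for u, off in _positive_windows(upstreams, refine)],
            background,
        ),
    }
    summary = summarize(classified, genome.replicons)
    return PipelineResult(
        config=config,
        genome=genome,
        truth=truth,
        records=records,
        classified=classified,
        refine=refine,
        promoter_calls=calls,
        t_stringent=t_stringent,
        t_relaxed=t_relaxed,
        summary=summary,
        analyses=analyses,
        n_upstream_skipped=skipped,
    )


def _positive_windows(upstreams, refine: RefineResult):
    by_id = {u.tss_id: u for u in upstreams}
    return [(by_id[tss_id], off) for tss_id, off in refine.positives.items()]


def run_pipeline(config: PipelineConfig | None = None, outdir: str | Path | None = None
                 ) -> PipelineResult:
    """Full synthetic run: generate the study, simulate coverage, analyze,
    and (optionally) write all result tables plus a manifest."""
    config = config or PipelineConfig()
    logger.info("simulate: genome %d bp, seed %d", config.synthetic.genome_length, config.synthetic.seed)
    genome, truth = generate_genome(config.synthetic)
    tracks: list[CoverageTrack] = []
    for rep in range(1, config.synthetic.n_replicates + 1):
        minus, plus = simulate_coverage(genome, truth, config.synthetic, rep)
        tracks.extend(minus + plus)
    result = analyze_genome(genome, tracks, config, truth)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> dict:
    """Write every result table to ``outdir`` and a manifest.json listing
    files, parameters and stage counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    def save(name: str, df: pd.DataFrame) -> None:
        io.write_table(df, outdir / name)
        files[name] = str(outdir / name)

    save("classified.tsv", to_frame(result.classified))
    save("summary.tsv", result.summary.reset_index(names="row"))
    save("promoter_calls.tsv", pd.DataFrame(
        {
            "tss_id": [c.tss_id for c in result.promoter_calls],
            "score": [c.score if c.score is not None else np.nan for c in result.promoter_calls],
            "offset": [c.offset if c.offset is not None else -1 for c in result.promoter_calls],
            "promoter_class": [c.promoter_class for c in result.promoter_calls],
        }
    ))
    pwm = result.refine.pwm
    save("pwm.tsv", pd.DataFrame(
        np.vstack([pwm.counts, pwm.log_odds]).T,
        columns=["count_A", "count_C", "count_G", "count_T",
                 "logodds_A", "logodds_C", "logodds_G", "logodds_T"],
    ))
    contrib, info = result.analyses["logo"]
    save("logo.tsv", pd.DataFrame(
        np.vstack([contrib, info]).T,
        columns=["A", "C", "G", "T", "information"],
    ))
    save("utr_extension.tsv", result.analyses["extension_counts"].rename_axis("utr_length").reset_index())
    save("utr_leader_bins.tsv", result.analyses["leader_bins"].rename_axis("bin").reset_index())
    save("start_codons.tsv", result.analyses["start_codons"][0])
    save("multi_tss.tsv", result.analyses["multi_tss"])
    save("uorfs.tsv", uorf_table(result.analyses["uorfs"]))
    save("antisense_pairs.tsv", pairs_to_frame(result.analyses["antisense_pairs"]))
    save("itss_atss_deciles.tsv", pd.DataFrame(
        {
            "section": np.arange(1, 11),
            "iTSS": result.analyses["itss_deciles"],
            "aTSS": result.analyses["atss_deciles"],
        }
    ))

    manifest = {
        "package": "drnatss",
        "version": "0.1.0",
        "parameters": {
            "seed": result.config.synthetic.seed,
            "min_enrichment": result.config.calling.min_enrichment,
            "min_height": result.config.calling.min_height,
            "step_factor": result.config.calling.step_factor,
            "p_stringent": result.config.p_stringent,
            "p_relaxed": result.config.p_relaxed,
            "max_shift": result.config.max_shift,
        },
        "counts": {
            "tss": len(result.classified),
            "refine_iterations": result.refine.n_iterations,
            "refine_positives": len(result.refine.positives),
            "upstream_skipped": result.n_upstream_skipped,
        },
        "thresholds": {"stringent": result.t_stringent, "relaxed": result.t_relaxed},
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    files["manifest.json"] = str(outdir / "manifest.json")
    return manifest
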