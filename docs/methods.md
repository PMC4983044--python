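# Methods

This note documents the models and numerical choices behind `drnatss`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
option existed.

## Coverage model and TSS calling

Tracks hold strand-specific **5′-read-start counts per base**, not full
read-body coverage: the read-start signal is what single-nucleotide TSS
calling consumes, and read bodies would only add a nuisance background.
Normalization rescales every library by `min(mapped_reads)/mapped_reads`,
so values stay on the scale of real read counts in the shallowest library
and within-library ratios (hence rank order) are untouched.

Candidate criteria per replicate and strand:

| parameter | default | meaning |
|---|---|---|
| `min_height` | 5 normalized read starts | floor on the +TEX peak |
| `step_factor` | 2.0 | peak must be ≥ 2× the base one nt upstream |
| `min_enrichment` | 2.5 (inclusive) | +TEX/(−TEX + 1) ratio of a primary 5′ end |
| `pseudocount` | 1 read | avoids division by zero in the enrichment ratio |

The 2.5 enrichment cutoff is the scientifically meaningful number (it
discriminates 5′-triphosphate from processed 5′ ends); `min_height` and
`step_factor` are pragmatic defaults exposed in `CallParams`. The base at a
replicon edge is never a candidate (it has no upstream neighbour to step
from). Candidates closer than 10 nt are one TSS — single-linkage chains,
represented by the highest +TEX member, ties resolved to the most upstream
position in transcription direction. The same <10 nt rule identifies TSSs
across replicates; the consensus record keeps `detected_in` (height + step)
and `enriched_in` (ratio) separately, and the pipeline reports TSSs enriched
in at least one replicate. `average_coverage` is the mean normalized +TEX
height over detecting replicates.

## Classification

Distances are measured in transcription direction from the TSS to a gene's
5′ end; d = 0 means the TSS sits on the first base of the start codon.
Precedence: sense association with a protein-coding gene (leaderless
0–5 nt, leadered 6–250 nt) > known-RNA association (−3 to 250 nt; the small
retraction absorbs slightly over-long RNA annotations) > overlap (same
strand → internal, opposite → antisense) > intergenic novel. Within a rule
the nearest eligible gene wins. Transposase-category genes count as
protein-coding for the distance rules; their category matters only to the
overlap tabulations. A TSS inside genes on both strands is internal
(same-strand overlap preferred). The >250 nt novelty rule considers
same-strand gene starts only — UTR association is strand-directional, so
opposite-strand proximity does not block the novel call.

One consequence of sense-association-first precedence: a TSS with a
same-strand annotated gene start 1–250 nt downstream is classified
leaderless/leadered/known-RNA, never internal — so the downstream-gene flag
(`flag_downstream_gene`, distances 1–250 nt) is exposed as a standalone
query for externally supplied internal/antisense records and is empty on
pipeline output by construction.

Intragenic decile positions use `section = floor(10·offset/length)`,
clamped to the last section, with the offset measured from the gene's 5′
end on its own strand.

## Promoter model

Every TSS contributes a 71-mer whose last base is the first transcribed
base; TSSs closer than 71 nt to a replicon edge (or with ambiguous bases
upstream) are skipped and counted. The background q is the strand-symmetric
base composition of the complete genome — deliberately not of the 71-mer
collection, which is biased by the promoters themselves.

The PWM has width 28 and per-column log₂ odds
`m = log2(((count + 0.5)/(n + 2)) / q)`. The pseudocount of 0.5 per base per
column prevents −∞ odds; at pseudocount 0 a zero-frequency cell is guarded
to −30 bits. Score thresholds come from the **exact** distribution of the
PWM score of a random background window, computed by dynamic programming
over columns with scores floored to a 0.001 grid (flooring makes the
threshold conservative; the discretization error is bounded by
28 × 0.001 bits). The returned threshold is the smallest achievable grid
score whose tail probability is ≤ p. For widths ≤ 5 the DP is tested
against brute-force enumeration of all 4^W windows.

Refinement starts from the window whose 3′ edge sits 18 nt upstream of the
TSS in every sequence — wide enough to cover archaeal BRE+TATA spacing
(TATA 3′ edge ≈ 24 nt upstream) anywhere inside the 28-mer. Each iteration
rebuilds the PWM from the current positives, recomputes the p = 0.001
threshold, rescans all 71-mers on the given strand only (44 offsets),
determines the modal match offset, and keeps hits within ±4 nt of it,
realigned to their own offsets. Convergence is exact equality of the
positive set (ids and offsets) between successive iterations; a two-state
oscillation is detected, logged with both state sizes, and reported as
non-converged. The modal (peak) offset is used rather than the mean — the
match-position distribution is sharply unimodal and a mean would be dragged
by stragglers. Stringent/relaxed calls rescan the original unshifted
71-mers with the p = 0.001 and p = 0.01 thresholds; the resulting numeric
cutoffs are dataset-dependent outputs, reported, never hard-coded.

Logo matrices report per-column Kullback–Leibler information
`I_j = Σ_b f_bj log2(f_bj/q_b) ≥ 0` and signed per-base contributions
(negative when a base is rarer than background, matching inverted letters
in rendered logos), with 0·log 0 := 0.

## Peptide properties and uORFs

uORFs are ATG-initiated by default (GTG optional), must terminate at an
in-frame stop fully inside the UTR, and must encode ≥ 15 aa — consistent
with small uORF peptides fitting inside 150–250 nt UTRs; overlap with the
main ORF is excluded. pI is the bisection root (tolerance 10⁻³) of the
Henderson–Hasselbalch net-charge curve over the EMBOSS pKa set (N-term 8.6,
C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1); the test
suite checks it against an independent pH-grid search over the same charge
model. Molecular weight uses average residue masses plus one water
(Biopython), matching kDa-scale reporting. The intergenic-concatenation
utility joins regions sorted by length with the `TTAATTAATTAA` linker
(stop codons in all six frames) and emits ~2–3 kb chunks without ever
splitting a region; a chunk exceeds 3 kb only when a single region does,
and the final chunk may fall short of 2 kb.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes, at a
deliberately desk-sized scale: the default is a single 3 Mb replicon with
~630 truth TSSs in haloarchaeal proportions (leaderless ≈ 72 % of
protein-coding starts; antisense as the largest novel class), GC 0.67,
three replicates with depth factors (1.0, 1.25, 0.8). All randomness flows
from one master seed; per-replicate streams are derived deterministically.

- **Layout.** Genes are placed on alternating random strands with ≥ 500 nt
  gaps, inflated to spread the annotation over the whole replicon (the
  annotated span is kept ≤ 10 % of the genome; a `SizingError` rejects
  configurations that cannot satisfy this). The spacing guarantees every
  planted TSS respects its class's distance windows exactly, so
  classification recovery is a sharp test.
- **Sequence.** Background bases are i.i.d. at the configured GC; CDS
  regions are overwritten with start codon (ATG, or GTG at 9 % of
  leaderless genes), GC-weighted non-stop codons, and a stop. Leaderless
  truth TSSs sit exactly on the start codon's first base. 5′-UTR lengths mix
  a short exponential body with a 15 % long-UTR (150–250 nt) component, and
  30 % of long UTRs carry a planted 15–31 aa uORF.
- **Promoters.** Half of all truth TSSs (configurable) get the consensus
  `CGAAA`+`TTAT` planted with the TATA 3′ edge 24(+jitter ≤ 2) nt upstream.
- **Counts.** Per site and replicate, a gamma latent rate g (shape =
  `dispersion` = 10, mean 1) is shared between the two libraries:
  −TEX ~ Poisson(g·µ/5), +TEX ~ Poisson(g·µ) at primary sites (tex
  enrichment 5), both ~ Poisson(g·µ·0.5) at the one TEX-neutral processed
  site planted per expressed transcript. Marginals are exactly negative
  binomial; the shared latent encodes that both libraries are split from
  the same RNA sample, which keeps the enrichment ratio stable the way
  biological replicate noise does. Expression levels are a shifted
  log-normal (floor 50 + lognormal(ln 120, 0.6) expected +TEX read starts),
  i.e. "well above background"; leaderless transcripts get 4× that level
  and GTG-start genes half of it.
- **Antisense.** Sense/antisense expression pairs come from a Gaussian
  copula at ρ = −0.6 (both marginals strictly monotone in the latent
  normal, so the planted Spearman correlation is (6/π)·asin(ρ/2) ≈ −0.58);
  60 % of antisense host genes have no sense TSS at all, and a quarter of
  those are annotated as transposases.

What passing tests on this generator show — and do not show. They show the
pipeline's logic is correct under its own assumptions: exact class
recovery, full recall of well-expressed primary sites with zero calls at
TEX-neutral decoys, promoter-motif recovery from 80 %-planted upstream
sets, and recovery of the planted antisense structure. They do not show
robustness to the things real dRNA-Seq adds: mapping ambiguity and
multi-mapping reads, sequencing error, RNA secondary-structure biases in
library preparation (tRNAs are notoriously under-represented), expression
near the detection floor, overlapping genes and operonic read-through, or
promoters that diverge from a single consensus. Real thresholds may need
retuning at real depths.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive everywhere; reverse-strand windows are
  reverse-complemented so sequences always read 5′→3′ on the TSS strand.
- Expression deciles take the lowest/highest ⌊N/10⌋ records with ties
  broken by (coverage, position) for determinism; N < 20 logs a warning.
- `percent()` rounds half-up via decimal arithmetic (72 from 1329/1851,
  7.5 from 139/1851); summary-table percentages use block denominators
  (class of all; subclass of its block), 0 for an empty block.
- Refinement with fewer than 2 positives, or with no hits above threshold,
  raises a degenerate-motif error rather than returning a meaningless PWM;
  fewer than 50 input sequences logs a warning.
- "3′-end overlap" for category counts means the 3′-most 20 % of the gene
  (exposed as a parameter; no canonical definition exists).
- Sense coverage for an antisense pair aggregates by maximum over the
  gene's sense TSSs; the reciprocity Spearman uses only doubly-detected
  pairs and is reported as absent when fewer than two exist.

## Known limitations

- Single-replicon defaults; multi-replicon inputs are supported by the data
  model but the generator plants everything on one chromosome.
- The caller assumes read-start tracks; it has no deconvolution for peaks
  broadened by imprecise transcription initiation beyond the 10 nt merge.
- The promoter model is a single basal motif; no TFB/TBP paralog-specific
  submotifs, and no both-strand scanning (deliberate: promoters are
  strand-specific relative to their TSS).
- pI assumes free termini and no post-translational modification; values
  for very Cys/His-rich peptides depend strongly on the pKa set chosen.
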