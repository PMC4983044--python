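import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from drnatss.calling import TssRecord
from drnatss.genome import Feature, GenomeModel
from drnatss.report import PipelineConfig, run_pipeline
from drnatss.synthetic import SynthConfig, generate_genome, random_sequence

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# deliberately scaled-down study (89 truth TSSs) so every stage stays fast;
# class proportions follow the default configuration
SMALL = SynthConfig(
    genome_length=450_000,
    n_leaderless=24,
    n_leadered=16,
    n_known_rna=5,
    n_intergenic=8,
    n_internal=12,
    n_antisense=16,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SMALL


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_result(small_config):
    return run_pipeline(PipelineConfig(synthetic=small_config))


def make_record(position: int, strand: str, replicon: str = "chr", coverage: float = 10.0,
                support: int = 1) -> TssRecord:
    reps = frozenset(range(1, support + 1))
    return TssRecord(replicon, position, strand, reps, reps, coverage)


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    """3 kb hand-laid genome: a forward CDS, a reverse CDS, a known RNA and
    a transposase, with fixed start codons."""
    rng = np.random.default_rng(7)
    seq = list(random_sequence(rng, 3000, 0.5))
    seq[1000:1003] = list("ATG")       # geneA start codon (forward, 1001..1300)
    seq[1797:1800] = list("CAT")       # geneB start codon on '-' (1501..1800)
    features = [
        Feature("rnaC", "chr", 401, 520, "+", "known_rna"),
        Feature("geneA", "chr", 1001, 1300, "+", "CDS"),
        Feature("geneB", "chr", 1501, 1800, "-", "CDS"),
        Feature("tnpT", "chr", 2301, 2500, "+", "transposase"),
    ]
    return GenomeModel({"chr": "".join(seq)}, features)
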