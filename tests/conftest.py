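import numpy as np
import pytest
from hypothesis import settings

from re1scan.intervals import GenomicInterval, MergedPeak
from re1scan.pipeline import config_for_simulation, run_pipeline
from re1scan.scanner import MotifHit
from re1scan.synthetic_data import SimulationConfig, simulate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_peak(chrom="chr1", start=0, end=1000, support=("expA",)):
    return MergedPeak(GenomicInterval(chrom, start, end), frozenset(support))


def make_hit(start, width, strand, kind, score=20.0, chrom="chr1", peak=None):
    peak = peak or make_peak(chrom, 0, 10_000)
    return MotifHit(
        interval=GenomicInterval(chrom, start, start + width),
        strand=strand,
        segment_kind=kind,
        score=score,
        matched_seq="N" * width,
        source_peak=peak,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240417)


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The standard synthetic study (default config, seed 7)."""
    out = tmp_path_factory.mktemp("default_sim")
    return simulate(SimulationConfig(), out)


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    """Full pipeline run on the standard synthetic study."""
    out = tmp_path_factory.mktemp("default_run")
    return run_pipeline(config_for_simulation(default_sim, out))


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A fast, reduced synthetic study for behavioural tests."""
    cfg = SimulationConfig(
        seed=3,
        genome_length=400_000,
        n_universal_sites=8,
        n_line_specific_sites=8,
        n_singleton_peaks=4,
        n_motif_free_sites=4,
        n_blacklist_regions=2,
    )
    return simulate(cfg, tmp_path_factory.mktemp("small_sim"))
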