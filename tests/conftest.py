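import numpy as np
import pandas as pd
import pytest

from mmrsclc.synthdata import SimConfig, simulate_all, simulate_transcriptome


def small_config(seed: int = 0, **kw) -> SimConfig:
    """A scaled-down study: fast enough for unit tests, same structure."""
    defaults = dict(
        seed=seed,
        n_transcripts=12,
        cds_length_range=(300, 900),
        n_samples_per_group={"RP": 3, "RPM_flfl": 3, "RPM_flwt": 1},
        mutation_rate_per_group={"RP": 30.0, "RPM_flfl": 540.0, "RPM_flwt": 30.0},
        n_animals_per_group={"RP": 6, "RPM_flfl": 6, "RPM_flwt": 2},
        n_animals_per_arm=4,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def study():
    """One small simulated study shared across tests (read-only)."""
    return simulate_all(small_config(seed=7))


@pytest.fixture(scope="session")
def transcriptome():
    cfg = small_config(seed=3)
    transcripts, genome = simulate_transcriptome(cfg)
    return cfg, transcripts, genome


def make_variant_table(rows):
    """Tiny helper: rows of (sample, chrom, pos, ref, alt, depth)."""
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "depth"]
    )
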