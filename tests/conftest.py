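import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from popepigen.simulate import SimulationConfig, TraitSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared by unit tests (n=80, 2 chroms)."""
    cfg = SimulationConfig(
        seed=42, n_accessions=80,
        chrom_lengths={"chr1": 300_000, "chr2": 300_000},
        n_snps_per_chrom=150,
        sites_per_chrom={"CG": 300, "CHG": 150, "CHH": 200},
        n_cis_meqtl=10, cis_meqtl_r2=0.5,
        n_eqtm=6, eqtm_r2=0.4, n_eqtl=4, eqtl_r2=0.4, n_genes_per_chrom=25,
        traits={"LP": TraitSpec(n_ewas_loci=2, ewas_variance=0.10, h2_poly=0.3),
                "FL": TraitSpec(n_ewas_loci=1, ewas_variance=0.10, h2_poly=0.3)},
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_sites():
    return pd.DataFrame({
        "chrom": ["chr1"] * 4,
        "pos": [100, 200, 300, 400],
        "strand": ["+", "-", "+", "+"],
        "context": ["CG", "CHG", "CG", "CHH"],
    })
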