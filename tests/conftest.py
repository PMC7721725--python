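import numpy as np
import pandas as pd
import pytest

from methorigin.containers import BetaMatrix, ProbeAnnotation, SampleSheet
from methorigin.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(seed=42, n_probes=4000))


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, uncompressed configuration for exact-arithmetic checks."""
    return SimulationConfig(
        seed=7, n_probes=1200, noise_sd=0.0, type2_compression=1.0, frac_sex_probes=0.0
    )


@pytest.fixture()
def tiny_beta():
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(50, 8)),
        index=[f"cg{i:05d}" for i in range(50)],
        columns=[f"s{j}" for j in range(8)],
    )
    return BetaMatrix(values)


def make_annotation(probe_ids, chromosome="1", design_type="II", **overrides):
    """Helper building a minimal valid annotation for given probes."""
    n = len(probe_ids)
    table = pd.DataFrame(
        {
            "chromosome": overrides.get("chromosomes", [chromosome] * n),
            "position": overrides.get("positions", np.arange(1, n + 1) * 1000),
            "design_type": overrides.get("design_types", [design_type] * n),
            "chromatin_state": overrides.get("states", ["quiescent"] * n),
            "nearest_gene": overrides.get("genes", [""] * n),
            "arm": overrides.get("arms", ["q"] * n),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeAnnotation(table)
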