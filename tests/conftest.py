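import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from m6ascreen import IntensityTable, SampleSheet, SimConfig, simulate_experiment
from m6ascreen.simulate import planted_cohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")

NINE_SAMPLES = [f"{g}_{r}" for g in ("OA", "HP", "SOMA") for r in (1, 2, 3)]


def make_table(ip, sup, flags=None, genes=None, is_spikein=None, samples=None):
    """Hand-build a small IntensityTable from row-major lists."""
    ip = np.asarray(ip, float)
    n_probes, n_samples = ip.shape
    samples = samples or [f"S{j}" for j in range(n_samples)]
    probes = pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id")
    if flags is None:
        flags = np.full(ip.shape, "P")
    return IntensityTable(
        ip=pd.DataFrame(ip, index=probes, columns=samples),
        sup=pd.DataFrame(np.asarray(sup, float), index=probes, columns=samples),
        flags=pd.DataFrame(np.asarray(flags), index=probes, columns=samples),
        genes=pd.Series(genes or [f"G{i}" for i in range(n_probes)], index=probes),
        is_spikein=pd.Series(is_spikein or [False] * n_probes, index=probes),
    )


@pytest.fixture
def study_sheet():
    """The study design: three groups of three arrays."""
    return SampleSheet(
        pd.DataFrame(
            {
                "group": [s.split("_")[0] for s in NINE_SAMPLES],
                "replicate": [int(s.split("_")[1]) for s in NINE_SAMPLES],
            },
            index=pd.Index(NINE_SAMPLES, name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """A modest noisy cohort with one planted gene per evidence category."""
    config = SimConfig(
        n_genes=60,
        planted=planted_cohort({"i": 1, "ii": 1, "iii": 1, "iv": 1, "v": 1}),
        noise_sigma=0.15,
        seed=3,
    )
    return simulate_experiment(config)
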