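import numpy as np
import pandas as pd
import pytest

from clamarray.containers import (
    ArraySample,
    ControlType,
    Orientation,
    ProbeRecord,
    SignalMatrix,
    Site,
    Tissue,
)
from clamarray.simulate import SimulationConfig, simulate_experiment


def make_matrix(values: np.ndarray, probes=None, arrays=None, found=None) -> SignalMatrix:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    arrays = arrays or [f"a{j}" for j in range(values.shape[1])]
    vdf = pd.DataFrame(values, index=probes, columns=arrays)
    if found is None:
        fdf = pd.DataFrame(True, index=probes, columns=arrays)
    else:
        fdf = pd.DataFrame(np.asarray(found, dtype=bool), index=probes, columns=arrays)
    return SignalMatrix(vdf, fdf)


@pytest.fixture(scope="session")
def small_experiment():
    """Shared medium-size synthetic experiment (paired design, duplicates)."""
    cfg = SimulationConfig(
        n_transcripts=600,
        frac_paired=0.5,
        frac_nat=0.1,
        n_duplicated=60,
        arrays_per_group={"digestive_gland": 4, "gills": 3},
        frac_de=0.1,
        noise_log2_sd=0.25,
        n_gene_sets=10,
        seed=20_250_101,
    )
    return simulate_experiment(cfg)


@pytest.fixture
def tiny_annotation():
    return [
        ProbeRecord("t1_s1", "t1", Orientation.SENSE, 1),
        ProbeRecord("t1_as1", "t1", Orientation.ANTISENSE, 1),
        ProbeRecord("t2_s1", "t2", Orientation.SENSE, 1),
        ProbeRecord("t2_s2", "t2", Orientation.SENSE, 2),
        ProbeRecord("spike_00", "", Orientation.UNKNOWN, 1, ControlType.SPIKE_IN),
        ProbeRecord("neg_00", "", Orientation.UNKNOWN, 1, ControlType.NEGATIVE),
    ]


@pytest.fixture
def tiny_samples():
    return [
        ArraySample("dg1", Tissue.DIGESTIVE_GLAND, Site.CLEAN, "pool1"),
        ArraySample("dg2", Tissue.DIGESTIVE_GLAND, Site.CLEAN, "pool2"),
        ArraySample("gi1", Tissue.GILLS, Site.CLEAN, "pool3"),
        ArraySample("gi2", Tissue.GILLS, Site.CLEAN, "pool4"),
    ]
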