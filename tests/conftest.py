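import numpy as np
import pandas as pd
import pytest

from epiclone import synthetic_data as sd


@pytest.fixture(scope="session")
def small_mutation_cohort():
    cfg = sd.SimConfig(seed=11, n_patients=60)
    return sd.simulate_mutation_cohort(cfg)


@pytest.fixture(scope="session")
def small_bulk_cohort():
    cfg = sd.SimConfig(seed=12, n_peaks=1200, signature_size=80, n_bulk_patients=8)
    return sd.simulate_bulk_chromatin_cohort(cfg)


@pytest.fixture(scope="session")
def small_reference():
    cfg = sd.SimConfig(seed=13, n_peaks=1500, cells_per_type=60,
                       mean_reads_per_cell=1200.0)
    return sd.simulate_reference_hematopoiesis(cfg)


@pytest.fixture(scope="session")
def small_mito():
    cfg = sd.SimConfig(seed=14, n_peaks=800, n_cells_per_timepoint=400)
    return sd.simulate_mito_scatac(cfg)


@pytest.fixture
def toy_peaks():
    return pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [1000, 3000, 500],
        "end": [1500, 3500, 1000],
    })


def brute_force_classify(vaf_dx, vaf_rel):
    """Independent reimplementation of the VAF threshold rule for oracles."""
    if vaf_dx < 0.05 and vaf_rel > 0.1:
        return "gained"
    if vaf_dx > 0.1 and vaf_rel < 0.05:
        return "lost"
    return "stable"


def brute_force_count(sites: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Quadratic cut-site counting oracle."""
    out = np.zeros(len(peaks), dtype=int)
    for i, (_, pk) in enumerate(peaks.iterrows()):
        for _, s in sites.iterrows():
            if s["chrom"] == pk["chrom"] and pk["start"] <= s["pos"] < pk["end"]:
                out[i] += 1
    return out
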