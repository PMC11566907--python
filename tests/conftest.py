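import numpy as np
import pandas as pd
import pytest

from screentriage import normalize_screen, call_hits, morgan_fingerprints
from screentriage import synthetic as syn
from screentriage.config import SimulationConfig


@pytest.fixture(scope="session")
def small_config():
    """One-plate-scale campaign with an inflated hit rate for clustering tests."""
    return SimulationConfig(n_compounds=640, seed=3, active_fraction=0.05)


@pytest.fixture(scope="session")
def small_campaign(small_config):
    """Library + screened/normalized records + ground truth, generated once."""
    lib = syn.generate_library(small_config)
    readings, truth = syn.simulate_primary_screen(lib, small_config)
    normed, qc = normalize_screen(readings)
    samples = normed[normed["role"] == "sample"][["compound_id", "k_norm"]]
    records = lib.merge(samples, on="compound_id")
    return {
        "config": small_config,
        "library": lib,
        "readings": readings,
        "truth": truth,
        "normalized": normed,
        "qc": qc,
        "records": records,
    }


@pytest.fixture(scope="session")
def hit_records(small_campaign):
    records = small_campaign["records"]
    hit_ids = sorted(call_hits(records, threshold=50.0))
    hit_rec = records[records["compound_id"].isin(hit_ids)].reset_index(drop=True)
    fps = morgan_fingerprints(hit_rec["smiles"].tolist())
    return hit_rec, fps


def make_plate(mu_neg, sigma_neg, mu_pos, sigma_pos, n_each=2, plate_id="P001"):
    """Plate with controls of exact sample mean/SD (ddof=1) and no samples.

    n wells alternating mu +/- sigma*sqrt((n-1)/n) have sample SD exactly
    sigma for any even n.
    """
    assert n_each % 2 == 0
    rows = []
    scale = np.sqrt((n_each - 1) / n_each)
    d_n = sigma_neg * scale
    d_p = sigma_pos * scale
    for i in range(n_each):
        sign = 1 if i % 2 == 0 else -1
        rows.append((plate_id, f"A{i + 1:02d}", "neg", "", mu_neg + sign * d_n))
        rows.append((plate_id, f"B{i + 1:02d}", "pos", "", mu_pos + sign * d_p))
    return pd.DataFrame(
        rows, columns=["plate_id", "well", "role", "compound_id", "raw_value"]
    )
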