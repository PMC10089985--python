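import numpy as np
import pandas as pd
import pytest

import harborhab as hh


def det_frame(rows):
    """Build a detection frame from (tag, receiver, seconds-offset) tuples."""
    base = pd.Timestamp("2016-06-01")
    return pd.DataFrame({
        "det_id": np.arange(len(rows)),
        "timestamp": [base + pd.Timedelta(seconds=float(s)) for _, _, s in rows],
        "receiver_id": [r for _, r, _ in rows],
        "tag_id": [t for t, _, _ in rows],
    })


SMALL_CFG = dict(n_nodes=12, n_days=400, species=("largemouth_bass", "walleye"),
                 n_per_species=8, n_spurious=30)


@pytest.fixture(scope="session")
def small_study():
    """A small two-species study with contaminants."""
    return hh.simulate_study(hh.SimConfig(**SMALL_CFG), seed=11)


@pytest.fixture(scope="session")
def clean_study():
    """Same design, contaminant-free."""
    cfg = dict(SMALL_CFG, n_spurious=0, dead_tags_per_species=0)
    return hh.simulate_study(hh.SimConfig(**cfg), seed=11)


@pytest.fixture(scope="session")
def clean_presence(clean_study):
    qc = hh.run_qc(clean_study.detections, clean_study.tags)
    table = hh.build_daily_presence(
        qc.detections, clean_study.deployments, clean_study.nodes,
        clean_study.tags, qc.windows)
    return hh.filter_min_active(table)
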