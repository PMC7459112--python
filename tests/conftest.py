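import numpy as np
import pandas as pd
import pytest

import terraflux as tf


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study (seed 1): dem, soil fields, campaign panel."""
    return tf.generate_dataset(seed=1)


@pytest.fixture(scope="session")
def merged_table(dataset):
    """Proxy table merged with terrain extraction for seed 1, levels 1-5."""
    dem, _, panel = dataset
    stack = tf.build_pyramid(dem, max_level=5)
    ext = tf.extract_at_positions(stack, panel.positions)
    return tf.compute_proxies(panel).merge(
        ext.drop(columns=["x", "y"]), on="position_id"
    )


@pytest.fixture(scope="session")
def multi_seed_tables():
    """Merged proxy+terrain tables for 20 generator seeds (shared by the
    qualitative-structure checks)."""
    tables = []
    for seed in range(20):
        dem, _, panel = tf.generate_dataset(seed=seed)
        stack = tf.build_pyramid(dem, max_level=5)
        ext = tf.extract_at_positions(stack, panel.positions)
        t = tf.compute_proxies(panel).merge(
            ext.drop(columns=["x", "y"]), on="position_id"
        )
        t["ALT"] = [dem.value_at(x, y) for x, y in zip(t["x"], t["y"])]
        tables.append(t)
    return tables


def make_panel(rs: np.ndarray, swc=None, soc=None) -> tf.CampaignPanel:
    """Tiny campaign panel from an (n_positions, n_campaigns) Rs matrix."""
    rs = np.asarray(rs, dtype=float)
    n, m = rs.shape
    pids = [f"P{i + 1:02d}" for i in range(n)]
    cids = [f"C{j + 1:02d}" for j in range(m)]
    idx = pd.Index(pids, name="position_id")
    mk = lambda a: pd.DataFrame(np.asarray(a, dtype=float), index=idx, columns=cids)
    return tf.CampaignPanel(
        positions=pd.DataFrame(
            {"position_id": pids, "x": np.arange(n, dtype=float), "y": np.zeros(n)}
        ),
        campaigns=pd.DataFrame({"campaign_id": cids, "date": [f"d{j}" for j in range(m)]}),
        rs=mk(rs),
        ts=mk(np.full((n, m), 15.0)),
        swc=mk(np.full((n, m), 20.0) if swc is None else swc),
        soc=mk(np.full((n, m), np.nan) if soc is None else soc),
    )
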