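import numpy as np
import pandas as pd
import pytest

from steersense.synthdata import SimConfig


@pytest.fixture(scope="session")
def tiny_config():
    """Three steers, 15 min each: enough blocks for segmentation tests."""
    return SimConfig(n_steers=3, n_trials=3, duration=900.0, seed=7)


def make_feature_table(
    n_steers=10,
    blocks_per_steer=30,
    n_noise_features=3,
    class_means=((0.0, 0.0), (2.0, 0.0), (0.0, 2.0)),
    noise_sd=0.5,
    seed=0,
):
    """Small block-level table with known signal/noise feature structure.

    Features sig0, sig1 carry class separation per ``class_means``; the
    remaining ``noise`` features are label-independent. Labels cycle through
    the three behaviours so every steer has all classes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    labels = np.array(["eating", "rumination", "other"], dtype=object)
    for s in range(n_steers):
        sid = f"steer{s + 1:02d}"
        tid = f"trial{s % 3 + 1}"
        y = rng.integers(0, 3, blocks_per_steer)
        for b in range(blocks_per_steer):
            c = int(y[b])
            row = {
                "steer_id": sid,
                "trial_id": tid,
                "block_index": b,
                "label": labels[c],
                "purity": 1.0,
                "sig0": class_means[c][0] + rng.normal(0, noise_sd),
                "sig1": class_means[c][1] + rng.normal(0, noise_sd),
            }
            for j in range(n_noise_features):
                row[f"noise{j}"] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def signal_table():
    return make_feature_table()
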