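import io

import numpy as np
import pandas as pd
import pytest

import tempagree as ta


def make_table(rows, devices=ta.DEFAULT_DEVICES):
    """rows: iterable of (participant_id, device, time_min, temp_c)."""
    df = pd.DataFrame(rows, columns=["participant_id", "device", "time_min", "temp_c"])
    return ta.MeasurementTable(df, devices=devices)


@pytest.fixture
def full_grid_table():
    """2 participants x 3 devices x 4 time points, all readings present."""
    rows = []
    base = {"P1": 36.8, "P2": 36.4}
    bias = {"heat_flux": 0.0, "oral": 0.3, "infrared": -0.2}
    for pid in ("P1", "P2"):
        for dev in ta.DEFAULT_DEVICES:
            for j, t in enumerate((0, 10, 20, 30)):
                rows.append((pid, dev, t, base[pid] + bias[dev] - 0.1 * j))
    return make_table(rows)


@pytest.fixture
def full_grid_csv(full_grid_table, tmp_path):
    path = tmp_path / "table.csv"
    ta.write_measurements(full_grid_table, path)
    return path


@pytest.fixture
def clean_config():
    """Small synthetic study with no missing/erroneous readings."""
    return ta.SyntheticConfig(
        n_participants=40, missing_prob=0.0, erroneous_prob=0.0, seed=11
    )


@pytest.fixture
def clean_table(clean_config):
    table, _ = ta.generate_table(clean_config)
    return table


@pytest.fixture
def study_table():
    """Default-size synthetic study with corruption, as in a realistic run."""
    table, _ = ta.generate_table(ta.SyntheticConfig(seed=20210802))
    return table


def simulate_differences(rng, n_participants, n_per, mu, sigma_b, sigma_w):
    """Direct draws from the difference model d_ij = mu + b_i + e_ij."""
    b = rng.normal(0.0, sigma_b, size=n_participants)
    diffs = mu + np.repeat(b, n_per) + rng.normal(
        0.0, sigma_w, size=n_participants * n_per
    )
    pid = np.repeat([f"P{i:03d}" for i in range(n_participants)], n_per)
    time = np.tile(np.arange(n_per) * 10, n_participants)
    return diffs, pid, time


def pairs_from_differences(diffs, pid, time, anchor=36.5):
    """Wrap raw differences into a PairedDifferenceSet around an anchor mean."""
    df = pd.DataFrame({
        "participant_id": pid,
        "time_min": time,
        "value_a": anchor + diffs / 2.0,
        "value_b": anchor - diffs / 2.0,
    })
    df["pair_mean"] = (df["value_a"] + df["value_b"]) / 2.0
    df["diff"] = df["value_a"] - df["value_b"]
    return ta.PairedDifferenceSet("a", "b", df)
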