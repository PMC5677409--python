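import numpy as np
import pandas as pd
import pytest

import seatsense as ss


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 subjects, 3 minutes per activity: fast but covers all activities."""
    streams, manifest = ss.simulate_cohort(
        n_subjects=2, per_activity_minutes=3.0, seed=7
    )
    return streams, manifest


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    """Std + ApEn feature table extracted from the tiny cohort."""
    streams, _ = tiny_cohort
    rows = []
    for stream in streams:
        cop = ss.compute_cop(stream)
        rows.extend(
            ss.extract_features(
                stream, cop, ss.WindowConfig(), ss.ApEnParams(), sets="both"
            )
        )
    return ss.feature_frame(rows)


@pytest.fixture()
def simple_stream():
    """100-sample constant-force stream with labels, for I/O round-trips."""
    n = 100
    rng = np.random.default_rng(0)
    return ss.RawStream(
        t=np.arange(n) / 10.0,
        fsr=rng.uniform(1.0, 5.0, size=(n, 6)),
        gyro_x=rng.normal(size=n),
        gyro_y=rng.normal(size=n),
        fs=10.0,
        label=np.array(["reading"] * n, dtype=object),
        subject="S1",
    )


def separable_rows(n_per_class: int = 20, seed: int = 0) -> pd.DataFrame:
    """Two perfectly separable classes in one feature."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1.0, 0.0, size=n_per_class)
    b = rng.uniform(1.0, 2.0, size=n_per_class)
    return pd.DataFrame(
        {
            "f": np.concatenate([a, b]),
            "activity": ["reading"] * n_per_class + ["swing"] * n_per_class,
        }
    )
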