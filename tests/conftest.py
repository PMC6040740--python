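import numpy as np
import pandas as pd
import pytest

from ocrstats import SimConfig, simulate_plates


@pytest.fixture(scope="session")
def noise_free():
    """One plate with zero noise: exact interpolation territory."""
    cfg = SimConfig(
        n_plates=1, sigma_noise=0.0, sigma_well=0.0, sigma_plate_interval=0.0, seed=0
    )
    return simulate_plates(cfg)


@pytest.fixture(scope="session")
def default_plates():
    """Three default-noise plates, clean (no injected outliers)."""
    return simulate_plates(SimConfig(seed=42))


def make_plate_df(levels, wells_per_biosample=2, points_per_interval=3, plate_id="P01",
                  beta=None, rng=None):
    """Small hand-built plate: levels = {biosample: (t1, t2, t3, t4) log scale}."""
    rows = []
    widx = 0
    letters = "ABCDEFGH"
    for bios, theta in levels.items():
        for _ in range(wells_per_biosample):
            well = f"{letters[widx // 12]}{widx % 12 + 1}"
            widx += 1
            b = beta.get(well, 0.0) if beta else 0.0
            t = 0
            for interv in (1, 2, 3, 4):
                for _ in range(points_per_interval):
                    t += 1
                    y = theta[interv - 1] + b
                    if rng is not None:
                        y = y + rng.normal(0, 0.05)
                    rows.append(
                        {
                            "plate_id": plate_id,
                            "well": well,
                            "biosample": bios,
                            "time_point": t,
                            "interval": interv,
                            "ocr": float(np.exp(y)),
                            "is_blank": False,
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture
def hand_plate():
    """Two biosamples at the canonical (100, 40, 150, 20) pmol/min levels."""
    theta = (np.log(100), np.log(40), np.log(150), np.log(20))
    return make_plate_df({"A": theta, "B": theta})
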