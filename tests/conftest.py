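import numpy as np
import pandas as pd
import pytest

from dcrws.model import McmcConfig, run_mcmc
from dcrws.prefilter import prefilter
from dcrws.simulate import (
    GulfSpec,
    SimulationConfig,
    make_synthetic_coastline,
    simulate_track,
)


@pytest.fixture(scope="session")
def gulf_spec():
    return GulfSpec()


@pytest.fixture(scope="session")
def coastline(gulf_spec):
    return make_synthetic_coastline(gulf_spec)


@pytest.fixture(scope="session")
def small_track():
    """A 40-day synthetic tag under the default study-like conditions."""
    return simulate_track(SimulationConfig(n_days=40, seed=11))


@pytest.fixture(scope="session")
def small_filtered(small_track):
    return prefilter(small_track.fixes)


@pytest.fixture(scope="session")
def small_samples(small_filtered):
    """A short but real MCMC fit, shared by posterior-summary tests."""
    cfg = McmcConfig(n_iter=1500, burn_in=500, thin=2, seed=7)
    return run_mcmc(small_filtered, config=cfg)


def random_fix_table(rng, n, ptts=("p1", "p2"), duplicate_rate=0.0):
    """Random fix table for oracle comparisons."""
    lcs = np.array(["3", "2", "1", "0", "A", "B", "Z"])
    base = pd.Timestamp("2001-03-26 00:00:00", tz="UTC")
    rows = {
        "ptt": rng.choice(ptts, size=n),
        "timestamp": base + pd.to_timedelta(rng.uniform(0, 30 * 24 * 60, size=n), unit="m"),
        "lc": rng.choice(lcs, size=n),
        "lon": rng.uniform(-114, -109, size=n),
        "lat": rng.uniform(23, 32, size=n),
    }
    df = pd.DataFrame(rows)
    n_dup = int(duplicate_rate * n)
    if n_dup:
        src = df.sample(n=n_dup, random_state=int(rng.integers(2**31)))
        dup = src.copy()
        dup["lc"] = rng.choice(lcs, size=n_dup)  # same place/time, other LC
        df = pd.concat([df, dup], ignore_index=True)
    return df.sort_values(["ptt", "timestamp"], ignore_index=True)
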