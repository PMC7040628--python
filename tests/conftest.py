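import numpy as np
import pandas as pd
import pytest

from xylokin.core import CellCountObservation


@pytest.fixture
def simple_counts():
    """Three radial files, one tree, two days."""
    rows = []
    for day, (c, e, l, m) in {60: (5, 2, 0, 0), 70: (6, 4, 1, 0)}.items():
        for f, bump in ((1, 0), (2, 1), (3, 2)):
            rows.append(
                CellCountObservation(
                    tree_id="t1",
                    group="control",
                    season_day=day,
                    radial_file=f,
                    n_cambial=c,
                    n_enlarging=e,
                    n_thickening=l,
                    n_mature=m + bump,
                )
            )
    return rows


@pytest.fixture(scope="session")
def bump_data():
    """Known Gaussian-bump response, 5 trees x 38 dates, noise sd 0.5."""
    rng = np.random.default_rng(42)
    days = np.arange(60, 431, 10)
    truth = lambda t: 6.0 * np.exp(-(((t - 85.0) / 30.0) ** 2))
    rows = [
        (f"t{k}", t, truth(t) + 0.5 * rng.standard_normal())
        for k in range(5)
        for t in days
    ]
    df = pd.DataFrame(rows, columns=["tree_id", "season_day", "value"])
    return df, truth


@pytest.fixture(scope="session")
def paper_fit():
    """Default-scenario simulation pushed through the smoothing stage once."""
    import xylokin as xk

    cfg = xk.default_paper_scenario(seed=2017)
    sim = xk.synthetic.simulate(cfg)
    obs = xk.synthetic.observe_counts(sim)
    mean_counts = xk.average_radial_files(obs)
    curves = xk.fit_group_phase_curves(mean_counts)
    return sim, mean_counts, curves
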