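import numpy as np
import pandas as pd
import pytest

from hdtrial import SimConfig, SiteConfig, TrialTable, generate_trial


@pytest.fixture
def small_table() -> TrialTable:
    """A tiny hand-built two-site trial, all trees alive."""
    rows = []
    rng = np.random.default_rng(42)
    for site in ("S1", "S2"):
        for block in ("B1", "B2"):
            for prov in ("A", "B", "C"):
                d = float(rng.uniform(8, 30))
                h = 1.3 + 20 * (1 - np.exp(-0.03 * d**1.2)) + rng.normal(0, 0.5)
                rows.append((site, prov, block, f"{site}{block}{prov}",
                             d, h, 1))
    df = pd.DataFrame(rows, columns=["site", "provenance", "block", "tree",
                                     "dbh_cm", "height_m", "alive"])
    return TrialTable(df, planned_per_block=3)


@pytest.fixture
def weibull_trial() -> TrialTable:
    """Noise-free single-site trial on a known Weibull curve."""
    cfg = SimConfig(
        sites=[SiteConfig(label="S", n_blocks=4, dbh_mean=18.0,
                          trees_per_plot=4)],
        provenances=["A", "B", "Y"],
        provenance_offsets={"S": {"A": 1.0, "B": -1.0, "Y": 0.0}},
        phi0=22.0, phi1=1.3, phi2=0.03,
        sigma=0.0, sigma0_block=0.0, sigma1_block=0.0, gamma=0.0,
        survival_prob=1.0, reference_site="S", seed=7,
    )
    return generate_trial(cfg)
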