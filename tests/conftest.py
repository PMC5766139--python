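import numpy as np
import pytest

from speiyield import (
    SiteSpec,
    compute_spei,
    default_panel_params,
    generate_climate,
    generate_yields,
    season_covariate,
)


def small_sites(n=3):
    """A compact 3-station network spanning the study latitudes."""
    specs = [
        ("North", 34.5, 13.0, 750.0, 0.04),
        ("Middle", 32.5, 14.5, 950.0, 0.055),
        ("South", 31.1, 16.0, 1200.0, 0.07),
    ]
    return [
        SiteSpec(name=n_, latitude=lat, mean_annual_temp=t, annual_precip=p, warming_slope=w)
        for n_, lat, t, p, w in specs[:n]
    ]


@pytest.fixture(scope="session")
def climate_panel():
    """36 years of monthly climate for 3 sites, fixed seed."""
    return generate_climate(small_sites(), start_year=1979, n_years=36, seed=11)


@pytest.fixture(scope="session")
def spei_frame(climate_panel):
    """SPEI at scales 1 and 3 for the session climate panel."""
    return compute_spei(climate_panel, scales=[1, 3])


@pytest.fixture(scope="session")
def yield_panel(spei_frame):
    """Yields generated from the panel model on the SPEI_3_S3 covariate."""
    cov = season_covariate(spei_frame[spei_frame.scale_k == 3], "S3")
    params = default_panel_params([s.name for s in small_sites()])
    return generate_yields(cov, params, seed=12)
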