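import numpy as np
import pytest

import vegtherm as vt


@pytest.fixture(scope="session")
def noisefree_scene():
    """Small scene with every noise source off: the exact-recovery oracle."""
    cfg = vt.SceneConfig(
        nx=10, ny=12, n_days=12, seed=11,
        noise_sd_lst=0.0, noise_sd_fvc=0.0, noise_sd_albedo=0.0,
        interannual_noise_sd=0.0, cloud_gap_prob=0.0,
    )
    return vt.generate_scene(cfg)


@pytest.fixture(scope="session")
def default_scene():
    """Default-noise scene at a size adequate for bin fitting."""
    return vt.generate_scene(vt.SceneConfig(nx=20, ny=24, n_days=30, seed=7))


@pytest.fixture
def small_cfg():
    return vt.AnalysisConfig(min_pixels_per_regressor=1, min_valid_days=1)


def make_trendless_panel(n_pixels, n_years, betas, noise_sd, seed,
                         intercept=305.0, ndvi_mean=0.5):
    """Annual panels whose regressor draws are orthogonalized against the
    year index, so the trend screen never triggers and the planted
    coefficients are the exact generative truth."""
    rng = np.random.default_rng(seed)
    b_ndvi, b_p, b_rs = betas
    t = np.arange(n_years, dtype=float)
    t_c = t - t.mean()

    def draw(loc, sd):
        x = rng.normal(loc, sd, (n_pixels, n_years))
        slope = (x @ t_c) / (t_c @ t_c)
        return x - slope[:, None] * t_c[None, :]

    ndvi = draw(ndvi_mean, 0.05)
    p = draw(800.0, 80.0)
    rs = draw(250.0, 10.0)
    lst = intercept + b_ndvi * ndvi + b_p * p + b_rs * rs
    if noise_sd > 0:
        lst = lst + rng.normal(0.0, noise_sd, lst.shape)
    return vt.AnnualPanel(ndvi=ndvi, lst=lst, p=p, rs=rs,
                          years=np.arange(2003, 2003 + n_years))
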