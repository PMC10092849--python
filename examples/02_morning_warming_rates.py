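"""Compute diurnal warming-rate statistics from a 15-min LST cube.

The daily median of 07:00-11:00 local-solar finite-difference rates is the
pipeline's core temperature statistic: it integrates the rising limb of
the diurnal cycle and is robust to cloud gaps.  Its spatial correlation
with the 13:30 - 06:00 diurnal temperature range shows why DTR is an
acceptable stand-in when 15-min data are unavailable.
"""

import numpy as np

import vegtherm as vt

scene = vt.generate_scene(vt.SceneConfig(nx=20, ny=20, n_days=30, seed=1))
cfg = vt.AnalysisConfig(min_valid_days=25)

rate_map = vt.compute_rate_map(scene.cube, cfg)

daily = rate_map.rate_daily
print(f"daily rates: {np.isfinite(daily).mean() * 100:.1f}% of pixel-days valid "
      f"(cloud-gap probability {scene.config.cloud_gap_prob})")
print(f"annual-mean morning rate: {np.nanmean(rate_map.rate_annual_mean):.2f} K/h "
      f"(range {np.nanmin(rate_map.rate_annual_mean):.2f}-"
      f"{np.nanmax(rate_map.rate_annual_mean):.2f})")
print(f"mean DTR: {np.nanmean(rate_map.dtr):.1f} K")

corr = vt.rate_dtr_correlation(daily[:, 0], rate_map.dtr[:, 0])
print(f"spatial rate-DTR correlation (day 1): {corr:.3f}")
# On the piecewise-linear cycle DTR = 6 h x rate + const, so the
# correlation is ~1; on real scenes it typically stays above 0.8.
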