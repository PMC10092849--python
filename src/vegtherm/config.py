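"""Analysis configuration and shared constants."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import yaml

#: Multiplicative factor that renders the energy-dissipation efficiency
#: (negated slope of the d(LST)/dt-versus-LST regression, units h^-1)
#: unitless.  Follows the force-restore normalization of Bateni & Entekhabi
#: (2012, their Eq. 12).
DISSIPATION_NORMALIZATION = 32.5

#: Conditioning-bin tile widths: twice the matching half-widths, so that a
#: tiling anchored at zero guarantees every member lies within the stated
#: tolerance of its bin center.
THETA_BIN_WIDTH = 0.005  # m3 m-3  (half-width +-0.0025)
RS_BIN_WIDTH = 2.5       # W m-2   (half-width +-1.25)


@dataclass
class AnalysisConfig:
    """Tunable knobs of the attribution pipeline.

    Defaults mirror the study protocol: +-0.0025 m3/m3 and +-1.25 W/m2
    conditioning tolerances, a 500 mm/yr dryland threshold probed at
    +-200 mm/yr, alpha = 0.05 significance, effects reported per 0.1 FVC,
    the 07:00-11:00 local-solar morning window, the 12:30-14:30 afternoon
    window and the 13:30 - 06:00 diurnal temperature range.
    """

    theta_half_width: float = 0.0025      # m3 m-3
    rs_half_width: float = 1.25           # W m-2
    dryland_threshold: float = 500.0      # mm yr-1
    dryland_sensitivity: float = 200.0    # mm yr-1
    alpha_level: float = 0.05
    fvc_report_step: float = 0.1
    morning_window: Tuple[float, float] = (7.0, 11.0)    # [start, end) local solar hours
    afternoon_window: Tuple[float, float] = (12.5, 14.5) # [start, end] local solar hours
    dtr_times: Tuple[float, float] = (13.5, 6.0)         # max, min local solar hours
    max_gap_hours: float = 2.0            # longest QC gap an increment may span
    min_valid_days: int = 30              # valid days required for an annual rate mean
    min_pixels_per_regressor: int = 10
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_half_width <= 0 or self.rs_half_width <= 0:
            raise ValueError("bin half-widths must be positive")
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must lie in (0, 1)")
        for name in ("morning_window", "afternoon_window", "dtr_times"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo < 24.0 and 0.0 <= hi < 24.0):
                raise ValueError(f"{name} must lie within [0, 24) hours")

    @property
    def theta_bin_width(self) -> float:
        return 2.0 * self.theta_half_width

    @property
    def rs_bin_width(self) -> float:
        return 2.0 * self.rs_half_width

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("morning_window", "afternoon_window", "dtr_times"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)
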