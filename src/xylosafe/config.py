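"""Study configuration for the synthetic-data generator.

Defaults encode the design and generating values of a 30-site × 10-tree
beech gradient campaign: per-SD fixed-effect sizes, site and residual
SDs of the P50 mixed model, covariate ranges spanning the observed site
table, and the cavitron measurement protocol (start pressure −0.37 MPa,
stepwise descent until 90 % loss of conductivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from xylosafe.errors import ConfigurationError

__all__ = ["StudyConfig"]


def _default_fixed_effects() -> dict[str, float]:
    # per-SD effects on P50 (MPa); branch age enters on the log scale
    return {
        "CWB": 0.004,
        "AWC": 0.086,
        "height": 0.000,
        "log_branch_age": 0.088,
        "CI": -0.011,
    }


def _default_covariate_ranges() -> dict[str, tuple[float, float]]:
    # site-level ranges of the study gradient (units: CWB mm/month,
    # AWC mm, MAP mm/yr, MAT °C, height m, DBH cm)
    return {
        "CWB": (-10.82, 25.56),
        "AWC": (43.4, 301.0),
        "MAP": (522.0, 886.2),
        "MAT": (9.0, 10.0),
        "height": (21.1, 34.4),
        "DBH": (35.7, 58.2),
    }


@dataclass
class StudyConfig:
    """Generating parameters for a synthetic hydraulic-trait study."""

    n_sites: int = 30
    n_trees_per_site: int = 10
    seed: int = 0

    # P50 generating model (MPa; effects per predictor SD)
    intercept_p50: float = -3.381
    fixed_effects: dict[str, float] = field(default_factory=_default_fixed_effects)
    site_sd: float = 0.199
    residual_sd: float = 0.279

    # log-slope and Ks generating distributions (site + residual components)
    slope_log_mean: float = 1.049
    slope_log_site_sd: float = 0.118
    slope_log_residual_sd: float = 0.258
    ks_mean: float = 1.536
    ks_site_sd: float = 0.175
    ks_residual_sd: float = 0.535

    covariate_ranges: dict[str, tuple[float, float]] = field(
        default_factory=_default_covariate_ranges
    )

    # branch ages: shifted lognormal, observed range and mean
    branch_age_range: tuple[float, float] = (1.5, 20.5)
    branch_age_mean: float = 6.0

    # cavitron protocol
    pressure_start: float = -0.37  # MPa
    pressure_step: float = -0.25   # MPa per step (negative increment)
    loss_cutoff: float = 0.90      # stop at 90 % loss of conductivity
    noise_cv: float = 0.05         # measurement noise SD as fraction of Kmax

    # climate record
    period: tuple[int, int] = (1991, 2018)

    # flushing-comparison sub-sample (extra non-flushed branches)
    n_flush_check_trees: int = 13

    def __post_init__(self):
        if self.n_sites < 1 or self.n_trees_per_site < 1:
            raise ConfigurationError("n_sites and n_trees_per_site must be at least 1")
        if self.site_sd < 0:
            raise ConfigurationError("site_sd must be non-negative")
        if self.residual_sd <= 0:
            raise ConfigurationError("residual_sd must be positive")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")
        if self.pressure_step >= 0:
            raise ConfigurationError(
                f"pressure_step must be negative (descending pressures), got {self.pressure_step}"
            )
        if self.pressure_start >= 0:
            raise ConfigurationError("pressure_start must be negative")
        if not (0 < self.loss_cutoff < 1):
            raise ConfigurationError("loss_cutoff must be in (0, 1)")
        for name, (lo, hi) in self.covariate_ranges.items():
            if lo > hi:
                raise ConfigurationError(f"covariate range for {name!r} has min > max")
        lo, hi = self.branch_age_range
        if not (0 < lo < hi):
            raise ConfigurationError("branch_age_range must be positive and increasing")

    def to_dict(self) -> dict:
        return asdict(self)
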