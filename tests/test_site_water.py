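"""Climatic water balance, van Genuchten retention and profile AWC."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xylosafe.errors import DomainError, InputError
from xylosafe.site_water import (
    SoilLayer,
    SoilProfile,
    VanGenuchtenParams,
    aggregate_climate,
    classify_texture,
    layer_awc,
    monthly_cwb,
    pF_of_potential,
    potential_of_pF,
    profile_awc,
    texture_to_vg,
    vg_theta,
    TEXTURE_CLASS_VG,
)


class TestCWB:
    def test_identity_and_subtraction(self):
        assert monthly_cwb(50.0, 50.0) == 0.0
        assert monthly_cwb(50.0, 60.0) == -10.0

    def test_rejects_negative_inputs(self):
        with pytest.raises(DomainError):
            monthly_cwb(-1.0, 5.0)
        with pytest.raises(DomainError):
            monthly_cwb(5.0, -1.0)


def constant_climate(n_years=3, precip=50.0, temp=9.5, pet=40.0, site="A", y0=2000):
    rows = [
        {"site_id": site, "year": y, "month": m, "precip_mm": precip,
         "pet_mm": pet, "temp_C": temp}
        for y in range(y0, y0 + n_years)
        for m in range(1, 13)
    ]
    return pd.DataFrame(rows)


class TestAggregateClimate:
    def test_constant_inputs(self):
        clim = constant_climate()
        out = aggregate_climate(clim, period=(2000, 2002))
        row = out.iloc[0]
        assert row["MAP"] == pytest.approx(600.0)
        assert row["MAT"] == pytest.approx(9.5)
        assert row["MSP"] == pytest.approx(150.0)  # Apr–Jun
        assert row["CWB"] == pytest.approx(10.0)

    def test_missing_month_reported(self):
        clim = constant_climate()
        clim = clim[~((clim["year"] == 2001) & (clim["month"] == 7))]
        with pytest.raises(InputError, match="2001, 7"):
            aggregate_climate(clim, period=(2000, 2002))

    def test_generator_roundtrip(self, small_study, small_config):
        """Aggregating generated climate reproduces the configured targets."""
        summary = aggregate_climate(small_study.climate_table, period=small_config.period)
        merged = summary.merge(small_study.site_table, on="site_id", suffixes=("", "_cfg"))
        assert np.allclose(merged["MAP"], merged["MAP_cfg"], rtol=1e-10)
        assert np.allclose(merged["MAT"], merged["MAT_cfg"], rtol=1e-10)
        assert np.allclose(merged["CWB"], merged["CWB_cfg"], rtol=1e-8)


class TestPF:
    def test_conventional_anchor_points(self):
        assert pF_of_potential(-1.5) == pytest.approx(math.log10(15000.0))
        assert round(pF_of_potential(-1.5), 1) == 4.2
        assert pF_of_potential(-60.0 / 1e4) == pytest.approx(math.log10(60.0))
        assert round(pF_of_potential(-60.0 / 1e4), 1) == 1.8

    def test_unit_suction_is_pf_zero(self):
        assert pF_of_potential(-1.0 / 1e4) == pytest.approx(0.0)  # −1 hPa

    @given(st.floats(-3.0, 5.0))
    @settings(max_examples=60, derandomize=True)
    def test_roundtrip(self, pf):
        assert pF_of_potential(potential_of_pF(pf)) == pytest.approx(pf, rel=1e-12, abs=1e-12)

    def test_rejects_nonnegative_potential(self):
        with pytest.raises(DomainError):
            pF_of_potential(0.0)


class TestVanGenuchten:
    def test_saturation_and_residual_limits(self):
        p = VanGenuchtenParams(0.05, 0.40, 0.02, 1.5)
        assert vg_theta(p, 0.0) == pytest.approx(0.40)
        assert vg_theta(p, 1e12) == pytest.approx(0.05, abs=1e-5)

    def test_closed_form_value(self):
        p = VanGenuchtenParams(0.05, 0.40, 0.02, 1.5)
        # θ = 0.05 + 0.35·(1 + 1.2^1.5)^(−1/3)
        expected = 0.05 + 0.35 * (1.0 + 1.2**1.5) ** (-(1 - 1 / 1.5))
        assert vg_theta(p, 60.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.3146, abs=2e-4)

    @given(
        theta_r=st.floats(0.0, 0.15),
        span=st.floats(0.05, 0.5),
        alpha=st.floats(1e-3, 0.2),
        n=st.floats(1.05, 3.5),
    )
    @settings(max_examples=80, derandomize=True)
    def test_monotone_and_bounded(self, theta_r, span, alpha, n):
        p = VanGenuchtenParams(theta_r, min(theta_r + span, 1.0), alpha, n)
        h = np.logspace(-2, 6, 80)
        theta = vg_theta(p, h)
        assert np.all(np.diff(theta) <= 1e-15)
        assert np.all(theta <= p.theta_s + 1e-12) and np.all(theta >= p.theta_r - 1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            VanGenuchtenParams(0.4, 0.3, 0.02, 1.5)
        with pytest.raises(DomainError):
            VanGenuchtenParams(0.05, 0.4, -0.1, 1.5)
        with pytest.raises(DomainError):
            VanGenuchtenParams(0.05, 0.4, 0.02, 1.0)


class TestTexture:
    def test_pure_sand_class(self):
        assert classify_texture(1.0, 0.0, 0.0) == "sand"
        assert texture_to_vg(1.0, 0.0, 0.0) is TEXTURE_CLASS_VG["sand"]

    def test_loam_classification(self):
        assert classify_texture(0.4, 0.4, 0.2) == "loam"

    def test_nonclosed_fractions_rejected(self):
        with pytest.raises(InputError):
            classify_texture(0.5, 0.3, 0.1)

    def test_override_passthrough(self):
        custom = VanGenuchtenParams(0.01, 0.5, 0.01, 2.0)
        assert texture_to_vg(0.4, 0.4, 0.2, override=custom) is custom

    def test_all_classes_reachable(self):
        # representative interior points of each USDA class
        probes = {
            "sand": (0.92, 0.05, 0.03),
            "loamy sand": (0.82, 0.12, 0.06),
            "sandy loam": (0.65, 0.25, 0.10),
            "loam": (0.40, 0.40, 0.20),
            "silt loam": (0.20, 0.65, 0.15),
            "silt": (0.08, 0.87, 0.05),
            "sandy clay loam": (0.60, 0.15, 0.25),
            "clay loam": (0.35, 0.32, 0.33),
            "silty clay loam": (0.10, 0.57, 0.33),
            "sandy clay": (0.50, 0.10, 0.40),
            "silty clay": (0.07, 0.48, 0.45),
            "clay": (0.20, 0.20, 0.60),
        }
        for cls, (s, si, c) in probes.items():
            assert classify_texture(s, si, c) == cls


def uniform_profile(depth=60.0):
    return SoilProfile(
        site_id="X",
        layers=(
            SoilLayer(0, 10, 0.4, 0.4, 0.2),
            SoilLayer(10, 30, 0.4, 0.4, 0.2),
            SoilLayer(30, depth, 0.4, 0.4, 0.2),
        ),
    )


class TestAWC:
    def test_uniform_delta_theta(self):
        # Δθ = 0.15 over 100 cm ⇒ 150 mm, independent of the retention shape
        assert layer_awc(0.30, 0.15, 100.0) == pytest.approx(150.0)

    def test_degenerate_retention_gives_zero(self):
        assert layer_awc(0.2, 0.2, 100.0) == 0.0

    def test_negative_delta_rejected(self):
        with pytest.raises(DomainError):
            layer_awc(0.1, 0.2, 100.0)

    def test_subsoil_extension_to_standard_depth(self):
        """The 30–60 cm parameters are reused for 60–100 cm, so a uniform
        profile's AWC scales exactly with the standard depth."""
        profile = uniform_profile()
        a100 = profile_awc(profile, standard_depth_cm=100.0)
        a60 = profile_awc(profile, standard_depth_cm=60.0)
        assert a100 == pytest.approx(a60 * 100.0 / 60.0, rel=1e-12)

    def test_additive_over_split_layers(self):
        whole = uniform_profile()
        split = SoilProfile(
            site_id="X",
            layers=(
                SoilLayer(0, 5, 0.4, 0.4, 0.2),
                SoilLayer(5, 10, 0.4, 0.4, 0.2),
                SoilLayer(10, 30, 0.4, 0.4, 0.2),
                SoilLayer(30, 45, 0.4, 0.4, 0.2),
                SoilLayer(45, 60, 0.4, 0.4, 0.2),
            ),
        )
        assert profile_awc(split) == pytest.approx(profile_awc(whole), rel=1e-12)

    def test_stone_correction_reduces_awc(self):
        stony = SoilProfile(
            site_id="X",
            layers=(
                SoilLayer(0, 30, 0.4, 0.4, 0.2, stone_fraction=0.3),
                SoilLayer(30, 60, 0.4, 0.4, 0.2, stone_fraction=0.3),
            ),
        )
        assert profile_awc(stony, correct_stones=True) == pytest.approx(
            0.7 * profile_awc(stony, correct_stones=False), rel=1e-12
        )

    def test_profile_gap_rejected(self):
        with pytest.raises(InputError):
            SoilProfile(
                site_id="X",
                layers=(SoilLayer(0, 10, 0.4, 0.4, 0.2), SoilLayer(20, 60, 0.4, 0.4, 0.2)),
            )

    def test_synthetic_sites_within_study_range(self, small_study, small_config):
        lo, hi = small_config.covariate_ranges["AWC"]
        assert ((small_study.site_table["AWC"] >= lo) & (small_study.site_table["AWC"] <= hi)).all()
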