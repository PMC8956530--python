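"""Synthetic study generator.

Builds a complete, self-consistent synthetic field campaign with the
hierarchical structure the analysis assumes — sites with monthly climate
and layered soils, stands of mapped trees, one sampled branch per target
tree, and a cavitron (pressure, conductivity) series per branch — so
that every downstream stage (curve fitting, covariate computation,
mixed modelling) can be exercised and validated without external data.

The generating model for the focal trait is the same random-intercept
structure the trait models assume: per-branch true P50 is a linear
combination of z-scored covariates plus a Gaussian site effect and a
Gaussian residual; curve slope is lognormal and the conductivity scale
(Ks) truncated normal, each with their own site/residual components.

What the generator does *not* emulate: spatial autocorrelation of
climate between sites, genetic/provenance structure, within-tree branch
replication, or leaf-area allometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from xylosafe.config import StudyConfig
from xylosafe.errors import ConfigurationError, InputError
from xylosafe.hydraulics import loss_fraction, pressure_at_loss
from xylosafe.site_water import SoilLayer, SoilProfile, profile_awc
from xylosafe.stand import cross_section_area, hegyi_for_stand, xylem_area, M2_PER_MM2

__all__ = [
    "SyntheticStudy",
    "simulate_covariates",
    "simulate_true_traits",
    "simulate_cavitron_series",
    "simulate_study",
    "true_trait_table",
    "write_study",
]

_STAGES = ("climate", "soil", "stand", "branches", "traits", "cavitron", "extras")


@dataclass
class SyntheticStudy:
    """All tables of one synthetic campaign (schemas mirror the CSV files)."""

    config: StudyConfig
    site_table: pd.DataFrame
    tree_table: pd.DataFrame
    branch_table: pd.DataFrame
    climate_table: pd.DataFrame
    soil_table: pd.DataFrame
    cavitron: dict[str, pd.DataFrame] = field(default_factory=dict)

    def soil_profiles(self) -> dict[str, SoilProfile]:
        out = {}
        for site, grp in self.soil_table.groupby("site_id"):
            layers = tuple(
                SoilLayer(
                    r.top_cm, r.bottom_cm, r.sand, r.silt, r.clay,
                    r.bulk_density, r.stone_fraction,
                )
                for r in grp.itertuples()
            )
            out[site] = SoilProfile(site_id=site, layers=layers)
        return out


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """One child generator per stage from a single root seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _simulate_site_climate(
    site_id: str, map_target: float, mat_target: float, cwb_target: float,
    period: tuple[int, int], rng: np.random.Generator,
) -> pd.DataFrame:
    """Monthly climate whose 28-year aggregates hit the targets exactly."""
    y0, y1 = period
    years = np.arange(y0, y1 + 1)
    months = np.arange(1, 13)
    yy, mm = np.meshgrid(years, months, indexing="ij")
    yy, mm = yy.ravel(), mm.ravel()

    # mild summer maximum in precipitation, strong one in PET
    p_shape = 1.0 + 0.25 * np.sin(2.0 * math.pi * (mm - 4) / 12.0)
    precip = p_shape * rng.lognormal(mean=0.0, sigma=0.35, size=mm.size)
    precip *= map_target / (precip.sum() / years.size)  # mean annual sum == MAP

    temp = mat_target + 8.5 * np.sin(2.0 * math.pi * (mm - 4) / 12.0) + rng.normal(0, 1.2, mm.size)
    temp += mat_target - temp.mean()  # mean of annual means == MAT

    pet_shape = np.clip(1.0 + 0.95 * np.sin(2.0 * math.pi * (mm - 4) / 12.0), 0.05, None)
    pet = pet_shape * rng.lognormal(mean=0.0, sigma=0.15, size=mm.size)
    pet_mean_target = map_target / 12.0 - cwb_target  # mean monthly CWB == target
    pet *= pet_mean_target / pet.mean()

    return pd.DataFrame(
        {
            "site_id": site_id,
            "year": yy,
            "month": mm,
            "precip_mm": precip,
            "pet_mm": pet,
            "temp_C": temp,
        }
    )


_LAYER_BOUNDS = ((0.0, 10.0), (10.0, 30.0), (30.0, 60.0))


def _simulate_site_soil(
    site_id: str, awc_range: tuple[float, float], rng: np.random.Generator,
) -> tuple[pd.DataFrame, float]:
    """Three-layer sandy profile; rejection-sampled until AWC is in range."""
    for _ in range(200):
        sand0 = rng.uniform(0.30, 0.78)
        clay0 = rng.uniform(0.05, 0.20)
        rows = []
        for top, bottom in _LAYER_BOUNDS:
            clay = float(np.clip(clay0 + rng.uniform(-0.02, 0.02), 0.01, 0.4))
            sand = float(np.clip(sand0 + rng.uniform(-0.05, 0.05), 0.05, 0.96 - clay))
            silt = 1.0 - sand - clay
            rows.append(
                {
                    "site_id": site_id,
                    "top_cm": top,
                    "bottom_cm": bottom,
                    "sand": sand,
                    "silt": silt,
                    "clay": clay,
                    "bulk_density": float(rng.uniform(1.2, 1.6)),
                    "stone_fraction": float(rng.uniform(0.0, 0.15)),
                }
            )
        table = pd.DataFrame(rows)
        profile = SoilProfile(
            site_id=site_id,
            layers=tuple(
                SoilLayer(r.top_cm, r.bottom_cm, r.sand, r.silt, r.clay,
                          r.bulk_density, r.stone_fraction)
                for r in table.itertuples()
            ),
        )
        try:
            awc = profile_awc(profile)
        except KeyError:  # texture outside the sampled classes
            continue
        if awc_range[0] <= awc <= awc_range[1]:
            return table, float(awc)
    raise ConfigurationError(
        f"could not sample a soil profile with AWC in {awc_range} for {site_id}"
    )


def _simulate_site_stand(
    site_id: str, dbh_range, height_range, rng: np.random.Generator,
    n_targets: int, grid_side: int = 7, spacing_m: float = 6.0,
) -> pd.DataFrame:
    """Jittered-grid stand map; targets are interior trees."""
    dbh_mean = rng.uniform(*dbh_range)
    height_mean = rng.uniform(*height_range)
    age_mean = rng.uniform(62.0, 165.0)

    ids, xs, ys, interior = [], [], [], []
    k = 0
    for i in range(grid_side):
        for j in range(grid_side):
            ids.append(f"{site_id}-T{k:03d}")
            xs.append(i * spacing_m + rng.uniform(-1.5, 1.5))
            ys.append(j * spacing_m + rng.uniform(-1.5, 1.5))
            interior.append(0 < i < grid_side - 1 and 0 < j < grid_side - 1)
            k += 1
    n = len(ids)
    if sum(interior) < n_targets:
        raise ConfigurationError(
            f"stand grid too small for {n_targets} interior target trees"
        )
    dbh = np.clip(rng.normal(dbh_mean, 2.5, n), dbh_range[0], dbh_range[1])
    height = np.clip(rng.normal(height_mean, 1.0, n), height_range[0], height_range[1])
    age = np.clip(rng.normal(age_mean, 5.0, n), 40.0, 200.0)

    table = pd.DataFrame(
        {
            "tree_id": ids,
            "site_id": site_id,
            "x": xs,
            "y": ys,
            "dbh": dbh,
            "height": height,
            "age": age,
            "target": False,
        }
    )
    interior_idx = np.flatnonzero(interior)
    chosen = rng.permutation(interior_idx)[:n_targets]
    table.loc[chosen, "target"] = True
    return table


def _draw_branch_age(rng: np.random.Generator, age_range, age_mean) -> tuple[int, int]:
    """Ring counts at both segment ends; mean age right-skewed in range.

    Shifted lognormal: age = 1 + LogNormal(μ, σ) with σ = 0.55 and μ set
    so the mean matches the configured mean branch age; draws outside
    the admissible range are rejected.
    """
    sigma = 0.55
    mu = math.log(max(age_mean - 1.0, 0.5)) - sigma**2 / 2.0
    lo, hi = age_range
    for _ in range(1000):
        age = 1.0 + rng.lognormal(mu, sigma)
        if not (lo <= age <= hi):
            continue
        half = round(2.0 * age) / 2.0
        half = min(max(half, lo), hi)
        if half == int(half):
            spread = int(rng.integers(0, 2))  # (t, t) or (t+1, t-1)
            basi, acro = int(half) + spread, int(half) - spread
        else:
            basi, acro = int(half + 0.5), int(half - 0.5)
        if acro >= 1:
            return basi, acro
    raise ConfigurationError("branch-age sampling failed; check branch_age_range")


def simulate_covariates(config: StudyConfig) -> SyntheticStudy:
    """Sites, climate, soils, stands and branches — everything but traits.

    Site-level MAP, MAT and CWB are drawn independently within their
    configured ranges and the monthly climate record is built to
    reproduce them exactly under aggregation; AWC is the retention-curve
    capacity of a sampled soil profile, rejection-sampled into its
    configured range.  Stand maps are jittered grids with ten interior
    target trees; each target tree carries one branch with ring counts
    at both segment ends.
    """
    rngs = _stage_rngs(config.seed)
    ranges = config.covariate_ranges

    site_rows, climate_parts, soil_parts, tree_parts, branch_rows = [], [], [], [], []
    for s in range(1, config.n_sites + 1):
        site_id = f"S{s:03d}"
        map_t = rngs["climate"].uniform(*ranges["MAP"])
        mat_t = rngs["climate"].uniform(*ranges["MAT"])
        cwb_t = rngs["climate"].uniform(*ranges["CWB"])
        climate_parts.append(
            _simulate_site_climate(site_id, map_t, mat_t, cwb_t, config.period, rngs["climate"])
        )
        soil, awc = _simulate_site_soil(site_id, ranges["AWC"], rngs["soil"])
        soil_parts.append(soil)
        stand = _simulate_site_stand(
            site_id, ranges["DBH"], ranges["height"], rngs["stand"], config.n_trees_per_site
        )
        tree_parts.append(stand)
        site_rows.append(
            {"site_id": site_id, "MAP": map_t, "MAT": mat_t, "CWB": cwb_t, "AWC": awc}
        )

        for t, tree in enumerate(stand.loc[stand["target"], "tree_id"]):
            basi, acro = _draw_branch_age(
                rngs["branches"], config.branch_age_range, config.branch_age_mean
            )
            d_basi = float(np.clip(rngs["branches"].normal(8.97, 1.0), 6.0, 13.0))
            taper = float(np.clip(rngs["branches"].normal(1.5, 0.5), 0.1, 3.0))
            branch_rows.append(
                {
                    "branch_id": f"{tree}-B1",
                    "tree_id": tree,
                    "site_id": site_id,
                    "basipetal_diameter_mm": d_basi,
                    "acropetal_diameter_mm": d_basi - taper,
                    "segment_length_cm": 27.5,
                    "rings_basipetal": basi,
                    "rings_acropetal": acro,
                    "flushed": True,
                }
            )

    return SyntheticStudy(
        config=config,
        site_table=pd.DataFrame(site_rows),
        tree_table=pd.concat(tree_parts, ignore_index=True),
        branch_table=pd.DataFrame(branch_rows),
        climate_table=pd.concat(climate_parts, ignore_index=True),
        soil_table=pd.concat(soil_parts, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# true traits
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_true_traits(study: SyntheticStudy, config: StudyConfig | None = None) -> SyntheticStudy:
    """Draw true (P50, slope, Kmax) per branch from the generating model.

    True P50 = intercept + Σ βk·z(xk) + b_site + ε with the per-SD
    effects, site SD and residual SD of the configuration; slope is
    lognormal and the conductivity scale truncated normal, each with
    their own site/residual components.  Also fills max_Kh via the
    xylem-area allometry so the raw branch table is self-consistent.
    """
    config = config or study.config
    rng = _stage_rngs(config.seed)["traits"]
    branches = study.branch_table.copy()
    trees = study.tree_table.set_index("tree_id")
    sites = study.site_table.set_index("site_id")

    needed = {"CWB", "AWC"}
    if not needed <= set(sites.columns):
        raise InputError(f"site table missing {sorted(needed - set(sites.columns))}")

    main = branches["flushed"].astype(bool)
    age = (branches["rings_basipetal"] + branches["rings_acropetal"]) / 2.0
    covars = pd.DataFrame(
        {
            "CWB": sites.loc[branches["site_id"], "CWB"].to_numpy(),
            "AWC": sites.loc[branches["site_id"], "AWC"].to_numpy(),
            "height": trees.loc[branches["tree_id"], "height"].to_numpy(),
            "log_branch_age": np.log(age.to_numpy()),
        }
    )
    ci_parts = []
    for site, stand in study.tree_table.groupby("site_id"):
        ci_parts.append(hegyi_for_stand(stand))
    ci = pd.concat(ci_parts)
    covars["CI"] = ci.loc[branches["tree_id"]].to_numpy()

    # per-SD scale: standardize within the main (modelled) sample
    z = {}
    for col in covars.columns:
        ref = covars.loc[main, col].to_numpy()
        mu, sd = ref.mean(), ref.std(ddof=1)
        z[col] = (covars[col].to_numpy() - mu) / sd if sd > 0 else np.zeros(len(covars))

    site_ids = sites.index.to_numpy()
    b_p50 = dict(zip(site_ids, rng.normal(0.0, config.site_sd, site_ids.size)))
    b_slope = dict(zip(site_ids, rng.normal(0.0, config.slope_log_site_sd, site_ids.size)))
    b_ks = dict(zip(site_ids, rng.normal(0.0, config.ks_site_sd, site_ids.size)))

    n = len(branches)
    fixed = np.full(n, config.intercept_p50)
    for name, beta in config.fixed_effects.items():
        if name not in z:
            raise InputError(f"fixed effect refers to unknown predictor {name!r}")
        fixed = fixed + beta * z[name]
    site_of = branches["site_id"].to_numpy()
    p50 = fixed + np.array([b_p50[s] for s in site_of]) + rng.normal(0, config.residual_sd, n)
    p50 = np.minimum(p50, -0.5)  # keep curves inside the measurable range

    slope = np.exp(
        config.slope_log_mean
        + np.array([b_slope[s] for s in site_of])
        + rng.normal(0, config.slope_log_residual_sd, n)
    )
    ks = config.ks_mean + np.array([b_ks[s] for s in site_of]) + rng.normal(
        0, config.ks_residual_sd, n
    )
    for i in np.flatnonzero(ks <= 0.05):  # redraw the residual, keep Ks physical
        while ks[i] <= 0.05:
            ks[i] = config.ks_mean + b_ks[site_of[i]] + rng.normal(0, config.ks_residual_sd)

    branches["true_p50"] = p50
    branches["true_slope"] = slope
    branches["true_kmax"] = ks
    a_xylem = np.array(
        [xylem_area(cross_section_area(d)) for d in branches["basipetal_diameter_mm"]]
    )
    branches["max_kh"] = ks * a_xylem * M2_PER_MM2

    return SyntheticStudy(
        config=config,
        site_table=study.site_table,
        tree_table=study.tree_table,
        branch_table=branches,
        climate_table=study.climate_table,
        soil_table=study.soil_table,
        cavitron=study.cavitron,
    )


# ---------------------------------------------------------------------------
# cavitron series
# ---------------------------------------------------------------------------

def simulate_cavitron_series(
    kmax: float,
    p50: float,
    slope: float,
    config: StudyConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One noisy (pressure, conductivity) series for a branch.

    The pressure grid starts at the configured start pressure and
    descends by ``pressure_step`` until the modelled loss first reaches
    the 90 % cutoff (extended, if necessary, to the minimum of five
    points).  Observations are the model curve plus additive Gaussian
    noise with SD ``noise_cv × Kmax``, truncated at zero.
    """
    if kmax <= 0 or slope <= 0 or p50 >= 0:
        raise InputError("need kmax > 0, slope > 0, p50 < 0")
    if config.pressure_step >= 0:
        raise ConfigurationError("pressure_step must be negative")

    psi_stop = pressure_at_loss(p50, slope, config.loss_cutoff)
    pressures = [config.pressure_start]
    while (pressures[-1] > psi_stop) or (len(pressures) < 5):
        pressures.append(pressures[-1] + config.pressure_step)
    psi = np.array(pressures)
    model = kmax * (1.0 - loss_fraction(psi, p50, slope))
    noise = rng.normal(0.0, config.noise_cv * kmax, psi.size) if config.noise_cv > 0 else 0.0
    obs = np.clip(model + noise, 0.0, None)
    return pd.DataFrame({"pressure_MPa": psi, "conductivity": obs})


def simulate_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Full synthetic campaign: covariates, true traits, cavitron series."""
    config = config or StudyConfig()
    study = simulate_true_traits(simulate_covariates(config), config)

    # flushing-comparison sub-sample: extra non-flushed branches on the
    # first few target trees, sharing the tree's site effect structure
    rng_extra = _stage_rngs(config.seed)["extras"]
    if config.n_flush_check_trees > 0:
        extra_rows = []
        main = study.branch_table[study.branch_table["flushed"]].head(config.n_flush_check_trees)
        for r in main.itertuples():
            basi, acro = _draw_branch_age(
                rng_extra, config.branch_age_range, config.branch_age_mean
            )
            extra_rows.append(
                {
                    "branch_id": r.branch_id.replace("-B1", "-B2"),
                    "tree_id": r.tree_id,
                    "site_id": r.site_id,
                    "basipetal_diameter_mm": r.basipetal_diameter_mm,
                    "acropetal_diameter_mm": r.acropetal_diameter_mm,
                    "segment_length_cm": r.segment_length_cm,
                    "rings_basipetal": basi,
                    "rings_acropetal": acro,
                    "flushed": False,
                    "true_p50": r.true_p50 + rng_extra.normal(0, config.residual_sd / 2),
                    "true_slope": r.true_slope * math.exp(rng_extra.normal(0, 0.1)),
                    "true_kmax": r.true_kmax * 0.8,  # unflushed: residual emboli
                    "max_kh": r.max_kh * 0.8,
                }
            )
        study.branch_table = pd.concat(
            [study.branch_table, pd.DataFrame(extra_rows)], ignore_index=True
        )

    rng = _stage_rngs(config.seed)["cavitron"]
    cavitron = {}
    for r in study.branch_table.itertuples():
        cavitron[r.branch_id] = simulate_cavitron_series(
            r.true_kmax, r.true_p50, r.true_slope, config, rng
        )
    study.cavitron = cavitron
    return study


def true_trait_table(study: SyntheticStudy) -> pd.DataFrame:
    """Tree-level trait table built from the *true* generating values.

    One row per flushed branch with the true responses (P12/P50/P88 from
    the closed-form quantiles, slope, Ks) and raw-scale covariates —
    the noiseless counterpart of the pipeline's fitted trait table,
    used for parameter-recovery simulations.
    """
    b = study.branch_table[study.branch_table["flushed"]].copy()
    trees = study.tree_table.set_index("tree_id")
    sites = study.site_table.set_index("site_id")
    ci = pd.concat(
        [hegyi_for_stand(stand) for _, stand in study.tree_table.groupby("site_id")]
    )
    out = pd.DataFrame(
        {
            "tree_id": b["tree_id"].to_numpy(),
            "site_id": b["site_id"].to_numpy(),
            "P50": b["true_p50"].to_numpy(),
            "P12": [
                pressure_at_loss(p, s, 0.12)
                for p, s in zip(b["true_p50"], b["true_slope"])
            ],
            "P88": [
                pressure_at_loss(p, s, 0.88)
                for p, s in zip(b["true_p50"], b["true_slope"])
            ],
            "slope": b["true_slope"].to_numpy(),
            "Ks": b["true_kmax"].to_numpy(),
            "CWB": sites.loc[b["site_id"], "CWB"].to_numpy(),
            "AWC": sites.loc[b["site_id"], "AWC"].to_numpy(),
            "height": trees.loc[b["tree_id"], "height"].to_numpy(),
            "branch_age": ((b["rings_basipetal"] + b["rings_acropetal"]) / 2.0).to_numpy(),
            "CI": ci.loc[b["tree_id"]].to_numpy(),
        }
    )
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_study(study: SyntheticStudy, outdir: str | Path) -> dict:
    """Write the study as the CSV schemas the pipeline reads.

    sites.csv, trees.csv, branches.csv, soil.csv, climate.csv and one
    cavitron/<branch_id>.csv per series, plus metadata.yaml recording
    the seed and configuration.  Returns {filename: row count}.
    """
    import yaml

    outdir = Path(outdir)
    (outdir / "cavitron").mkdir(parents=True, exist_ok=True)
    counts = {}
    for name, table in [
        ("sites.csv", study.site_table),
        ("trees.csv", study.tree_table),
        ("branches.csv", study.branch_table),
        ("soil.csv", study.soil_table),
        ("climate.csv", study.climate_table),
    ]:
        table.to_csv(outdir / name, index=False)
        counts[name] = len(table)
    for branch_id, series in study.cavitron.items():
        series.to_csv(outdir / "cavitron" / f"{branch_id}.csv", index=False)
    counts["cavitron"] = len(study.cavitron)
    with open(outdir / "metadata.yaml", "w") as fh:
        yaml.safe_dump({"seed": study.config.seed, "config": study.config.to_dict()}, fh)
    return counts
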