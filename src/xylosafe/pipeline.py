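"""End-to-end orchestration: generate/load → fit curves → covariates → models.

A run is driven by a :class:`PipelineConfig` that points either at a
directory of input CSVs (sites/trees/branches/soil/climate plus one
cavitron series per branch) or at a synthetic :class:`StudyConfig`.  All
randomness fans out from a single seed via ``numpy.random.SeedSequence``
spawning, so stage results are individually reproducible.  Outputs are
plain CSVs plus a JSON manifest with the config hash, row counts,
warnings and a checksum for every file written.

Unit conventions across the pipeline: xylem pressures are negative MPa;
soil matric suctions positive cm of water (converted to hPa only inside
the pF computation); conductivities kg m MPa⁻¹ s⁻¹ raw and
kg m⁻¹ MPa⁻¹ s⁻¹ specific; areas mm² with a single mm²→m² conversion
site.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from xylosafe.config import StudyConfig
from xylosafe.errors import ConfigurationError, FitError, InputError
from xylosafe.hydraulics import (
    CavitronSeries,
    bootstrap_vc,
    compare_groups_kruskal,
    fit_vulnerability_curve,
)
from xylosafe.lmm import fit_trait_models
from xylosafe.site_water import SoilLayer, SoilProfile, aggregate_climate, profile_awc
from xylosafe.stand import build_covariate_table
from xylosafe import synthetic

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "read_study_tables"]

log = logging.getLogger("xylosafe.pipeline")


@dataclass
class PipelineConfig:
    """What to run and where to write it."""

    outdir: str | Path
    input_dir: str | Path | None = None
    study: StudyConfig | None = None
    period: tuple[int, int] = (1991, 2018)
    bootstrap_B: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.input_dir is None and self.study is None:
            raise ConfigurationError(
                "pipeline needs either an input directory or a synthetic study block"
            )


# ---------------------------------------------------------------------------
# input handling
# ---------------------------------------------------------------------------

def read_study_tables(input_dir: str | Path) -> dict:
    """Load the CSV schemas of a study directory into DataFrames."""
    d = Path(input_dir)
    tables = {}
    for name in ("sites", "trees", "branches", "soil", "climate"):
        path = d / f"{name}.csv"
        if not path.exists():
            raise InputError(f"missing input table: {path}")
        tables[name] = pd.read_csv(path)
    cav_dir = d / "cavitron"
    cavitron = {}
    if cav_dir.is_dir():
        for f in sorted(cav_dir.glob("*.csv")):
            cavitron[f.stem] = pd.read_csv(f)
    tables["cavitron"] = cavitron
    return tables


_REQUIRED_COLUMNS = {
    "trees": {"tree_id", "site_id", "x", "y", "dbh", "height"},
    "branches": {
        "branch_id", "tree_id", "site_id", "basipetal_diameter_mm",
        "acropetal_diameter_mm", "rings_basipetal", "rings_acropetal", "flushed", "max_kh",
    },
    "soil": {"site_id", "top_cm", "bottom_cm", "sand", "silt", "clay"},
    "climate": {"site_id", "year", "month", "precip_mm", "pet_mm", "temp_C"},
}


def validate_inputs(tables: dict) -> list[str]:
    """Schema, unit-range and referential-integrity report.

    Returns a list of human-readable violations; an empty list means the
    inputs are clean.  Checks: required columns, branch→tree→site links,
    cavitron series linkage, pressure sign and conductivity
    non-negativity, texture closure, positive tree dimensions.
    """
    violations: list[str] = []
    for name, required in _REQUIRED_COLUMNS.items():
        if name not in tables:
            violations.append(f"missing table {name!r}")
            continue
        missing = required - set(tables[name].columns)
        if missing:
            violations.append(f"{name}: missing columns {sorted(missing)}")
    if violations:
        return violations

    trees, branches = tables["trees"], tables["branches"]
    soil, climate = tables["soil"], tables["climate"]

    known_trees = set(trees["tree_id"])
    for b in branches.loc[~branches["tree_id"].isin(known_trees), "branch_id"]:
        violations.append(f"branches: {b} references unknown tree_id")
    for t in trees.loc[~trees["site_id"].isin(set(climate["site_id"])), "tree_id"]:
        violations.append(f"trees: {t} references site without climate record")

    if (trees["dbh"] <= 0).any() or (trees["height"] <= 0).any():
        violations.append("trees: non-positive dbh or height")
    if (branches["rings_acropetal"] > branches["rings_basipetal"]).any():
        bad = branches.loc[
            branches["rings_acropetal"] > branches["rings_basipetal"], "branch_id"
        ].tolist()
        violations.append(f"branches: acropetal ring count exceeds basipetal for {bad}")
    if (climate[["precip_mm", "pet_mm"]] < 0).any().any():
        violations.append("climate: negative precipitation or PET")
    closure = (soil[["sand", "silt", "clay"]].sum(axis=1) - 1.0).abs()
    if (closure > 1e-6).any():
        violations.append("soil: texture fractions do not sum to 1")

    known_branches = set(branches["branch_id"])
    for bid, series in tables.get("cavitron", {}).items():
        if bid not in known_branches:
            violations.append(f"cavitron: series {bid} references unknown branch_id")
        if (series["pressure_MPa"] >= 0).any():
            violations.append(f"cavitron: {bid} contains non-negative pressures")
        if (series["conductivity"] < 0).any():
            violations.append(f"cavitron: {bid} contains negative conductivities")
    return violations


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _fit_all_curves(
    cavitron: dict[str, pd.DataFrame], bootstrap_B: int, seed: int
) -> tuple[pd.DataFrame, list[str]]:
    rows, warnings_out = [], []
    rng = np.random.default_rng(seed)
    for branch_id, table in cavitron.items():
        series = CavitronSeries(
            branch_id, table["pressure_MPa"].to_numpy(), table["conductivity"].to_numpy()
        )
        try:
            fit = fit_vulnerability_curve(series, restart_seed=seed)
        except FitError as err:
            warnings_out.append(f"fit failed for {branch_id}: {err}")
            continue
        if not fit.identifiable:
            warnings_out.append(f"{branch_id}: P50 weakly identified (no point below Kmax/2)")
        row = {
            "branch_id": branch_id,
            "kmax": fit.kmax,
            "p50": fit.p50,
            "slope": fit.slope,
            "p12": fit.p12,
            "p88": fit.p88,
            "se_kmax": fit.se_kmax,
            "se_p50": fit.se_p50,
            "se_slope": fit.se_slope,
            "converged": fit.converged,
            "identifiable": fit.identifiable,
            "rss": fit.rss,
            "n_points": fit.n,
        }
        if bootstrap_B > 0:
            bands = bootstrap_vc(series, fit, B=bootstrap_B, seed=int(rng.integers(2**31)))
            row.update(
                p50_ci_low=bands.ci_p50[0],
                p50_ci_high=bands.ci_p50[1],
                slope_ci_low=bands.ci_slope[0],
                slope_ci_high=bands.ci_slope[1],
                bootstrap_failed=bands.n_failed,
            )
            if bands.n_failed:
                warnings_out.append(
                    f"{branch_id}: {bands.n_failed} bootstrap replicates dropped"
                )
        rows.append(row)
    return pd.DataFrame(rows), warnings_out


def _site_water_summary(climate: pd.DataFrame, soil: pd.DataFrame, period) -> pd.DataFrame:
    summary = aggregate_climate(climate, period=period)
    awc_rows = []
    for site, grp in soil.groupby("site_id"):
        layers = tuple(
            SoilLayer(
                r.top_cm, r.bottom_cm, r.sand, r.silt, r.clay,
                getattr(r, "bulk_density", 1.4), getattr(r, "stone_fraction", 0.0),
            )
            for r in grp.itertuples()
        )
        awc_rows.append(
            {"site_id": site, "AWC": profile_awc(SoilProfile(site_id=site, layers=layers))}
        )
    return summary.merge(pd.DataFrame(awc_rows), on="site_id", how="left")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the manifest (also written to disk).

    Stages: (0) simulate or load inputs, (1) validate, (2) fit one
    vulnerability curve per branch, (3) site water summary (climate
    aggregation + soil AWC), (4) tree covariates (Hegyi CI, branch age,
    Ks), (5) trait table join, (6) five mixed models with variance
    decomposition, (7) flushed-vs-non-flushed comparison when both
    groups exist.  Deterministic under a fixed seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seed_sim, seed_fit, seed_boot = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
    )

    manifest: dict = {"seed": config.seed, "warnings": [], "stages": {}}

    if config.study is not None:
        study_cfg = config.study
        if study_cfg.seed != seed_sim:
            d = study_cfg.to_dict()
            d["seed"] = seed_sim
            study_cfg = StudyConfig(**d)
        study = synthetic.simulate_study(study_cfg)
        tables = {
            "sites": study.site_table,
            "trees": study.tree_table,
            "branches": study.branch_table,
            "soil": study.soil_table,
            "climate": study.climate_table,
            "cavitron": study.cavitron,
        }
        manifest["input"] = {"synthetic": True, "study_seed": study_cfg.seed}
    else:
        tables = read_study_tables(config.input_dir)
        manifest["input"] = {"synthetic": False, "input_dir": str(config.input_dir)}

    log.info("validating inputs")
    violations = validate_inputs(tables)
    if violations:
        raise InputError(f"input validation failed with {len(violations)} violations: "
                         f"{violations[:10]}")
    manifest["stages"]["inputs"] = {
        name: len(t) for name, t in tables.items() if isinstance(t, pd.DataFrame)
    }
    manifest["stages"]["inputs"]["cavitron_series"] = len(tables["cavitron"])

    log.info("fitting %d vulnerability curves", len(tables["cavitron"]))
    fits, fit_warnings = _fit_all_curves(tables["cavitron"], config.bootstrap_B, seed_boot)
    manifest["warnings"].extend(fit_warnings)
    manifest["stages"]["vc_fits"] = {"fitted": len(fits), "failed": len(fit_warnings)}

    log.info("site water summary")
    site_summary = _site_water_summary(tables["climate"], tables["soil"], config.period)

    log.info("tree covariates")
    covariates = build_covariate_table(tables["trees"], tables["branches"], site_summary)
    manifest["stages"]["covariates"] = {"rows": len(covariates)}

    traits = covariates.merge(
        fits[["branch_id", "p50", "p12", "p88", "slope"]], on="branch_id", how="inner"
    ).rename(columns={"p50": "P50", "p12": "P12", "p88": "P88"})

    log.info("fitting trait models on %d trees", len(traits))
    results = fit_trait_models(traits)

    model_rows, frac_rows = [], []
    for resp, res in results.items():
        if res.singular:
            manifest["warnings"].append(f"{resp}: singular fit (site variance at boundary)")
        if res.df_fallback:
            manifest["warnings"].append(f"{resp}: Satterthwaite df fell back to residual df")
        for term, row in res.coefs.iterrows():
            model_rows.append(
                {
                    "response": resp, "term": term, "estimate": row["estimate"],
                    "se": row["se"], "df": row["df"], "t": row["t"], "p": row["p"],
                    "site_sd": res.site_sd, "residual_sd": res.residual_sd,
                    "marginal_r2": res.marginal_r2, "conditional_r2": res.conditional_r2,
                    "n": res.n_used,
                }
            )
        f_fixed, f_site, f_resid = res.var_fractions
        frac_rows.append(
            {"response": resp, "fixed": f_fixed, "site": f_site, "residual": f_resid}
        )
    models_table = pd.DataFrame(model_rows)
    fractions_table = pd.DataFrame(frac_rows)
    manifest["stages"]["trait_models"] = {
        "models": len(results), "n_modelled": int(models_table["n"].iloc[0]),
    }
    manifest["multiple_testing_correction"] = "none (five models reported as fitted)"

    # flushing comparison where both treatments exist
    branches = tables["branches"]
    if (~branches["flushed"].astype(bool)).any():
        merged = branches.merge(fits, on="branch_id", how="inner")
        flushed = merged.loc[merged["flushed"].astype(bool)]
        non_flushed = merged.loc[~merged["flushed"].astype(bool)]
        paired_trees = set(non_flushed["tree_id"])
        flushed_sub = flushed[flushed["tree_id"].isin(paired_trees)]
        if len(flushed_sub) >= 2 and len(non_flushed) >= 2:
            h_p50, p_p50 = compare_groups_kruskal(flushed_sub["p50"], non_flushed["p50"])
            h_s, p_s = compare_groups_kruskal(flushed_sub["slope"], non_flushed["slope"])
            manifest["flush_comparison"] = {
                "n_flushed": len(flushed_sub), "n_non_flushed": len(non_flushed),
                "p50_H": h_p50, "p50_p": p_p50, "slope_H": h_s, "slope_p": p_s,
            }

    outputs = {
        "fits.csv": fits,
        "site_water.csv": site_summary,
        "covariates.csv": covariates,
        "trait_models.csv": models_table,
        "variance_fractions.csv": fractions_table,
    }
    checksums = {}
    for name, table in outputs.items():
        path = outdir / name
        table.to_csv(path, index=False, float_format="%.10g")
        checksums[name] = _sha256(path)
    manifest["outputs"] = checksums

    import scipy
    import statsmodels

    from xylosafe import __version__

    manifest["versions"] = {
        "xylosafe": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
    cfg_repr = {
        "period": list(config.period), "bootstrap_B": config.bootstrap_B,
        "seed": config.seed,
        "study": config.study.to_dict() if config.study else None,
        "input_dir": str(config.input_dir) if config.input_dir else None,
    }
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(cfg_repr, sort_keys=True, default=str).encode()
    ).hexdigest()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
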