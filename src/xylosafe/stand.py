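"""Tree- and branch-level covariates.

* Hegyi competition index from a stand map: CI_i = Σ_j (d_j/d_i)/Dist_ij
  over the three nearest neighbouring trees (diameters in cm, distances
  in m; dimensionless).
* Xylem-area allometry for branch segments,
  A_xylem = −3.715 + 0.770 · A_cross (mm²), and specific conductivity
  Ks = Kh,max / A_xylem with the area converted to m² at a single
  conversion site.
* Branch age as the mean of basipetal and acropetal growth-ring counts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from xylosafe.errors import DomainError, InputError

__all__ = [
    "hegyi_index",
    "nearest_neighbours",
    "hegyi_for_stand",
    "cross_section_area",
    "xylem_area",
    "specific_conductivity",
    "mean_branch_age",
    "build_covariate_table",
    "XYLEM_AREA_INTERCEPT",
    "XYLEM_AREA_SLOPE",
]

XYLEM_AREA_INTERCEPT = -3.715  # mm^2
XYLEM_AREA_SLOPE = 0.770
M2_PER_MM2 = 1e-6  # single mm^2 -> m^2 conversion site


def hegyi_index(target_dbh: float, neighbour_dbhs, distances) -> float:
    """Hegyi competition index: Σ (d_j / d_i) / Dist_ij.

    ``target_dbh`` and ``neighbour_dbhs`` in cm, ``distances`` in m.
    Homogeneous of degree 0 in diameters and −1 in distances.
    """
    d = np.asarray(neighbour_dbhs, dtype=float)
    dist = np.asarray(distances, dtype=float)
    if d.size != dist.size:
        raise InputError("neighbour diameters and distances differ in length")
    if target_dbh <= 0 or np.any(d <= 0):
        raise DomainError("diameters must be positive")
    if np.any(dist <= 0):
        raise DomainError("neighbour distance must be positive (coincident stems?)")
    return float(np.sum((d / target_dbh) / dist))


def nearest_neighbours(
    trees: pd.DataFrame, target_id, n: int = 3
) -> pd.DataFrame:
    """The ``n`` nearest trees to ``target_id`` by Euclidean stand-map distance.

    ``trees`` needs columns tree_id, x, y, dbh.  Distance ties are
    broken by tree_id order so the selection is deterministic.  Raises
    if fewer than ``n`` other trees exist.
    """
    row = trees.loc[trees["tree_id"] == target_id]
    if row.empty:
        raise InputError(f"unknown tree_id {target_id!r}")
    x0, y0 = float(row["x"].iloc[0]), float(row["y"].iloc[0])
    others = trees[trees["tree_id"] != target_id].copy()
    if len(others) < n:
        raise InputError(
            f"tree {target_id!r}: only {len(others)} potential neighbours, need {n}"
        )
    others["distance_m"] = np.hypot(others["x"] - x0, others["y"] - y0)
    if (others["distance_m"] <= 0).any():
        raise DomainError(f"tree {target_id!r} has a coincident neighbour in the stand map")
    others = others.sort_values(["distance_m", "tree_id"], kind="mergesort")
    return others.head(n)[["tree_id", "dbh", "distance_m"]].reset_index(drop=True)


def hegyi_for_stand(
    trees: pd.DataFrame, targets=None, n_neighbours: int = 3
) -> pd.Series:
    """Hegyi index for each target tree in a stand map (one site)."""
    if targets is None:
        targets = trees.loc[trees.get("target", True) == True, "tree_id"]  # noqa: E712
    out = {}
    for tid in targets:
        nb = nearest_neighbours(trees, tid, n=n_neighbours)
        d_i = float(trees.loc[trees["tree_id"] == tid, "dbh"].iloc[0])
        out[tid] = hegyi_index(d_i, nb["dbh"].to_numpy(), nb["distance_m"].to_numpy())
    return pd.Series(out, name="CI")


def cross_section_area(diameter_mm: float) -> float:
    """Circular cross-sectional area (mm²) from a diameter (mm)."""
    if diameter_mm <= 0:
        raise DomainError("diameter must be positive")
    return math.pi * diameter_mm**2 / 4.0


def xylem_area(a_cross_mm2: float) -> float:
    """Xylem cross-sectional area without pith and bark (mm²).

    Linear allometry A_xylem = −3.715 + 0.770 · A_cross, valid only
    above the root of the line (A_cross ≈ 4.825 mm²); smaller segments
    are rejected rather than returned as non-positive areas.
    """
    out = XYLEM_AREA_INTERCEPT + XYLEM_AREA_SLOPE * a_cross_mm2
    if out <= 0:
        min_across = -XYLEM_AREA_INTERCEPT / XYLEM_AREA_SLOPE
        raise DomainError(
            f"cross-sectional area {a_cross_mm2:.3f} mm² gives non-positive xylem area; "
            f"minimum valid A_cross is {min_across:.3f} mm²"
        )
    return out


def specific_conductivity(max_kh: float, a_xylem_mm2: float) -> float:
    """Specific conductivity Ks = Kh,max / A_xylem.

    ``max_kh`` in kg m MPa⁻¹ s⁻¹, area in mm²; result in
    kg m⁻¹ MPa⁻¹ s⁻¹.
    """
    if a_xylem_mm2 <= 0:
        raise DomainError("xylem area must be positive")
    if max_kh < 0:
        raise DomainError("conductivity must be non-negative")
    return max_kh / (a_xylem_mm2 * M2_PER_MM2)


def mean_branch_age(rings_basipetal: float, rings_acropetal: float) -> float:
    """Branch age (years) as the mean of the two end ring counts.

    The basipetal (older) end must carry at least as many rings as the
    acropetal end; half-integer ages are legitimate.
    """
    if rings_basipetal < 1 or rings_acropetal < 1:
        raise InputError("ring counts must be at least 1")
    if rings_acropetal > rings_basipetal:
        raise InputError(
            "acropetal ring count exceeds basipetal count; age cannot increase toward the tip"
        )
    return (rings_basipetal + rings_acropetal) / 2.0


def build_covariate_table(
    trees: pd.DataFrame,
    branches: pd.DataFrame,
    site_summary: pd.DataFrame | None = None,
    n_neighbours: int = 3,
) -> pd.DataFrame:
    """Tree-keyed covariate table ready for trait modelling.

    Computes per-tree Hegyi CI from the stand map (per site), branch age
    from ring counts, xylem area and Ks from branch geometry, and joins
    site-level covariates (CWB, AWC, ...) when ``site_summary`` is given.
    Only target trees (``target`` column truthy) receive a row.
    """
    ci_parts = []
    for site, stand in trees.groupby("site_id"):
        ci = hegyi_for_stand(stand, n_neighbours=n_neighbours)
        ci_parts.append(ci.rename_axis("tree_id").reset_index().assign(site_id=site))
    ci_table = pd.concat(ci_parts, ignore_index=True)

    main = branches.loc[branches.get("flushed", True) == True].copy()  # noqa: E712
    main["branch_age"] = [
        mean_branch_age(b, a)
        for b, a in zip(main["rings_basipetal"], main["rings_acropetal"])
    ]
    main["a_xylem_mm2"] = [
        xylem_area(cross_section_area(d)) for d in main["basipetal_diameter_mm"]
    ]
    main["Ks"] = [
        specific_conductivity(kh, a) for kh, a in zip(main["max_kh"], main["a_xylem_mm2"])
    ]

    targets = trees.loc[trees.get("target", True) == True]  # noqa: E712
    out = targets[["tree_id", "site_id", "dbh", "height"]].merge(
        ci_table[["tree_id", "CI"]], on="tree_id", how="left"
    )
    out = out.merge(
        main[["tree_id", "branch_id", "branch_age", "a_xylem_mm2", "Ks"]],
        on="tree_id",
        how="left",
    )
    if site_summary is not None:
        out = out.merge(site_summary, on="site_id", how="left")
    return out
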