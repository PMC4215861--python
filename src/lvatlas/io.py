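"""Plain-text I/O: point-set tables, covariate tables, atlas serialization
and YAML configs.

All interchange formats are delimited text so artifacts stay inspectable:
point sets as long tables (case id, frame, surface, point index, x, y, z in
mm), covariates as one row per case, atlases as a directory of delimited
matrices plus a YAML header.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .atlas import PCAAtlas
from .geometry import ED, ES, SurfaceGrid
from .synthetic import (COVARIATE_NAMES, Cohort, GroupConfig, PopulationConfig)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def points_long_table(cohort: Cohort) -> pd.DataFrame:
    """Long-format point table of the whole cohort (large: one row per point
    per frame per case)."""
    half = cohort.grid.points_per_surface
    n_pts = cohort.grid.total_points
    surface = np.array(["endo"] * half + ["epi"] * half)
    records = []
    for frame, arr in ((ED, cohort.ed_points), (ES, cohort.es_points)):
        for i, cid in enumerate(cohort.ids):
            records.append(pd.DataFrame({
                "case_id": cid, "frame": frame, "surface": surface,
                "point_index": np.arange(n_pts),
                "x": arr[i, :, 0], "y": arr[i, :, 1], "z": arr[i, :, 2],
            }))
    return pd.concat(records, ignore_index=True)


def write_cohort(cohort: Cohort, outdir: str | Path,
                 include_points: bool = True) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cov = cohort.covariates.copy()
    cov.insert(0, "group", cohort.labels)
    write_table(cov.reset_index(), outdir / "covariates.tsv")
    if cohort.latents is not None:
        write_table(cohort.latents.reset_index(), outdir / "latents.tsv")
    meta = {
        "n_cases": cohort.n_cases,
        "grid": {"n_circumferential": cohort.grid.n_circumferential,
                 "n_longitudinal": cohort.grid.n_longitudinal},
    }
    (outdir / "cohort.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    if include_points:
        write_table(points_long_table(cohort), outdir / "points.tsv")


def read_cohort(outdir: str | Path) -> Cohort:
    outdir = Path(outdir)
    meta = yaml.safe_load((outdir / "cohort.yaml").read_text())
    grid = SurfaceGrid(**meta["grid"])
    cov = read_table(outdir / "covariates.tsv").set_index("case_id")
    labels = cov.pop("group").to_numpy(dtype=int)
    ids = list(cov.index)
    pts = read_table(outdir / "points.tsv")
    n_pts = grid.total_points
    order = {cid: i for i, cid in enumerate(ids)}
    arrays = {ED: np.empty((len(ids), n_pts, 3)), ES: np.empty((len(ids), n_pts, 3))}
    for (frame, cid), chunk in pts.groupby(["frame", "case_id"], sort=False):
        chunk = chunk.sort_values("point_index")
        arrays[frame][order[cid]] = chunk[["x", "y", "z"]].to_numpy()
    latents = None
    if (outdir / "latents.tsv").exists():
        latents = read_table(outdir / "latents.tsv").set_index("case_id")
    return Cohort(ids=ids, labels=labels, covariates=cov[list(COVARIATE_NAMES)],
                  ed_points=arrays[ED], es_points=arrays[ES], grid=grid,
                  latents=latents)


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def write_atlas(atlas: PCAAtlas, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "mean.tsv", atlas.mean[None, :], delimiter="\t")
    np.savetxt(outdir / "modes.tsv", atlas.modes, delimiter="\t")
    np.savetxt(outdir / "eigenvalues.tsv",
               np.column_stack([atlas.eigenvalues, atlas.variance_fractions]),
               delimiter="\t", header="eigenvalue_mm2\tvariance_fraction")
    meta = {"frame": atlas.frame, "n_retained": int(atlas.n_retained),
            "variance_threshold": float(atlas.variance_threshold)}
    (outdir / "atlas.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_atlas(outdir: str | Path) -> PCAAtlas:
    outdir = Path(outdir)
    meta = yaml.safe_load((outdir / "atlas.yaml").read_text())
    mean = np.loadtxt(outdir / "mean.tsv", delimiter="\t")
    modes = np.loadtxt(outdir / "modes.tsv", delimiter="\t")
    if modes.ndim == 1:
        modes = modes[:, None]
    ev = np.loadtxt(outdir / "eigenvalues.tsv", delimiter="\t")
    ev = np.atleast_2d(ev)
    return PCAAtlas(mean=mean, modes=modes, eigenvalues=ev[:, 0],
                    variance_fractions=ev[:, 1], n_retained=meta["n_retained"],
                    variance_threshold=meta["variance_threshold"],
                    frame=meta["frame"])


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def _config_to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _config_to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _config_to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_config_to_dict(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def population_config_to_yaml(config: PopulationConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=False))


def population_config_from_yaml(path: str | Path) -> PopulationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    raw["control"] = GroupConfig(**raw["control"])
    raw["patient"] = GroupConfig(**raw["patient"])
    raw["grid"] = SurfaceGrid(**raw["grid"])
    if "shape_field_orders" in raw:
        raw["shape_field_orders"] = tuple(raw["shape_field_orders"])
    return PopulationConfig(**raw)
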