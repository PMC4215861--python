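"""End-to-end analysis pipeline: generate -> align -> correct -> atlas ->
models -> report.

Stages are pure functions of the run configuration; every stochastic element
derives from the single run seed through named substreams, so two runs with
the same config are bit-identical and stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lvio
from .alignment import generalized_procrustes, procrustes_pair
from .atlas import (PCAAtlas, build_pca, concatenate_frames, interpret_modes,
                    mode_scores_table, project)
from .cohortstats import demographics_table
from .correction import CorrectionMap, apply_correction, learn_correction
from .geometry import ED, ES, SurfaceGrid, SurfacePointSet, clinical_indices
from .models import LogisticFit, MODEL_ORDER, ModelComparison, compare_models
from .synthetic import (Cohort, PopulationConfig, ProtocolPerturbation,
                        default_population_config, generate_cohort,
                        generate_paired_protocol_cohort,
                        protocol_displacement_field)

FRAME_KEYS = ("ED", "ES", "ED&ES")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full analysis run needs; serialized next to its outputs."""

    population: PopulationConfig = field(default_factory=default_population_config)
    seed: int = 0
    apply_protocol_bias: bool = True
    protocol: ProtocolPerturbation = field(
        default_factory=lambda: ProtocolPerturbation(endo_inward_mm=1.0,
                                                     epi_inward_mm=0.5,
                                                     noise_sd=0.5))
    n_protocol_pairs: int = 40
    correction_ridge: float = 0.0
    gpa_tol: float = 1e-6            # mm; cohort-scale alignment tolerance
    gpa_max_iter: int = 100
    variance_threshold: float = 0.90
    models: tuple[str, ...] = MODEL_ORDER
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError("variance_threshold must be in (0, 1]")
        unknown = set(self.models) - set(MODEL_ORDER)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.n_protocol_pairs < 2:
            raise ValueError("n_protocol_pairs must be >= 2")


@dataclass
class RunResult:
    config: RunConfig
    cohort: Cohort
    aligned: dict[str, np.ndarray]         # frame -> (n, N, 3), bias-corrected
    gpa_iterations: dict[str, int]
    corrections: dict[str, CorrectionMap] | None
    indices: pd.DataFrame
    atlases: dict[str, PCAAtlas]
    mode_scores: dict[str, pd.DataFrame]
    demographics: pd.DataFrame
    mode_interpretation: dict[str, pd.DataFrame]
    comparison: ModelComparison
    summary: dict


def _stage_seeds(seed: int) -> dict[str, int]:
    """Named integer substream seeds (< 2^31) derived from the run seed."""
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("cohort", "pairs")
    return {name: int(state[i] % (2 ** 31)) for i, name in enumerate(names)}


def compute_indices(ed_points: np.ndarray, es_points: np.ndarray,
                    grid: SurfaceGrid, ids: list[str]) -> pd.DataFrame:
    """Per-case clinical indices table (EDV, ESV, mass, EF)."""
    rows = []
    for i, cid in enumerate(ids):
        ci = clinical_indices(SurfacePointSet(ed_points[i], grid, ED),
                              SurfacePointSet(es_points[i], grid, ES))
        rows.append({"case_id": cid, "edv_ml": ci.edv_ml, "esv_ml": ci.esv_ml,
                     "mass_g": ci.mass_g, "ef": ci.ejection_fraction})
    return pd.DataFrame(rows).set_index("case_id")


def _align_pairs_to_mean(points: np.ndarray, mean: np.ndarray) -> np.ndarray:
    out = np.empty_like(points)
    for i in range(points.shape[0]):
        transform, _ = procrustes_pair(points[i], mean)
        out[i] = transform.apply(points[i])
    return out


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages in order and assemble the run report."""
    seeds = _stage_seeds(config.seed)
    pop = replace(config.population, seed=seeds["cohort"])
    grid = pop.grid

    # stage 1: synthetic cohort (ground truth, reference protocol)
    cohort = generate_cohort(pop)
    controls = cohort.labels == 0

    # stage 2: protocol bias on the control group's observed shapes
    observed = {ED: cohort.ed_points.copy(), ES: cohort.es_points.copy()}
    if config.apply_protocol_bias:
        for frame in (ED, ES):
            disp = protocol_displacement_field(pop, config.protocol, frame)
            observed[frame][controls] += disp

    # stage 3: per-frame generalized Procrustes alignment (scale retained)
    aligned, gpa_iterations = {}, {}
    means = {}
    for frame in (ED, ES):
        aligned[frame], means[frame], gpa_iterations[frame] = \
            generalized_procrustes(observed[frame], tol=config.gpa_tol,
                                   max_iter=config.gpa_max_iter)

    # stage 4: learn the protocol correction from paired scans and apply it
    # to the aligned control shapes
    corrections: dict[str, CorrectionMap] | None = None
    if config.apply_protocol_bias:
        paired = generate_paired_protocol_cohort(
            pop, config.protocol, n_pairs=config.n_protocol_pairs,
            seed=seeds["pairs"])
        corrections = {}
        for frame in (ED, ES):
            ref = _align_pairs_to_mean(paired.reference[frame], means[frame])
            bia = _align_pairs_to_mean(paired.biased[frame], means[frame])
            cmap = learn_correction(bia, ref, ridge=config.correction_ridge)
            corrections[frame] = cmap
            aligned[frame][controls] = apply_correction(
                cmap, aligned[frame][controls])

    # stage 5: clinical indices from the corrected shapes
    indices = compute_indices(aligned[ED], aligned[ES], grid, cohort.ids)

    # stage 6: PCA atlases at ED, ES and the ED&ES concatenation
    n = cohort.n_cases
    vectors = {
        "ED": aligned[ED].reshape(n, -1),
        "ES": aligned[ES].reshape(n, -1),
    }
    vectors["ED&ES"] = concatenate_frames(vectors["ED"], vectors["ES"])
    atlases, mode_scores = {}, {}
    for key in FRAME_KEYS:
        atl = build_pca(vectors[key], variance_threshold=config.variance_threshold,
                        frame=key, store_modes="retained")
        atlases[key] = atl
        mode_scores[key] = mode_scores_table(atl, vectors[key])

    # stage 7: cohort table and mode interpretation
    demo = demographics_table(cohort.covariates, cohort.labels, indices)
    interpretation = {}
    if cohort.latents is not None:
        for key in FRAME_KEYS:
            interpretation[key] = interpret_modes(mode_scores[key], cohort.latents)

    # stage 8: disease-association models
    comparison = compare_models(cohort.covariates, cohort.labels,
                                mode_scores=mode_scores, indices=indices,
                                models=config.models)

    summary = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_cases": int(n),
        "n_patients": int(cohort.labels.sum()),
        "n_controls": int(n - cohort.labels.sum()),
        "gpa_iterations": {k: int(v) for k, v in gpa_iterations.items()},
        "correction_residual_rms_mm": (
            {k: float(v.residual_rms) for k, v in corrections.items()}
            if corrections else None),
        "retained_modes": {k: int(atlases[k].n_retained) for k in FRAME_KEYS},
        "mode1_variance_fraction": {
            k: float(atlases[k].variance_fractions[0]) for k in FRAME_KEYS},
        "model_comparison": {
            m: {c: float(v) for c, v in row.items()}
            for m, row in comparison.table.iterrows()},
        "group_mean_indices": {
            "patient": indices[cohort.labels == 1].mean().to_dict(),
            "control": indices[controls].mean().to_dict()},
    }

    result = RunResult(config=config, cohort=cohort, aligned=aligned,
                       gpa_iterations=gpa_iterations, corrections=corrections,
                       indices=indices, atlases=atlases, mode_scores=mode_scores,
                       demographics=demo, mode_interpretation=interpretation,
                       comparison=comparison, summary=summary)
    if config.outdir is not None:
        write_run_outputs(result, config.outdir)
    return result


def write_run_outputs(result: RunResult, outdir: str | Path) -> None:
    """Write the run report as delimited text + a machine-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(_jsonable(dataclasses.asdict(result.config)), indent=2))
    lvio.write_table(result.demographics, outdir / "cohort_table.tsv")
    lvio.write_table(result.indices.reset_index(), outdir / "clinical_indices.tsv")
    lvio.write_table(result.comparison.table.reset_index(),
                     outdir / "model_comparison.tsv")
    for key in FRAME_KEYS:
        tag = key.replace("&", "").lower()
        lvio.write_table(result.atlases[key].scree_table(),
                         outdir / f"scree_{tag}.tsv")
        if key in result.mode_interpretation:
            lvio.write_table(result.mode_interpretation[key].reset_index(),
                             outdir / f"mode_interpretation_{tag}.tsv")
    for model, fit in result.comparison.fits.items():
        tag = model.replace("&", "").replace(" ", "_").lower()
        lvio.write_table(format_coefficient_table(fit).reset_index(),
                         outdir / f"coefficients_{tag}.tsv")
        lvio.write_table(result.comparison.roc_curves[model],
                         outdir / f"roc_{tag}.tsv")
    (outdir / "summary.json").write_text(
        json.dumps(_jsonable(result.summary), indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def format_coefficient_table(fit: LogisticFit) -> pd.DataFrame:
    """Presentation form of a coefficient table: p-values below 1e-4 are
    shown as '<.0001' and significance is flagged at 0.05 / 0.01."""
    t = fit.summary.copy()
    t["p_display"] = [
        "<.0001" if p < 1e-4 else f"{p:.4f}" for p in t["p"]]
    t["significant"] = np.where(t["p"] < 0.01, "‡",
                                np.where(t["p"] <= 0.05, "†", ""))
    return t


def align_case_to_atlas(atlas: PCAAtlas, ed_points: np.ndarray,
                        es_points: np.ndarray | None = None) -> np.ndarray:
    """Rigidly align a new case's frame(s) to the atlas mean shape and return
    its shape vector in the atlas frame."""
    mean = atlas.mean
    if atlas.frame == "ED&ES":
        if es_points is None:
            raise ValueError("ED&ES atlas needs both frames")
        d = mean.shape[0] // 2
        ed_mean = mean[:d].reshape(-1, 3)
        es_mean = mean[d:].reshape(-1, 3)
        ted, _ = procrustes_pair(ed_points, ed_mean)
        tes, _ = procrustes_pair(es_points, es_mean)
        return np.concatenate([ted.apply(ed_points).reshape(-1),
                               tes.apply(es_points).reshape(-1)])
    pts = ed_points if atlas.frame == "ED" else (
        es_points if es_points is not None else ed_points)
    t, _ = procrustes_pair(pts, mean.reshape(-1, 3))
    return t.apply(pts).reshape(-1)


def score_new_case(atlas: PCAAtlas, fit: LogisticFit, covariates: dict[str, float],
                   ed_points: np.ndarray,
                   es_points: np.ndarray | None = None) -> float:
    """Probability that a new case belongs to the patient class.

    The case is rigidly aligned to the atlas mean, projected onto the
    retained modes, and pushed through the fitted logistic model together
    with its baseline covariates.  The case is assumed to be acquired with
    (or already corrected to) the reference protocol.
    """
    vec = align_case_to_atlas(atlas, np.asarray(ed_points, float),
                              None if es_points is None else np.asarray(es_points, float))
    scores = project(atlas, vec)
    features = dict(covariates)
    for i, s in enumerate(scores, start=1):
        features[f"mode{i}"] = float(s)
    beta = fit.params
    eta = 0.0
    for name in beta.index:
        if name == "Intercept":
            eta += beta[name]
        else:
            if name not in features:
                raise ValueError(f"missing predictor {name!r} for scoring")
            eta += beta[name] * features[name]
    return float(1.0 / (1.0 + np.exp(-eta)))
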