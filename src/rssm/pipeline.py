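"""End-to-end region-based shape-modeling pipeline.

Orchestrates the full study: obtain a cohort (mesh files or the synthetic
generator), pick the template subject, establish dense correspondence,
align with generalized Procrustes, partition the template surface by
Gaussian-curvature sign, fit the global (nrSSM) and region-based (rSSM)
models, synthesize the +/-2SD shape per reported mode, and tabulate the
products: distance maps, the cumulative-variance comparison between the
two models, and the curvature comparison of the +/-2SD shapes.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .curvature import (curvature_summary, gaussian_curvature,
                        partition_regions, transfer_labels)
from .mesh import TriangleMesh, read_mesh, write_mesh
from .registration import (CorrespondedSet, closest_points_on_surface,
                           establish_correspondence, generalized_procrustes,
                           select_template)
from .shape_model import (RegionalShapeModel, ShapeModel, cumulative_variance,
                          fit_rssm, fit_ssm, regional_mode_order, sd_model,
                          sd_model_regional)
from .synthetic import PopulationConfig, sample_population

__all__ = [
    "DistanceMap", "ComparisonReport", "PipelineConfig",
    "distance_map", "compare_cumulative_variance", "curvature_comparison",
    "run_pipeline",
]


@dataclass
class DistanceMap:
    """Per-vertex distances (mm) between two shape instances."""

    distances: np.ndarray
    source: str
    target: str
    corresponded: bool = True    # False: nearest-point-on-surface distances

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, float)
        if (self.distances < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def summary(self) -> dict:
        d = self.distances
        return {"mean": float(d.mean()), "max": float(d.max()),
                "rms": float(np.sqrt((d ** 2).mean()))}


def distance_map(a: TriangleMesh, b: TriangleMesh) -> DistanceMap:
    """Distance map between two meshes.

    Corresponded meshes (identical connectivity) get the exact per-vertex
    Euclidean distance, which is symmetric; otherwise each vertex of ``a``
    is measured to its nearest point on the surface of ``b`` and the map
    is flagged ``corresponded=False``.
    """
    if a.vertex_count == 0 or b.vertex_count == 0:
        raise ValueError("empty mesh")
    if a.vertex_count == b.vertex_count and np.array_equal(a.faces, b.faces):
        d = np.linalg.norm(a.vertices - b.vertices, axis=1)
        return DistanceMap(d, a.name, b.name, corresponded=True)
    nearest = closest_points_on_surface(a.vertices, b)
    d = np.linalg.norm(a.vertices - nearest, axis=1)
    return DistanceMap(d, a.name, b.name, corresponded=False)


def compare_cumulative_variance(nr: ShapeModel, r: RegionalShapeModel,
                                max_components: int | None = None) -> pd.DataFrame:
    """Cumulative variance (%) per component count for the global and the
    region-based model (regional modes pooled and sorted by variance)."""
    cv_nr = cumulative_variance(nr)["cumulative"]
    cv_r = cumulative_variance(r)["cumulative"]
    k = max(len(cv_nr), len(cv_r))
    if max_components is not None:
        k = min(k, max_components)

    def _curve(cv):
        # a model with fewer modes than k has explained everything already
        return np.concatenate([cv, np.ones(max(0, k - len(cv)))])[:k]

    return pd.DataFrame({
        "n_components": np.arange(1, k + 1),
        "nrssm_cumulative_pct": 100.0 * _curve(cv_nr),
        "rssm_cumulative_pct": 100.0 * _curve(cv_r),
    })


def curvature_comparison(nr: ShapeModel, r: RegionalShapeModel,
                         modes: list | None = None, k: float = 2.0) -> pd.DataFrame:
    """Gaussian-curvature summaries of the +/-kSD shapes of both models.

    For the regional model, mode ``i`` is the i-th largest pooled regional
    mode; its +/-kSD shape perturbs that region only, the rest staying at
    the mean.  Rows tabulate both the whole-bone summary and the summary
    restricted to the perturbed region (the whole surface for the global
    model).
    """
    if modes is None:
        modes = list(range(min(4, nr.n_modes)))
    order = regional_mode_order(r)
    rows = []
    for mode in modes:
        for sign in (-1.0, +1.0):
            mesh_nr = sd_model(nr, mode, sign * k)
            s = curvature_summary(mesh_nr, r.labeling)
            rows.append({"model": "nrssm", "mode": mode + 1, "sd": sign * k,
                         "region": "all", **_flat(s["overall"])})
            region, local = order[mode]
            mesh_r = sd_model_regional(r, region, local, sign * k)
            sr = curvature_summary(mesh_r, r.labeling)
            rows.append({"model": "rssm", "mode": mode + 1, "sd": sign * k,
                         "region": "all", **_flat(sr["overall"])})
            rows.append({"model": "rssm", "mode": mode + 1, "sd": sign * k,
                         "region": str(region), **_flat(sr[f"region_{region}"])})
    return pd.DataFrame(rows)


def _flat(summary: dict) -> dict:
    return {"mean_curv": summary["area_weighted_mean"],
            "mean_abs_curv": summary["area_weighted_mean_abs"],
            "min_curv": summary["min"], "max_curv": summary["max"]}


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Either ``input_dir`` (a directory of PLY/STL/OBJ surfaces, one per
    subject) or ``synthetic`` (a PopulationConfig) names the cohort.
    """

    synthetic: PopulationConfig | None = None
    input_dir: str | None = None
    n_report_modes: int = 4
    n_model_modes: int | None = None     # None: all n-1 modes
    smoothing_rounds: int = 3
    min_component_frac: float = 0.01
    skip_gpa: bool = False
    # synthetic cohorts share connectivity; correspondence can then be the
    # identity instead of CPD + surface projection
    identity_correspondence: bool = True
    gpa_max_iter: int = 100
    gpa_tol: float = 1e-8

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError("exactly one of synthetic/input_dir must be set")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "template_resolution" in syn:
                syn["template_resolution"] = tuple(syn["template_resolution"])
            raw["synthetic"] = PopulationConfig(**syn)
        return cls(**raw)

    def to_provenance(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "synthetic"}
        if self.synthetic is not None:
            syn = dict(self.synthetic.__dict__)
            syn["template_resolution"] = list(syn["template_resolution"])
            out["synthetic"] = syn
        return out


@dataclass
class ComparisonReport:
    """All pipeline data products plus provenance, serialisable to JSON."""

    cumulative_variance: pd.DataFrame
    curvature: pd.DataFrame
    distance_summaries: list
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "cumulative_variance": self.cumulative_variance.to_dict("records"),
            "curvature": self.curvature.to_dict("records"),
            "distance_summaries": self.distance_summaries,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _load_cohort(input_dir: str) -> list:
    paths = sorted(os.path.join(input_dir, p) for p in os.listdir(input_dir)
                   if os.path.splitext(p)[1].lower() in (".ply", ".stl", ".obj"))
    if len(paths) < 3:
        raise ValueError(f"need at least 3 mesh files in {input_dir}")
    return [read_mesh(p) for p in paths]


def run_pipeline(config: PipelineConfig, out_dir: str | None = None):
    """Run the complete study and return a :class:`ComparisonReport`.

    Stages: cohort -> template selection -> correspondence -> GPA ->
    curvature partition of the template -> label transfer -> nrSSM + rSSM
    fits -> +/-2SD synthesis per reported mode -> distance maps ->
    cumulative-variance and curvature comparisons.  Fully deterministic
    given the config (including the generator seed); artifacts and a
    timing log are written when ``out_dir`` is given.
    """
    log: list[str] = []
    t0 = time.time()

    def stage(name):
        log.append(f"[{time.time() - t0:8.2f}s] {name}")

    def fail(name, exc):
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- cohort ---------------------------------------------------------
    try:
        if config.synthetic is not None:
            sample = sample_population(config.synthetic)
            meshes = sample.meshes
        else:
            sample = None
            meshes = _load_cohort(config.input_dir)
        stage(f"cohort: {len(meshes)} subjects")
    except Exception as exc:
        fail("cohort", exc)

    # --- template selection --------------------------------------------
    try:
        template_index, rms_table = select_template(meshes)
        n = len(meshes)
        mean_rms = rms_table.sum(axis=1) / (n - 1)
        stage(f"template: subject {template_index}, "
              f"mean RMS {mean_rms[template_index]:.4f} mm")
    except Exception as exc:
        fail("select_template", exc)

    # --- correspondence -------------------------------------------------
    template = meshes[template_index]
    corr_meshes = []
    shared = config.identity_correspondence and all(
        m.vertex_count == template.vertex_count
        and np.array_equal(m.faces, template.faces) for m in meshes)
    for i, m in enumerate(meshes):
        try:
            corr_meshes.append(m.copy() if shared
                               else establish_correspondence(template, m))
        except Exception as exc:
            fail(f"establish_correspondence (subject {i})", exc)
    rms_corr = np.array([np.sqrt(((cm.vertices - template.vertices) ** 2)
                                 .sum(axis=1).mean()) if i == template_index else
                         rms_table[template_index, i]
                         for i, cm in enumerate(corr_meshes)])
    rms_corr[template_index] = 0.0
    corr_set = CorrespondedSet(corr_meshes, template_index, rms_corr)
    stage("correspondence: " + ("identity (shared connectivity)" if shared
                                else "CPD + surface projection"))

    # --- alignment ------------------------------------------------------
    try:
        if config.skip_gpa:
            aligned, mean_mesh = corr_meshes, None
        else:
            aligned, mean_mesh = generalized_procrustes(
                corr_meshes, max_iter=config.gpa_max_iter, tol=config.gpa_tol)
        stage("generalized Procrustes alignment")
    except Exception as exc:
        fail("generalized_procrustes", exc)

    # --- regions on the template ---------------------------------------
    try:
        aligned_template = aligned[template_index]
        fieldc = gaussian_curvature(aligned_template)
        labeling = partition_regions(fieldc, aligned_template,
                                     smoothing_rounds=config.smoothing_rounds,
                                     min_component_frac=config.min_component_frac)
        transfer_labels(labeling, corr_set)   # validates the transfer
        stage(f"regions: R = {labeling.n_regions}")
    except Exception as exc:
        fail("partition_regions", exc)

    # --- models ---------------------------------------------------------
    try:
        nr = fit_ssm(aligned, n_modes=config.n_model_modes)
        rr = fit_rssm(aligned, labeling, n_modes=config.n_model_modes)
        stage(f"models: nrSSM {nr.n_modes} modes; rSSM "
              f"{[m.n_modes for m in rr.region_models]} modes per region")
    except Exception as exc:
        fail("fit models", exc)

    # --- +/-2SD shapes and distance maps --------------------------------
    n_rep = min(config.n_report_modes, nr.n_modes)
    sd_meshes = {}
    dist_rows = []
    try:
        mean_nr = nr.mean_mesh()
        for mode in range(n_rep):
            lo = sd_model(nr, mode, -2.0)
            hi = sd_model(nr, mode, +2.0)
            sd_meshes[f"nrssm_mode{mode + 1}_minus2sd"] = lo
            sd_meshes[f"nrssm_mode{mode + 1}_plus2sd"] = hi
            for tag, a, b in [("mean_vs_minus2sd", mean_nr, lo),
                              ("mean_vs_plus2sd", mean_nr, hi),
                              ("minus2sd_vs_plus2sd", lo, hi)]:
                dm = distance_map(a, b)
                dist_rows.append({"model": "nrssm", "mode": mode + 1,
                                  "pair": tag, **dm.summary})
        order = regional_mode_order(rr)
        for mode in range(min(n_rep, len(order))):
            region, local = order[mode]
            lo = sd_model_regional(rr, region, local, -2.0)
            hi = sd_model_regional(rr, region, local, +2.0)
            sd_meshes[f"rssm_mode{mode + 1}_minus2sd"] = lo
            sd_meshes[f"rssm_mode{mode + 1}_plus2sd"] = hi
            mean_r = rr.mean_mesh()
            for tag, a, b in [("mean_vs_minus2sd", mean_r, lo),
                              ("mean_vs_plus2sd", mean_r, hi),
                              ("minus2sd_vs_plus2sd", lo, hi)]:
                dm = distance_map(a, b)
                dist_rows.append({"model": "rssm", "mode": mode + 1,
                                  "pair": tag, **dm.summary})
        stage(f"+/-2SD shapes and distance maps for {n_rep} modes")
    except Exception as exc:
        fail("sd_models/distance_maps", exc)

    # --- comparisons ----------------------------------------------------
    try:
        cv_table = compare_cumulative_variance(nr, rr)
        curv_table = curvature_comparison(nr, rr, modes=list(range(n_rep)))
        stage("comparison tables")
    except Exception as exc:
        fail("comparisons", exc)

    provenance = {
        "config": config.to_provenance(),
        "template_index": int(template_index),
        "template_mean_rms_mm": float(mean_rms[template_index]),
        "n_subjects": len(meshes),
        "n_regions": int(labeling.n_regions),
        "cohort_checksum": _sha256(np.concatenate(
            [m.vertices.ravel() for m in meshes])),
    }
    report = ComparisonReport(cv_table, curv_table, dist_rows, provenance)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
        cv_table.to_csv(os.path.join(out_dir, "cumulative_variance.csv"),
                        index=False)
        curv_table.to_csv(os.path.join(out_dir, "curvature_comparison.csv"),
                          index=False)
        pd.DataFrame(dist_rows).to_csv(
            os.path.join(out_dir, "distance_maps.csv"), index=False)
        from .shape_model import save_model
        save_model(nr, out_dir, "nrssm")
        for ri, sub in enumerate(rr.region_models):
            save_model(sub, out_dir, f"rssm_region{ri}")
        write_mesh(nr.mean_mesh(), os.path.join(out_dir, "mean_nrssm.ply"))
        write_mesh(rr.mean_mesh(), os.path.join(out_dir, "mean_rssm.ply"))
        for name, m in sd_meshes.items():
            write_mesh(m, os.path.join(out_dir, f"{name}.ply"))
        pd.DataFrame({"vertex": np.arange(labeling.vertex_count),
                      "curvature": fieldc.values,
                      "label": labeling.labels}).to_csv(
            os.path.join(out_dir, "template_curvature_labels.csv"), index=False)
        from .curvature import export_scalar_ply
        export_scalar_ply(aligned_template, fieldc.values,
                          os.path.join(out_dir, "template_curvature.ply"))
        pd.DataFrame(rms_table).to_csv(
            os.path.join(out_dir, "pairwise_rms.csv"), index=False)
        stage("artifacts written")
        with open(os.path.join(out_dir, "pipeline.log"), "w") as fh:
            fh.write("\n".join(log) + "\n")

    extras = {"nrssm": nr, "rssm": rr, "labeling": labeling,
              "aligned": aligned, "template_index": template_index,
              "rms_table": rms_table, "sample": sample, "log": log}
    return report, extras
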