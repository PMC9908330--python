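"""PCA statistical shape models on corresponded, aligned meshes.

The model is the linear form ``x = xbar + sum_i w_i Phi_i``: a mean
coordinate vector plus an orthonormal basis of variation modes, each with
the variance ``lambda_i`` of the training weights along it.  PCA is
computed through the n-by-n Gram (dual) eigenproblem, which is exact and
keeps memory linear in vertex count when 3V >> n.  At most ``n - 1``
modes exist for ``n`` training shapes.

Two model flavours are provided: the global (whole-surface, "nrSSM")
model, and the region-based ("rSSM") collection of independent per-region
models over a curvature-derived vertex partition.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .curvature import RegionLabeling
from .mesh import TriangleMesh

__all__ = [
    "ShapeModel", "RegionalShapeModel",
    "fit_ssm", "fit_rssm", "synthesize", "synthesize_vector", "sd_model", "project",
    "cumulative_variance", "synthesize_regional", "sd_model_regional",
    "regional_mode_order", "save_model", "load_model",
]


@dataclass
class ShapeModel:
    """A linear PCA shape model over flattened (3V,) vertex coordinates."""

    mean: np.ndarray                 # (3V,) mm
    components: np.ndarray           # (3V, k), orthonormal columns
    variances: np.ndarray            # (k,), non-increasing, mm^2
    n_train: int
    faces: np.ndarray | None = None  # shared connectivity (None for regional submodels)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float).ravel()
        self.components = np.asarray(self.components, float)
        self.variances = np.asarray(self.variances, float)
        k = self.components.shape[1]
        if self.variances.shape != (k,):
            raise ValueError("one variance per component required")
        if k > self.n_train - 1:
            raise ValueError(
                f"{k} modes exceed the n - 1 = {self.n_train - 1} limit for "
                f"{self.n_train} training shapes")
        if (np.diff(self.variances) > 1e-12).any():
            raise ValueError("variances must be non-increasing")
        G = self.components.T @ self.components
        if not np.allclose(G, np.eye(k), atol=1e-9):
            raise ValueError("components are not orthonormal to 1e-9")

    @property
    def n_modes(self) -> int:
        return self.components.shape[1]

    @property
    def n_vertices(self) -> int:
        return len(self.mean) // 3

    def mean_mesh(self) -> TriangleMesh:
        if self.faces is None:
            raise ValueError("model has no connectivity")
        return TriangleMesh(self.mean.reshape(-1, 3), self.faces.copy(), name="mean")


@dataclass
class RegionalShapeModel:
    """Independent per-region shape models over a vertex partition."""

    labeling: RegionLabeling
    region_models: list              # one ShapeModel per region id
    faces: np.ndarray                # full-surface connectivity
    region_indices: list = field(default=None)  # vertex ids per region

    def __post_init__(self) -> None:
        if len(self.region_models) != self.labeling.n_regions:
            raise ValueError("one model per region required")
        if self.region_indices is None:
            self.region_indices = [self.labeling.region_indices(r)
                                   for r in range(self.labeling.n_regions)]
        covered = np.sort(np.concatenate(self.region_indices))
        if not np.array_equal(covered, np.arange(self.labeling.vertex_count)):
            raise ValueError("region vertex sets must partition the surface")

    @property
    def n_regions(self) -> int:
        return self.labeling.n_regions

    def full_mean(self) -> np.ndarray:
        """(V, 3) mean shape reassembled from the regional means."""
        out = np.empty((self.labeling.vertex_count, 3))
        for idx, m in zip(self.region_indices, self.region_models):
            out[idx] = m.mean.reshape(-1, 3)
        return out

    def mean_mesh(self) -> TriangleMesh:
        return TriangleMesh(self.full_mean(), self.faces.copy(), name="mean")


def _flatten(meshes: list) -> np.ndarray:
    n0 = meshes[0].vertex_count
    for i, m in enumerate(meshes):
        if m.vertex_count != n0:
            raise ValueError(f"mesh {i} has {m.vertex_count} vertices, expected {n0}")
    return np.stack([m.vertices.ravel() for m in meshes])


def _orthonormal_completion(existing: np.ndarray, count: int) -> np.ndarray:
    """Deterministically extend an orthonormal column set by ``count``
    columns (used for zero-variance modes of degenerate cohorts)."""
    dim = existing.shape[0]
    cols = [existing[:, i] for i in range(existing.shape[1])]
    added = []
    for j in range(dim):
        if len(added) == count:
            break
        v = np.zeros(dim)
        v[j] = 1.0
        for u in cols:
            v -= (u @ v) * u
        nrm = np.linalg.norm(v)
        if nrm > 0.5:
            v /= nrm
            cols.append(v)
            added.append(v)
    if len(added) < count:
        raise RuntimeError("could not complete orthonormal basis")
    return np.column_stack(added)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Largest-magnitude entry of each column made positive (PCA signs are
    otherwise arbitrary and would break reproducibility)."""
    idx = np.argmax(np.abs(components), axis=0)
    flip = components[idx, np.arange(components.shape[1])] < 0
    components = components.copy()
    components[:, flip] *= -1.0
    return components


def _pca_dual(X: np.ndarray, n_modes: int):
    """Exact PCA of the rows of X via the Gram eigenproblem.

    Returns (mean, components, variances) with the 1/(n-1) variance
    convention; zero-variance modes are filled with a deterministic
    orthonormal completion.
    """
    n = len(X)
    mean = X.mean(axis=0)
    C = X - mean
    G = C @ C.T
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1][:n_modes]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = max(np.trace(G), 1.0) * 1e-12
    pos = evals > tol
    comps_pos = C.T @ evecs[:, pos]
    comps_pos /= np.sqrt(evals[pos])[None, :]
    k_zero = int((~pos).sum())
    if k_zero:
        comps = np.column_stack([comps_pos,
                                 _orthonormal_completion(comps_pos, k_zero)]) \
            if comps_pos.size else _orthonormal_completion(
                np.empty((X.shape[1], 0)), k_zero)
    else:
        comps = comps_pos
    variances = np.where(pos, evals, 0.0) / (n - 1)
    return mean, _fix_signs(comps), variances


def fit_ssm(meshes: list, n_modes: int | None = None) -> ShapeModel:
    """Fit the global PCA shape model on aligned, corresponded meshes.

    ``n_modes`` defaults to all ``n - 1`` available modes; asking for more
    is an error (the component count cannot exceed one less than the
    number of training shapes).
    """
    if len(meshes) < 2:
        raise ValueError("fit_ssm needs at least 2 meshes")
    X = _flatten(meshes)
    n = len(X)
    if n_modes is None:
        n_modes = n - 1
    if n_modes > n - 1:
        raise ValueError(
            f"n_modes={n_modes} exceeds n - 1 = {n - 1} (at most one fewer "
            f"modes than training shapes)")
    mean, comps, variances = _pca_dual(X, n_modes)
    return ShapeModel(mean, comps, variances, n_train=n,
                      faces=meshes[0].faces.copy())


def fit_rssm(meshes: list, labeling: RegionLabeling,
             n_modes: int | None = None) -> RegionalShapeModel:
    """Fit one independent PCA model per curvature region.

    Each regional model sees only its region's vertex coordinates, so the
    regions are quantified independently of one another.
    """
    if len(meshes) < 2:
        raise ValueError("fit_rssm needs at least 2 meshes")
    X = _flatten(meshes)
    n = len(X)
    V = meshes[0].vertex_count
    if labeling.vertex_count != V:
        raise ValueError("labeling does not match the meshes")
    k = (n - 1) if n_modes is None else n_modes
    if k > n - 1:
        raise ValueError(f"n_modes={k} exceeds n - 1 = {n - 1}")
    coords = X.reshape(n, V, 3)
    models = []
    indices = []
    for r in range(labeling.n_regions):
        idx = labeling.region_indices(r)
        if len(idx) < 1:
            raise ValueError(f"region {r} has no vertices")
        Xr = coords[:, idx, :].reshape(n, -1)
        mean, comps, variances = _pca_dual(Xr, k)
        models.append(ShapeModel(mean, comps, variances, n_train=n, faces=None))
        indices.append(idx)
    return RegionalShapeModel(labeling, models, meshes[0].faces.copy(), indices)


def synthesize(model: ShapeModel, weights: np.ndarray) -> TriangleMesh:
    """Evaluate ``x = xbar + sum w_i Phi_i`` and reshape to a mesh."""
    w = np.asarray(weights, float).ravel()
    if len(w) > model.n_modes:
        raise ValueError(f"{len(w)} weights for a {model.n_modes}-mode model")
    if not np.isfinite(w).all():
        raise ValueError("weights must be finite")
    x = model.mean + model.components[:, :len(w)] @ w
    if model.faces is None:
        raise ValueError("regional submodels synthesize via synthesize_regional")
    return TriangleMesh(x.reshape(-1, 3), model.faces.copy(), name="synthesized")


def synthesize_vector(model: ShapeModel, weights: np.ndarray) -> np.ndarray:
    """Like :func:`synthesize` but returning the flat coordinate vector
    (works for regional submodels, which carry no connectivity)."""
    w = np.asarray(weights, float).ravel()
    if len(w) > model.n_modes:
        raise ValueError(f"{len(w)} weights for a {model.n_modes}-mode model")
    if not np.isfinite(w).all():
        raise ValueError("weights must be finite")
    return model.mean + model.components[:, :len(w)] @ w


def sd_model(model: ShapeModel, mode_index: int, k: float) -> TriangleMesh:
    """The shape at ``k`` standard deviations along one mode
    (``w = k * sqrt(lambda)``, all other modes zero); ``k = +/-2`` gives
    the conventional +/-2SD models."""
    if not 0 <= mode_index < model.n_modes:
        raise ValueError(f"mode_index {mode_index} out of range")
    lam = model.variances[mode_index]
    w = np.zeros(model.n_modes)
    if lam == 0.0:
        warnings.warn(f"mode {mode_index} has zero variance; returning the mean",
                      RuntimeWarning, stacklevel=2)
    else:
        w[mode_index] = k * np.sqrt(lam)
    return synthesize(model, w)


def project(model: ShapeModel, mesh) -> np.ndarray:
    """Mode weights of a shape: ``w_i = Phi_i^T (x - xbar)`` (the
    orthonormal-projection inverse of :func:`synthesize` on the model span).

    Accepts a TriangleMesh or a flat coordinate vector.
    """
    x = mesh.vertices.ravel() if isinstance(mesh, TriangleMesh) else \
        np.asarray(mesh, float).ravel()
    if len(x) != len(model.mean):
        raise ValueError(
            f"shape has {len(x) // 3} vertices, model expects {model.n_vertices}")
    return model.components.T @ (x - model.mean)


def cumulative_variance(model) -> dict:
    """Per-mode variance fractions and their running sum.

    For a :class:`RegionalShapeModel` the regional modes are pooled,
    sorted by variance, and normalised by the pooled total; per-region
    curves are also returned.
    """
    if isinstance(model, ShapeModel):
        lam = model.variances
        total = lam.sum()
        frac = lam / total if total > 0 else np.zeros_like(lam)
        return {"fractions": frac, "cumulative": np.cumsum(frac)}
    pooled = np.concatenate([m.variances for m in model.region_models])
    regions = np.concatenate([np.full(m.n_modes, r)
                              for r, m in enumerate(model.region_models)])
    local = np.concatenate([np.arange(m.n_modes) for m in model.region_models])
    order = np.argsort(pooled, kind="stable")[::-1]
    pooled, regions, local = pooled[order], regions[order], local[order]
    total = pooled.sum()
    frac = pooled / total if total > 0 else np.zeros_like(pooled)
    per_region = {r: cumulative_variance(m)
                  for r, m in enumerate(model.region_models)}
    return {"fractions": frac, "cumulative": np.cumsum(frac),
            "mode_region": regions, "mode_local_index": local,
            "per_region": per_region}


def regional_mode_order(model: RegionalShapeModel) -> list:
    """Global mode ranking of a regional model: list of (region, local mode)
    pairs in decreasing pooled-variance order."""
    cv = cumulative_variance(model)
    return [(int(r), int(i)) for r, i in zip(cv["mode_region"],
                                             cv["mode_local_index"])]


def synthesize_regional(model: RegionalShapeModel, region: int,
                        weights: np.ndarray) -> TriangleMesh:
    """Full-surface shape with one region synthesized at the given weights
    and every other region held at its mean.  Region boundaries are not
    blended."""
    out = model.full_mean()
    sub = model.region_models[region]
    out[model.region_indices[region]] = \
        synthesize_vector(sub, weights).reshape(-1, 3)
    return TriangleMesh(out, model.faces.copy(), name="synthesized-regional")


def sd_model_regional(model: RegionalShapeModel, region: int,
                      mode_index: int, k: float) -> TriangleMesh:
    """Regional counterpart of :func:`sd_model`."""
    sub = model.region_models[region]
    if not 0 <= mode_index < sub.n_modes:
        raise ValueError(f"mode_index {mode_index} out of range for region {region}")
    lam = sub.variances[mode_index]
    w = np.zeros(sub.n_modes)
    if lam == 0.0:
        warnings.warn(f"region {region} mode {mode_index} has zero variance; "
                      "returning the mean", RuntimeWarning, stacklevel=2)
    else:
        w[mode_index] = k * np.sqrt(lam)
    return synthesize_regional(model, region, w)


def save_model(model: ShapeModel, out_dir: str, name: str = "ssm") -> None:
    """Persist a model: arrays in .npz, metadata in JSON."""
    os.makedirs(out_dir, exist_ok=True)
    np.savez(os.path.join(out_dir, f"{name}_arrays.npz"),
             mean=model.mean, components=model.components,
             variances=model.variances,
             faces=model.faces if model.faces is not None else np.empty((0, 3), int))
    with open(os.path.join(out_dir, f"{name}_meta.json"), "w") as fh:
        json.dump({"n_train": model.n_train, "n_modes": model.n_modes,
                   "n_vertices": model.n_vertices}, fh, indent=2)


def load_model(out_dir: str, name: str = "ssm") -> ShapeModel:
    arr = np.load(os.path.join(out_dir, f"{name}_arrays.npz"))
    with open(os.path.join(out_dir, f"{name}_meta.json")) as fh:
        meta = json.load(fh)
    faces = arr["faces"]
    return ShapeModel(arr["mean"], arr["components"], arr["variances"],
                      n_train=meta["n_train"],
                      faces=faces if len(faces) else None)
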