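"""Registry of data-driven denoising pipelines producing the "neural" datasets.

Six base strategies — raw (identity), FIX (externally ICA-denoised input,
pass-through here), MildA (white-matter/CSF means + 12 motion regressors),
MildB (WM/CSF means and derivatives + 24-parameter motion expansion), WM_50
and WM_200 (principal-component time courses from a white-matter voxel pool)
— each evaluated with and without global signal regression, giving 12
strategies in total.  Denoising is OLS residualization of the parcellated ROI
series against the high-pass-filtered regressor block plus an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .io import MotionParams, ROITimeseries
from .nuisance_model import highpass_filter

BASE_STRATEGIES = ("raw", "FIX", "MildA", "MildB", "WM_50", "WM_200")


@dataclass
class PipelineSpec:
    name: str
    base: str
    gsr: bool
    external: bool = False
    wm_pca_k: int | None = None
    recipe: list[str] = field(default_factory=list)


def enumerate_registry() -> list[PipelineSpec]:
    """The 12 preprocessing strategies: 6 base x {GSR off, GSR on}.

    FIX entries are marked ``external``: they consume input already denoised
    elsewhere and only the GSR stage is applied internally.
    """
    registry = []
    for base in BASE_STRATEGIES:
        for gsr in (False, True):
            name = base + ("_GSR" if gsr else "")
            recipe = {
                "raw": [],
                "FIX": [],
                "MildA": ["wm_csf_means", "motion12"],
                "MildB": ["wm_csf_means", "wm_csf_derivatives", "motion24"],
                "WM_50": ["wm_pca"],
                "WM_200": ["wm_pca"],
            }[base]
            recipe = list(recipe)
            if gsr:
                recipe.append("gsr")
                if base == "MildB":
                    recipe.append("gsr_derivative")
            registry.append(
                PipelineSpec(
                    name=name,
                    base=base,
                    gsr=gsr,
                    external=base == "FIX",
                    wm_pca_k={"WM_50": 50, "WM_200": 200}.get(base),
                    recipe=recipe,
                )
            )
    assert len({s.name for s in registry}) == len(registry)
    return registry


def global_signal(matrix: np.ndarray | ROITimeseries) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean time-series across columns and its backward-difference
    derivative (first frame 0)."""
    values = matrix.values if isinstance(matrix, ROITimeseries) else np.asarray(matrix, float)
    if values.size == 0:
        raise ValueError("empty matrix")
    gs = values.mean(axis=1)
    deriv = np.concatenate([[0.0], np.diff(gs)])
    return gs, deriv


def wm_pca(wm_ts: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component time courses of the white-matter voxel pool,
    ordered by explained variance, with a deterministic sign convention (the
    largest-magnitude voxel loading of each component is positive)."""
    wm = np.asarray(wm_ts, dtype=float)
    n, v = wm.shape
    if k > min(n - 1, v):
        raise ValueError(f"k={k} exceeds min(frames-1, voxels)={min(n - 1, v)}")
    wm = wm - wm.mean(axis=0, keepdims=True)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(wm)
    for j in range(k):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            scores[:, j] *= -1
    return scores


def _motion_expansion(motion: MotionParams, order24: bool) -> np.ndarray:
    params = motion.values
    derivs = np.vstack([np.zeros((1, 6)), np.diff(params, axis=0)])
    blocks = [params, derivs]
    if order24:
        blocks += [params**2, derivs**2]
    return np.hstack(blocks)


def apply_pipeline(
    roi_ts: ROITimeseries,
    spec: PipelineSpec,
    motion: MotionParams | None = None,
    wm_ts: np.ndarray | None = None,
    csf_ts: np.ndarray | None = None,
) -> ROITimeseries:
    """Run one denoising strategy on a parcellated scan.

    When no CSF pool is supplied for the Mild pipelines, the white-matter pool
    is split in half and the two half-pool means stand in for the WM and CSF
    mean regressors.  External (FIX) specs pass the input through, applying
    only the GSR stage.
    """
    regressors: list[np.ndarray] = []
    n = roi_ts.n_frames

    def need(cond: bool, what: str) -> None:
        if not cond:
            raise ValueError(f"pipeline {spec.name!r} requires {what}")

    if not spec.external:
        if "wm_csf_means" in spec.recipe:
            need(wm_ts is not None, "a white-matter voxel pool")
            if csf_ts is None:
                half = wm_ts.shape[1] // 2
                wm_mean = wm_ts[:, :half].mean(axis=1)
                csf_mean = wm_ts[:, half:].mean(axis=1)
            else:
                wm_mean = wm_ts.mean(axis=1)
                csf_mean = np.asarray(csf_ts, float).mean(axis=1)
            regressors += [wm_mean, csf_mean]
            if "wm_csf_derivatives" in spec.recipe:
                for col in (wm_mean, csf_mean):
                    regressors.append(np.concatenate([[0.0], np.diff(col)]))
        if "motion12" in spec.recipe or "motion24" in spec.recipe:
            need(motion is not None, "motion parameters")
            regressors.append(_motion_expansion(motion, order24="motion24" in spec.recipe))
        if "wm_pca" in spec.recipe:
            need(wm_ts is not None, "a white-matter voxel pool")
            k = min(spec.wm_pca_k, min(n - 1, wm_ts.shape[1]))
            regressors.append(wm_pca(wm_ts, k))
    if spec.gsr:
        gs, gs_deriv = global_signal(roi_ts)
        regressors.append(gs)
        if "gsr_derivative" in spec.recipe:
            regressors.append(gs_deriv)

    if not regressors:
        return roi_ts.with_values(roi_ts.values.copy())
    X = np.column_stack([np.atleast_2d(r.T).T for r in regressors])
    X = highpass_filter(X, tr=roi_ts.tr)
    keep = X.std(axis=0) > 1e-12
    X = X[:, keep]
    Xi = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xi, roi_ts.values, rcond=None)
    return roi_ts.with_values(roi_ts.values - Xi @ beta)
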