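"""Isolation of per-process nuisance fluctuations from parcellated BOLD.

Each ROI time-series is modelled with all 25 nuisance regressors at once:

    y(t) = b0 + b_SLFO x_SLFO(t) + b_CP x_CP(t) + b_BM x_BM(t) + b_HM x_HM(t) + e(t)

For a process of interest, its fitted fluctuation y_npi is the product of its
regressors with their coefficients, and the "clean" series y_npi_plus_neur
removes the intercept and every *other* process from y, retaining the process
of interest plus the residual.  The per-ROI contributions

    r_nuis = corr(y_npi, y_npi_plus_neur),   r_neur = corr(y_neur, y_npi_plus_neur)

satisfy r_nuis^2 + r_neur^2 = 1 because the OLS residual is orthogonal to the
fitted component.  Nuisance datasets replace the residual ("neural") part by a
stationary AR(1) process so that each synthetic ROI series carries the same
nuisance-to-signal balance as the measured one without correlations between
weakly driven ROIs being inflated to +/-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ROITimeseries
from .nuisance_model import PROCESS_SLICES, PROCESS_TAGS, DesignMatrix


@dataclass
class GLMFit:
    beta0: np.ndarray  # (R,)
    betas: np.ndarray  # (25, R)
    residual: np.ndarray  # (frames, R)
    column_labels: list[str]

    def process_betas(self, tag: str) -> np.ndarray:
        return self.betas[PROCESS_SLICES[tag], :]


@dataclass
class ProcessComponents:
    process: str
    y_npi: np.ndarray
    y_npi_plus_neur: np.ndarray

    @property
    def y_neur(self) -> np.ndarray:
        return self.y_npi_plus_neur - self.y_npi


@dataclass
class ContributionResult:
    r_nuis: np.ndarray
    r_neur: np.ndarray
    degenerate: np.ndarray  # ROIs where the process explains no variance


@dataclass
class AR1Params:
    a1_pool: np.ndarray
    excluded: int = 0

    def __post_init__(self) -> None:
        self.a1_pool = np.asarray(self.a1_pool, dtype=float)
        if self.a1_pool.size and np.abs(self.a1_pool).max() >= 1:
            raise ValueError("AR(1) pool must lie strictly inside (-1, 1)")


def fit_glm(roi_ts: ROITimeseries, design: DesignMatrix) -> GLMFit:
    """Per-ROI OLS of the BOLD series on all 25 regressors plus an intercept."""
    Y = roi_ts.values
    X = design.values
    if Y.shape[0] != X.shape[0]:
        raise ValueError("ROI series and design must have equal frame counts")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; inspect the collinearity report "
            "from assemble_design"
        )
    Xi = np.column_stack([np.ones(X.shape[0]), X])
    coef, *_ = np.linalg.lstsq(Xi, Y, rcond=None)
    fitted = Xi @ coef
    return GLMFit(
        beta0=coef[0],
        betas=coef[1:],
        residual=Y - fitted,
        column_labels=list(design.column_labels),
    )


def extract_components(
    fit: GLMFit, design: DesignMatrix, roi_ts: ROITimeseries, process: str
) -> ProcessComponents:
    """Fitted fluctuation of one process and the companion "clean" series with
    all other processes (and the intercept) removed."""
    if process not in PROCESS_TAGS:
        raise ValueError(f"unknown process tag {process!r}; expected one of {PROCESS_TAGS}")
    y_npi = design.process_columns(process) @ fit.process_betas(process)
    clean = roi_ts.values - fit.beta0[None, :]
    for other in PROCESS_TAGS:
        if other != process:
            clean = clean - design.process_columns(other) @ fit.process_betas(other)
    return ProcessComponents(process=process, y_npi=y_npi, y_npi_plus_neur=clean)


def compute_contributions(components: ProcessComponents) -> ContributionResult:
    """Per-ROI nuisance and neural contributions to the clean series.

    ROIs where the process explains no variance get r_nuis = 0 and are flagged
    as degenerate.
    """
    y_npi = components.y_npi
    clean = components.y_npi_plus_neur
    y_neur = components.y_neur
    sd_npi = y_npi.std(axis=0)
    degenerate = sd_npi < 1e-12
    r_nuis = np.zeros(y_npi.shape[1])
    r_neur = np.zeros(y_npi.shape[1])
    for j in range(y_npi.shape[1]):
        if not degenerate[j]:
            r_nuis[j] = _corr(y_npi[:, j], clean[:, j])
        r_neur[j] = _corr(y_neur[:, j], clean[:, j]) if y_neur[:, j].std() > 1e-12 else 0.0
    return ContributionResult(r_nuis=r_nuis, r_neur=r_neur, degenerate=degenerate)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def fit_ar1_pool(series_pool: list[np.ndarray] | np.ndarray) -> AR1Params:
    """Empirical pool of lag-1 autocorrelation coefficients across series.

    Accepts a list of 1-D series or a frames x series matrix.  Constant series
    are excluded with a count.  Values are clipped to (-0.999, 0.999).
    """
    if isinstance(series_pool, np.ndarray) and series_pool.ndim == 2:
        series_pool = [series_pool[:, j] for j in range(series_pool.shape[1])]
    coeffs = []
    excluded = 0
    for s in series_pool:
        s = np.asarray(s, dtype=float)
        s = s - s.mean()
        denom = s @ s
        if denom < 1e-24:
            excluded += 1
            continue
        a1 = float(s[1:] @ s[:-1] / denom)
        coeffs.append(np.clip(a1, -0.999, 0.999))
    return AR1Params(a1_pool=np.asarray(coeffs), excluded=excluded)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - x.mean(axis=0)) / sd


def synthesize_nuisance_dataset(
    components: ProcessComponents,
    contributions: ContributionResult,
    ar1: AR1Params,
    roi_ts: ROITimeseries,
    seed: int,
    burn_in: int = 200,
) -> tuple[ROITimeseries, dict]:
    """Synthetic nuisance dataset for one process:

        y_nuis = r_nuis * Z[y_npi] + r_neur * Z[psi],  psi_t = a1 psi_{t-1} + xi_t

    with one a1 drawn per ROI from the empirical pool and a stationary burn-in.
    ROIs flagged degenerate become pure AR(1) columns.  Returns the dataset in
    the input's ROI-timeseries dialect plus a provenance record.
    """
    if ar1.a1_pool.size == 0:
        raise ValueError("empty AR(1) pool")
    rng = np.random.default_rng(seed)
    n, R = components.y_npi.shape
    from scipy.signal import lfilter

    a1_draws = rng.choice(ar1.a1_pool, size=R)
    noise = rng.standard_normal((burn_in + n, R))
    psi = np.empty_like(noise)
    for j in range(R):
        psi[:, j] = lfilter([1.0], [1.0, -a1_draws[j]], noise[:, j])
    psi = _zscore(psi[burn_in:])

    z_npi = np.where(
        contributions.degenerate[None, :], 0.0, _zscore(components.y_npi)
    )
    values = contributions.r_nuis[None, :] * z_npi + contributions.r_neur[None, :] * psi
    values[:, contributions.degenerate] = psi[:, contributions.degenerate]
    provenance = {
        "process": components.process,
        "seed": int(seed),
        "a1_draws": a1_draws.tolist(),
        "r_nuis": contributions.r_nuis.tolist(),
        "r_neur": contributions.r_neur.tolist(),
    }
    return roi_ts.with_values(values), provenance
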