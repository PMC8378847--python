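"""Construction of the 25 nuisance regressors on the fMRI frame grid.

The model comprises one regressor for systemic low-frequency oscillations
(heart rate and respiratory flow convolved with physiological response
functions, PRFs), six 3rd-order RETROICOR regressors for cardiac pulsatility,
six for breathing motion, and twelve head-motion regressors (realignment
parameters plus backward-difference derivatives, residualized against the
breathing-motion block).  All regressors are high-pass filtered at 0.01 Hz and
normalized to zero mean and unit variance before entering the GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .io import MotionParams, UniformSeries

PROCESS_TAGS = ("SLFO", "CP", "BM", "HM")

#: column slices of the assembled design by process tag
PROCESS_SLICES = {
    "SLFO": slice(0, 1),
    "CP": slice(1, 7),
    "BM": slice(7, 13),
    "HM": slice(13, 25),
}

DESIGN_LABELS = (
    ["slfo"]
    + [f"cp_{k}{m}" for m in (1, 2, 3) for k in ("c", "s")]
    + [f"bm_{k}{m}" for m in (1, 2, 3) for k in ("c", "s")]
    + [f"hm_{i}" for i in range(1, 13)]
)

# gamma-difference response-curve parameters: (shape+, scale+, shape-, scale-, ratio)
# chosen so the cardiac curve peaks near 4 s with an undershoot near 12 s and the
# respiratory curve peaks near 3.5 s with an undershoot near 15 s, the shapes
# reported for heart-rate and breathing response functions in the literature.
CANONICAL_CARDIAC = (3.5, 1.6, 7.0, 2.0, 0.5)
CANONICAL_RESP = (3.1, 1.7, 6.0, 3.0, 0.5)

PRF_BOUNDS = [(1.2, 12.0), (0.3, 5.0), (1.2, 12.0), (0.3, 5.0), (0.0, 2.0)]
PRF_SUPPORT_S = 60.0


@dataclass
class PRFModel:
    """Scan-specific (or canonical) physiological response functions."""

    cardiac_params: tuple[float, ...]
    resp_params: tuple[float, ...]
    weights: tuple[float, float] = (1.0, 1.0)
    fit_quality: float = np.nan
    method: str = "canonical"
    fallback: bool = False

    def curves(self, fs: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
        t = np.arange(0.0, PRF_SUPPORT_S, 1.0 / fs)
        return prf_curve(t, self.cardiac_params), prf_curve(t, self.resp_params)


@dataclass
class DesignMatrix:
    """frames x 25 nuisance design, column-labelled by process."""

    values: np.ndarray
    column_labels: list[str]
    tr: float

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def process_columns(self, tag: str) -> np.ndarray:
        if tag not in PROCESS_SLICES:
            raise ValueError(f"unknown process tag {tag!r}; expected one of {PROCESS_TAGS}")
        return self.values[:, PROCESS_SLICES[tag]]


@dataclass
class CollinearityReport:
    max_pairwise_r: float
    vif: np.ndarray
    warnings: list[str] = field(default_factory=list)


def _gamma_lobe(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    # unnormalized gamma density, peak-normalized afterwards
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(t > 0, np.exp((shape - 1) * np.log(np.maximum(t, 1e-12)) - t / scale), 0.0)
    return g / max(g.max(), 1e-300)


def prf_curve(t: np.ndarray, params: tuple[float, ...]) -> np.ndarray:
    """Gamma-density difference response curve, unit positive lobe."""
    shape_p, scale_p, shape_n, scale_n, ratio = params
    return _gamma_lobe(t, shape_p, scale_p) - ratio * _gamma_lobe(t, shape_n, scale_n)


def _convolve_prf(series: np.ndarray, curve: np.ndarray) -> np.ndarray:
    x = series - series.mean()
    return signal.fftconvolve(x, curve, mode="full")[: x.size]


def _slfo_terms(
    hr: UniformSeries, rf: UniformSeries, prf: PRFModel, frame_times: np.ndarray
) -> np.ndarray:
    """HR*CRF and RF*RRF convolved at the physio rate, sampled on the frame grid,
    each z-scored.  Returns frames x 2."""
    cols = []
    for series, which in ((hr, 0), (rf, 1)):
        curve = prf.curves(series.fs)[which]
        conv = _convolve_prf(series.values, curve)
        x = np.interp(frame_times, series.times, conv)
        sd = np.std(x, ddof=1)
        cols.append((x - x.mean()) / sd if sd > 0 else x - x.mean())
    return np.column_stack(cols)


def estimate_prf(
    hr: UniformSeries,
    rf: UniformSeries,
    global_signal: np.ndarray,
    tr: float,
    method: str = "scan_specific",
    n_starts: int = 8,
    seed: int = 0,
) -> PRFModel:
    """Estimate PRF curves for one scan.

    ``scan_specific`` runs a bounded multi-start optimization of the
    gamma-difference parameters, maximizing the multiple correlation between
    the two convolved series and the global signal; the OLS combination
    weights are part of the model.  ``canonical`` keeps fixed literature-shaped
    curves and only reports the fit quality.  If every optimization start
    fails, the canonical model is returned with ``fallback=True``.
    """
    gs = np.asarray(global_signal, dtype=float)
    frame_times = np.arange(gs.size) * tr
    gs_c = gs - gs.mean()

    # cache the series FFTs so each objective evaluation only transforms the
    # (short) candidate response curves
    from scipy import fft as sp_fft

    cache = []
    for series in (hr, rf):
        x = series.values - series.values.mean()
        curve_len = int(PRF_SUPPORT_S * series.fs)
        nfft = sp_fft.next_fast_len(x.size + curve_len - 1)
        cache.append((series, sp_fft.rfft(x, nfft), nfft))

    def conv_terms(params: np.ndarray) -> np.ndarray:
        cols = []
        for (series, xf, nfft), p in zip(cache, (params[:5], params[5:])):
            t = np.arange(0.0, PRF_SUPPORT_S, 1.0 / series.fs)
            curve = prf_curve(t, tuple(p))
            conv = sp_fft.irfft(xf * sp_fft.rfft(curve, nfft), nfft)[: series.values.size]
            col = np.interp(frame_times, series.times, conv)
            sd = np.std(col, ddof=1)
            cols.append((col - col.mean()) / sd if sd > 0 else col - col.mean())
        return np.column_stack(cols)

    def quality(params: np.ndarray) -> tuple[float, tuple[float, float]]:
        X = conv_terms(np.asarray(params, dtype=float))
        beta, *_ = np.linalg.lstsq(X, gs_c, rcond=None)
        fitted = X @ beta
        denom = np.linalg.norm(fitted) * np.linalg.norm(gs_c)
        r = float(fitted @ gs_c / denom) if denom > 0 else 0.0
        return r, (float(beta[0]), float(beta[1]))

    if method == "canonical":
        model = PRFModel(CANONICAL_CARDIAC, CANONICAL_RESP, method="canonical")
        r, w = quality(np.array(CANONICAL_CARDIAC + CANONICAL_RESP))
        model.fit_quality, model.weights = r, w
        return model
    if method != "scan_specific":
        raise ValueError(f"unknown PRF method {method!r}")

    rng = np.random.default_rng(seed)
    x0_base = np.array(CANONICAL_CARDIAC + CANONICAL_RESP)
    bounds = PRF_BOUNDS * 2
    best: tuple[float, np.ndarray] | None = None
    for k in range(n_starts):
        x0 = x0_base.copy()
        if k > 0:
            lo = np.array([b[0] for b in bounds])
            hi = np.array([b[1] for b in bounds])
            x0 = np.clip(x0 * rng.uniform(0.6, 1.5, size=10), lo, hi)
        try:
            res = optimize.minimize(
                lambda p: -quality(p)[0],
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 200},
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
            best = (float(res.fun), res.x)
    if best is None:
        warnings.warn("PRF optimization failed at every start; using canonical curves")
        model = estimate_prf(hr, rf, gs, tr, method="canonical")
        model.fallback = True
        return model
    params = best[1]
    r, w = quality(params)
    return PRFModel(
        tuple(params[:5]), tuple(params[5:]), weights=w, fit_quality=r, method="scan_specific"
    )


def build_slfo_regressor(
    hr: UniformSeries, rf: UniformSeries, prf: PRFModel, tr: float, n_frames: int
) -> np.ndarray:
    """Total SLFO time-course: weighted sum of HR*CRF and RF*RRF, sampled at
    frame times t = k*TR."""
    frame_times = np.arange(n_frames) * tr
    X = _slfo_terms(hr, rf, prf, frame_times)
    w = np.asarray(prf.weights, dtype=float)
    if not np.any(w):
        w = np.ones(2)
    return X @ w


def cardiac_phase(beat_times: np.ndarray, frame_times: np.ndarray) -> np.ndarray:
    """Cardiac cycle phase in [0, 2*pi): linear within each beat interval.

    Frames before the first (after the last) beat use the first (last)
    inter-beat interval extrapolated outward.
    """
    beats = np.asarray(beat_times, dtype=float)
    if beats.size < 2:
        raise ValueError("need at least two beats")
    t = np.asarray(frame_times, dtype=float)
    first_rr = beats[1] - beats[0]
    last_rr = beats[-1] - beats[-2]
    # extend the beat grid so every frame falls inside some interval
    pre = np.arange(beats[0], t.min() - first_rr, -first_rr)[1:][::-1]
    post = np.arange(beats[-1], t.max() + last_rr, last_rr)[1:]
    grid = np.concatenate([pre, beats, post])
    idx = np.clip(np.searchsorted(grid, t, side="right") - 1, 0, grid.size - 2)
    frac = (t - grid[idx]) / (grid[idx + 1] - grid[idx])
    return 2 * np.pi * np.clip(frac, 0.0, 1.0 - 1e-12)


def respiratory_phase(
    cleaned_resp: UniformSeries, frame_times: np.ndarray, n_bins: int = 100
) -> np.ndarray:
    """Amplitude-histogram-equalized respiratory phase in (-pi, pi].

    phi(t) = pi * P(R <= R(t)) * sign(dR/dt): the phase magnitude encodes how
    deep into the breath the belt amplitude sits, the sign inspiration vs
    expiration.
    """
    x = cleaned_resp.values
    if np.std(x) == 0:
        raise ValueError("zero-variance respiratory signal")
    counts, edges = np.histogram(x, bins=n_bins)
    cum = np.concatenate([[0], np.cumsum(counts)]).astype(float)
    amp = np.interp(frame_times, cleaned_resp.times, x)
    deriv = np.interp(frame_times, cleaned_resp.times, np.gradient(x) * cleaned_resp.fs)
    bin_idx = np.clip(np.searchsorted(edges, amp, side="right") - 1, 0, n_bins - 1)
    frac_in_bin = np.where(
        np.diff(edges)[bin_idx] > 0, (amp - edges[bin_idx]) / np.diff(edges)[bin_idx], 0.0
    )
    cdf = (cum[bin_idx] + frac_in_bin * counts[bin_idx]) / cum[-1]
    sign = np.where(deriv >= 0, 1.0, -1.0)
    return np.pi * cdf * sign


def retroicor_regressors(phase: np.ndarray, order: int = 3) -> np.ndarray:
    """Fourier expansion of a cyclic phase: [cos(m*phi), sin(m*phi)], m=1..order."""
    phase = np.asarray(phase, dtype=float)
    cols = []
    for m in range(1, order + 1):
        cols.append(np.cos(m * phase))
        cols.append(np.sin(m * phase))
    return np.column_stack(cols)


def build_motion_regressors(motion: MotionParams, bm_regressors: np.ndarray) -> np.ndarray:
    """12 head-motion regressors: the 6 realignment parameters and their
    backward-difference derivatives (first frame 0), each OLS-residualized
    against the 6 breathing-motion regressors plus an intercept, so that
    breathing-locked true and factitious motion is attributed to the
    breathing-motion process instead."""
    bm = np.asarray(bm_regressors, dtype=float)
    if bm.shape[0] != motion.n_frames:
        raise ValueError("breathing-motion regressors must be on the frame grid")
    if np.linalg.matrix_rank(bm) < bm.shape[1]:
        sds = bm.std(axis=0)
        bad = [f"bm_{i}" for i in np.nonzero(sds < 1e-12)[0]]
        raise ValueError(
            f"breathing-motion block is rank deficient (suspect columns: {bad or 'collinear set'})"
        )
    params = motion.values
    derivs = np.vstack([np.zeros((1, 6)), np.diff(params, axis=0)])
    hm = np.hstack([params, derivs])
    X = np.column_stack([np.ones(motion.n_frames), bm])
    beta, *_ = np.linalg.lstsq(X, hm, rcond=None)
    return hm - X @ beta


def highpass_filter(series: np.ndarray, tr: float, cutoff: float = 0.01) -> np.ndarray:
    """Zero-phase high-pass (2nd-order Butterworth, forward-backward) with the
    DC component removed exactly."""
    x = np.atleast_2d(np.asarray(series, dtype=float).T).T
    fs = 1.0 / tr
    n = x.shape[0]
    if n * tr < 2.0 / cutoff:
        warnings.warn(
            f"scan duration {n * tr:.0f} s is under two cutoff periods ({2 / cutoff:.0f} s); "
            "high-pass response is poorly defined"
        )
    sos = signal.butter(2, cutoff, btype="high", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, x, axis=0)
    out = out - out.mean(axis=0, keepdims=True)
    return out if np.asarray(series).ndim > 1 else out[:, 0]


def assemble_design(
    slfo: np.ndarray,
    cp: np.ndarray,
    bm: np.ndarray,
    hm: np.ndarray,
    tr: float,
) -> tuple[DesignMatrix, CollinearityReport]:
    """Stack the four regressor blocks (1+6+6+12 = 25 columns), high-pass at
    0.01 Hz, z-score each column, and report collinearity (max pairwise |r|
    and variance-inflation factors; VIF > 10 warns but does not fail)."""
    blocks = [np.atleast_2d(np.asarray(b, dtype=float).T).T for b in (slfo, cp, bm, hm)]
    widths = [b.shape[1] for b in blocks]
    if widths != [1, 6, 6, 12]:
        raise ValueError(f"expected block widths [1, 6, 6, 12], got {widths}")
    X = np.hstack(blocks)
    X = highpass_filter(X, tr=tr)
    sds = X.std(axis=0, ddof=1)
    const = np.nonzero(sds < 1e-12)[0]
    if const.size:
        names = [DESIGN_LABELS[i] for i in const]
        raise ValueError(f"constant design column(s) after filtering: {names}")
    X = (X - X.mean(axis=0)) / sds

    corr = np.corrcoef(X, rowvar=False)
    off = corr[~np.eye(25, dtype=bool)]
    try:
        vif = np.diag(np.linalg.inv(corr))
    except np.linalg.LinAlgError:
        vif = np.full(25, np.inf)
    report = CollinearityReport(max_pairwise_r=float(np.abs(off).max()), vif=vif)
    for i in np.nonzero(vif > 10)[0]:
        report.warnings.append(f"column {DESIGN_LABELS[i]} has VIF {vif[i]:.1f}")
    return DesignMatrix(values=X, column_labels=list(DESIGN_LABELS), tr=tr), report
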