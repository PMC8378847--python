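"""Static and time-varying functional connectivity.

Static FC is the ROI x ROI Pearson correlation over the whole scan.
Time-varying FC uses sliding windows (default 60 samples with 70% overlap,
i.e. a step of 18 frames; at TR 0.72 s a window spans 43.2 s).  The FCD
(functional connectivity dynamics) matrix correlates the vectorized upper
triangles of the windowed FC matrices against each other, one row/column per
window.  Similarity between two connectomes is the Pearson correlation of
their upper-triangular entries, Fisher z-transformed; for FCD matrices the
pairs of temporally overlapping windows are excluded, since their correlation
is high by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ROITimeseries


@dataclass
class FCMatrix:
    values: np.ndarray
    roi_labels: list[str]
    network_labels: dict[str, str] = field(default_factory=dict)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_rois, k=1)
        return self.values[iu]


@dataclass
class FCDMatrix:
    values: np.ndarray
    window_starts: np.ndarray
    window_length: int
    step: int

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


@dataclass
class SimilarityResult:
    r: float
    z: float
    n_pairs_used: int


def static_fc(roi_ts: ROITimeseries | np.ndarray) -> FCMatrix:
    """Pairwise Pearson correlation between ROI time-series over the whole scan."""
    if isinstance(roi_ts, ROITimeseries):
        values, labels, nets = roi_ts.values, roi_ts.roi_labels, roi_ts.network_labels
    else:
        values = np.asarray(roi_ts, dtype=float)
        labels = [str(i) for i in range(values.shape[1])]
        nets = {}
    if values.shape[0] < 3:
        raise ValueError("need at least 3 frames for correlation")
    sds = values.std(axis=0)
    if np.any(sds < 1e-14):
        bad = [labels[i] for i in np.nonzero(sds < 1e-14)[0]]
        raise ValueError(f"constant ROI column(s): {bad}")
    fc = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    return FCMatrix(values=fc, roi_labels=list(labels), network_labels=dict(nets))


def sliding_windows(n_frames: int, window: int = 60, step: int = 18) -> np.ndarray:
    """Start frames of sliding windows: 0, step, ... while start+window <= n_frames.

    70% temporal overlap corresponds to step = round(0.3 * window).
    """
    if window > n_frames:
        raise ValueError("window longer than the scan")
    if step < 1:
        raise ValueError("step must be >= 1")
    return np.arange(0, n_frames - window + 1, step)


def fcd_matrix(roi_ts: ROITimeseries, window: int = 60, step: int = 18) -> FCDMatrix:
    """Window-by-window correlation of vectorized windowed FC upper triangles."""
    starts = sliding_windows(roi_ts.n_frames, window=window, step=step)
    if starts.size < 2:
        raise ValueError("need at least 2 windows for an FCD matrix")
    triangles = []
    for s in starts:
        sub = roi_ts.with_values(roi_ts.values[s : s + window])
        triangles.append(static_fc(sub).upper_triangle())
    fcd = np.corrcoef(np.asarray(triangles))
    np.fill_diagonal(fcd, 1.0)
    return FCDMatrix(values=fcd, window_starts=starts, window_length=window, step=step)


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z-transform with clipping at 1 - 1e-15 so degenerate equal
    matrices stay finite."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1):
        raise ValueError("correlation magnitude exceeds 1")
    z = np.arctanh(np.clip(r_arr, -1 + 1e-15, 1 - 1e-15))
    return float(z) if np.isscalar(r) or r_arr.ndim == 0 else z


def matrix_similarity(
    a: FCMatrix | FCDMatrix, b: FCMatrix | FCDMatrix, exclude_overlap: bool = True
) -> SimilarityResult:
    """Pearson correlation of the upper triangles of two same-kind matrices.

    For FCD matrices with ``exclude_overlap``, window pairs whose start times
    differ by less than the window length are dropped (their FC estimates
    share frames and correlate by design).
    """
    if type(a) is not type(b):
        raise ValueError("matrices must be of the same kind")
    if a.values.shape != b.values.shape:
        raise ValueError("shape mismatch")
    n = a.values.shape[0]
    iu = np.triu_indices(n, k=1)
    av, bv = a.values[iu], b.values[iu]
    if isinstance(a, FCDMatrix) and exclude_overlap:
        if not np.array_equal(a.window_starts, b.window_starts) or a.window_length != b.window_length:
            raise ValueError("FCD window metadata mismatch")
        lag = np.abs(a.window_starts[iu[1]] - a.window_starts[iu[0]])
        keep = lag >= a.window_length
        av, bv = av[keep], bv[keep]
    r = float(np.corrcoef(av, bv)[0, 1])
    return SimilarityResult(r=r, z=float(fisher_z(r)), n_pairs_used=int(av.size))
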