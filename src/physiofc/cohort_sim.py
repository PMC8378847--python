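"""Synthetic resting-state cohort with known nuisance ground truth.

The generator emulates the study design this package analyses: each subject
contributes scans on two days, one left-to-right (LR) and one right-to-left
(RL) phase-encoded run per day, with concurrent pulse-oximeter and
breathing-belt traces.  Per scan it produces

* quasi-periodic cardiac and respiratory waveforms with subject-specific
  rates and slow rate/depth variability,
* realignment parameters mixing slow drift, breathing-coupled pseudomotion
  on the phase-encoding axis, and sparse displacement steps,
* parcellated ROI series built as a forward model: a modular, subject-specific
  neural covariance driving an AR(1) process, plus every nuisance regressor
  scaled by per-ROI gain maps and ground-truth coefficients, plus white noise,
* a white-matter voxel pool sharing the nuisance components.

The breathing-motion gain map carries a hemispheric contrast whose sign flips
between LR and RL encodings, emulating the phase-encoding dependence of
breathing pseudomotion.  All ground truth (betas, gain maps, covariances,
subject physiology) is returned for parameter-recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import physio_prep
from .io import (
    MotionParams,
    PhysioRecording,
    ROITimeseries,
    write_motion,
    write_physio,
    write_roi_timeseries,
)
from .connectivity import FCMatrix, static_fc
from .nuisance_model import (
    CANONICAL_CARDIAC,
    CANONICAL_RESP,
    PRFModel,
    DesignMatrix,
    assemble_design,
    build_motion_regressors,
    build_slfo_regressor,
    cardiac_phase,
    respiratory_phase,
    retroicor_regressors,
)

DEFAULT_NETWORKS = ("visual", "sensorimotor", "dmn", "frontoparietal", "salience", "limbic")

#: per-process dimensionless gain scales (the simulated "SNR" of each process),
#: a strong-confound regime in which every process is detectable per scan
DEFAULT_GAINS = {"SLFO": 0.8, "CP": 0.3, "BM": 0.35, "HM": 0.4}


@dataclass
class SimConfig:
    """Cohort design and forward-model settings.

    Scan geometry defaults follow the emulated acquisition (1200 frames at
    TR 0.72 s, two days x {LR, RL}); the physiological sampling rate defaults
    to 100 Hz, ample for pulse-peak timing at the simulated waveform widths.
    """

    n_subjects: int = 10
    n_sessions: int = 2
    encodings: tuple[str, ...] = ("LR", "RL")
    n_frames: int = 1200
    tr: float = 0.72
    physio_fs: float = 100.0
    n_rois: int = 60
    network_labels: dict[str, str] | None = None
    n_wm_voxels: int = 250
    snr_params: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAINS))
    noise_sd: float = 0.2
    neural_ar1: float = 0.3
    subject_specific_gains: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.snr_params.values()):
            raise ValueError("nuisance gains must be >= 0")
        if self.network_labels is None:
            self.network_labels = {
                r: DEFAULT_NETWORKS[i * len(DEFAULT_NETWORKS) // self.n_rois]
                for i, r in enumerate(self.roi_labels)
            }

    @property
    def roi_labels(self) -> list[str]:
        return [f"roi_{i:03d}" for i in range(self.n_rois)]

    @property
    def duration(self) -> float:
        return self.n_frames * self.tr

    @property
    def sessions(self) -> list[str]:
        return [f"day{d + 1}" for d in range(self.n_sessions)]

    def hemispheres(self) -> np.ndarray:
        """Alternating left/right assignment (+1 / -1) across ROIs."""
        return np.where(np.arange(self.n_rois) % 2 == 0, 1.0, -1.0)


@dataclass
class SubjectParams:
    hr_baseline: float  # bpm
    hrv_sd: float  # bpm
    breathing_rate: float  # Hz
    depth_var: float
    motion_coupling: float  # mm per unit breathing amplitude
    spike_rate: float  # events / min
    prf: PRFModel
    gain_jitter: np.ndarray  # per-process per-ROI multiplicative jitter
    neural_cov: np.ndarray
    process_coeffs: dict[str, np.ndarray]  # per-regressor coefficients


@dataclass
class CohortGroundTruth:
    beta_true: np.ndarray  # R x 25
    gain_maps: dict[str, np.ndarray]
    neural_cov: np.ndarray
    subject_params: dict


@dataclass
class ScanBundle:
    physio: PhysioRecording
    motion: MotionParams
    roi_ts: ROITimeseries
    wm_ts: np.ndarray
    truth: CohortGroundTruth
    design: DesignMatrix  # the true mixing design, for oracle testing
    beat_times: np.ndarray


# ---------------------------------------------------------------------------
# waveform generators


def _bounded_walk(
    n: int, fs: float, baseline: float, sd: float, tau_s: float, rng: np.random.Generator,
    lo: float, hi: float,
) -> np.ndarray:
    """Smooth bounded random walk (OU process) around ``baseline``."""
    if sd == 0:
        return np.full(n, float(baseline))
    from scipy.signal import lfilter

    a = np.exp(-1.0 / (tau_s * fs))
    innov = rng.normal(0, sd * np.sqrt(1 - a**2), size=n)
    innov[0] = rng.normal(0, sd)
    x = lfilter([1.0], [1.0, -a], innov)
    return np.clip(baseline + x, lo, hi)


def simulate_cardiac_waveform(
    duration: float,
    fs: float,
    hr_baseline: float,
    hrv_sd: float,
    seed: int,
    noise_sd: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Pulse-oximeter-like waveform and its true beat times.

    The instantaneous rate is a bounded smooth random walk around
    ``hr_baseline``; a raised-cosine pulse with a dicrotic-notch bump is placed
    at each beat, the main peak exactly at the beat time.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (40 <= hr_baseline <= 200):
        raise ValueError("hr_baseline must lie in [40, 200] bpm")
    if fs < 50:
        raise ValueError("cardiac sampling rate must be >= 50 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    rate_bpm = _bounded_walk(n, fs, hr_baseline, hrv_sd, tau_s=8.0, rng=rng, lo=40.0, hi=200.0)
    phase = np.cumsum(rate_bpm / 60.0) / fs  # beats elapsed at each grid point
    phase -= phase[0]  # first beat exactly at t = 0
    n_beats = int(np.floor(phase[-1])) + 1
    t_grid = np.arange(n) / fs
    beat_times = np.interp(np.arange(n_beats), phase, t_grid)
    wave = np.zeros(n)
    # raised-cosine systolic peak (centered on the beat) + low-prominence
    # dicrotic shoulder that must not register as a separate beat
    for center, width, amp in ((0.0, 0.60, 1.0), (0.25, 0.20, 0.25)):
        for bt in beat_times:
            lo = int(np.floor((bt + center - width / 2) * fs))
            hi = int(np.ceil((bt + center + width / 2) * fs)) + 1
            idx = np.arange(max(lo, 0), min(hi, n))
            if idx.size:
                u = (idx / fs - bt - center) / (width / 2)
                wave[idx] += amp * 0.5 * (1 + np.cos(np.pi * np.clip(u, -1, 1)))
    wave += rng.normal(0, noise_sd, size=n)
    return wave, beat_times


def simulate_respiratory_waveform(
    duration: float,
    fs: float,
    rate_baseline: float,
    depth_var: float,
    seed: int,
    rate_var: float = 0.08,
    deep_breath_rate: float = 0.5,
    noise_sd: float = 0.02,
) -> np.ndarray:
    """Breathing-belt-like waveform: quasi-sinusoid with slowly varying rate
    and depth, plus occasional deep breaths (Poisson, ``deep_breath_rate`` per
    minute, amplitude >= 2x median)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (0.1 <= rate_baseline <= 0.5):
        raise ValueError("rate_baseline must lie in [0.1, 0.5] Hz")
    if fs < 2 * rate_baseline:
        raise ValueError("sampling rate below Nyquist for the breathing rate")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    rate = _bounded_walk(
        n, fs, rate_baseline, rate_var * rate_baseline, tau_s=20.0, rng=rng,
        lo=0.5 * rate_baseline, hi=1.5 * rate_baseline,
    )
    phase = 2 * np.pi * np.cumsum(rate) / fs
    depth = _bounded_walk(n, fs, 1.0, depth_var, tau_s=15.0, rng=rng, lo=0.2, hi=3.0)
    t_grid = np.arange(n) / fs
    n_deep = rng.poisson(deep_breath_rate * duration / 60.0)
    for te in rng.uniform(0, duration, size=n_deep):
        sigma = 1.0 / (2 * rate_baseline)
        depth += 1.5 * np.exp(-0.5 * ((t_grid - te) / sigma) ** 2)
    return depth * np.sin(phase) + rng.normal(0, noise_sd, size=n)


def simulate_motion_params(
    n_frames: int,
    tr: float,
    breathing_wave: np.ndarray,
    coupling: float,
    spike_rate: float,
    seed: int,
    drift_sd: float = 0.001,
    spike_amp: float = 0.2,
) -> MotionParams:
    """Six realignment-parameter columns: integrated drift + breathing-coupled
    pseudomotion (predominantly on the phase-encoding translation axis, column
    0) + sparse displacement steps (Poisson, ``spike_rate`` per minute)."""
    breathing_wave = np.asarray(breathing_wave, dtype=float)
    if breathing_wave.size != n_frames:
        raise ValueError("breathing wave must be resampled to the frame grid")
    rng = np.random.default_rng(seed)
    values = np.cumsum(rng.normal(0, drift_sd, size=(n_frames, 6)), axis=0)
    if coupling != 0:
        bw = breathing_wave - breathing_wave.mean()
        sd = bw.std()
        if sd > 0:
            bw = bw / sd
        values[:, 0] += coupling * bw
        values[:, 1:] += 0.1 * coupling * bw[:, None] * rng.normal(0, 1, size=5)
    n_spikes = rng.poisson(spike_rate * n_frames * tr / 60.0)
    for _ in range(n_spikes):
        frame = rng.integers(n_frames)
        col = rng.integers(6)
        amp = spike_amp * rng.choice([-1, 1]) * rng.uniform(0.5, 1.5)
        values[frame:, col] += amp  # a step: the head settles at a new position
    return MotionParams(values=values, tr=tr)


# ---------------------------------------------------------------------------
# subject- and cohort-level structure


def modular_covariance(
    n_rois: int,
    networks: list[str],
    rng: np.random.Generator | None = None,
    within: float = 0.35,
    between: float = 0.05,
    jitter_sd: float = 0.1,
) -> np.ndarray:
    """Modular correlation template (+ optional subject edge jitter), projected
    to the nearest positive-semidefinite matrix with unit diagonal."""
    nets = np.asarray(networks)
    cov = np.where(nets[:, None] == nets[None, :], within, between)
    np.fill_diagonal(cov, 1.0)
    if rng is not None and jitter_sd > 0:
        noise = rng.normal(0, jitter_sd, size=(n_rois, n_rois))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        cov = cov + noise
    w, v = np.linalg.eigh(cov)
    cov = (v * np.maximum(w, 1e-4)) @ v.T
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    return (cov + cov.T) / 2


def draw_subject_params(config: SimConfig, rng: np.random.Generator) -> SubjectParams:
    """One draw of subject-level physiology, motion tendency, PRF shape, gain
    jitter, coefficients and neural covariance (stable across that subject's
    scans)."""
    jitter_scale = 0.3 if config.subject_specific_gains else 0.0
    prf_jitter = rng.uniform(0.85, 1.15, size=10) if config.subject_specific_gains else np.ones(10)
    cardiac = tuple(np.asarray(CANONICAL_CARDIAC) * prf_jitter[:5])
    resp = tuple(np.asarray(CANONICAL_RESP) * prf_jitter[5:])
    coeffs = {
        "SLFO": np.ones(1),
        "CP": rng.normal(0, 1, size=6),
        "BM": rng.normal(0, 1, size=6),
        "HM": rng.normal(0, 1, size=12),
    }
    return SubjectParams(
        hr_baseline=float(np.clip(rng.normal(65, 7), 50, 90)),
        hrv_sd=float(rng.uniform(2, 5)),
        breathing_rate=float(np.clip(rng.normal(0.27, 0.04), 0.15, 0.4)),
        depth_var=float(rng.uniform(0.1, 0.3)),
        motion_coupling=float(rng.uniform(0.04, 0.08)),
        spike_rate=float(rng.uniform(0.2, 1.0)),
        prf=PRFModel(cardiac, resp, method="canonical"),
        gain_jitter=np.abs(1.0 + jitter_scale * rng.normal(0, 1, size=(4, config.n_rois))),
        neural_cov=modular_covariance(
            config.n_rois,
            [config.network_labels[r] for r in config.roi_labels],
            rng=rng if config.subject_specific_gains else None,
        ),
        process_coeffs=coeffs,
    )


def group_gain_maps(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Group-level per-ROI gain maps.  SLFOs weigh more on the visual network;
    breathing motion carries the hemispheric contrast (applied per encoding in
    :func:`simulate_scan`)."""
    nets = np.asarray([config.network_labels[r] for r in config.roi_labels])
    maps = {}
    for process, gain in config.snr_params.items():
        base = np.abs(rng.normal(1.0, 0.2, size=config.n_rois))
        if process == "SLFO":
            base = base * np.where(nets == "visual", 1.5, 1.0)
        maps[process] = gain * base
    return maps


def simulate_scan(
    subject_params: SubjectParams,
    config: SimConfig,
    session: str,
    encoding: str,
    group_gains: dict[str, np.ndarray],
    seed: int,
    subject: str | None = None,
) -> ScanBundle:
    """Forward model for one scan: nuisance regressors built from the simulated
    physiology/motion, mixed into a neural AR(1) draw with per-ROI gains."""
    if encoding not in config.encodings:
        raise ValueError(f"unknown encoding {encoding!r}")
    _assert_psd(subject_params.neural_cov)
    rng = np.random.default_rng(seed)
    duration, fs = config.duration, config.physio_fs

    cardiac, beat_times = simulate_cardiac_waveform(
        duration, fs, subject_params.hr_baseline, subject_params.hrv_sd,
        seed=int(rng.integers(2**31)),
    )
    respiratory = simulate_respiratory_waveform(
        duration, fs, subject_params.breathing_rate, subject_params.depth_var,
        seed=int(rng.integers(2**31)),
    )
    physio = PhysioRecording(cardiac=cardiac, respiratory=respiratory, fs=fs)
    frame_times = np.arange(config.n_frames) * config.tr

    # regressors from the simulated ground truth (true beats, true PRFs)
    cleaned_resp = physio_prep.preprocess_respiration(physio)
    hr = physio_prep.compute_heart_rate(beat_times)
    rf = physio_prep.compute_respiratory_flow(cleaned_resp)
    slfo = build_slfo_regressor(hr, rf, subject_params.prf, config.tr, config.n_frames)
    cp = retroicor_regressors(cardiac_phase(beat_times, frame_times))
    bm = retroicor_regressors(respiratory_phase(cleaned_resp, frame_times))
    breathing_on_frames = np.interp(frame_times, cleaned_resp.times, cleaned_resp.values)
    motion = simulate_motion_params(
        config.n_frames, config.tr, breathing_on_frames,
        coupling=subject_params.motion_coupling, spike_rate=subject_params.spike_rate,
        seed=int(rng.integers(2**31)),
    )
    hm = build_motion_regressors(motion, bm)
    design, _ = assemble_design(slfo, cp, bm, hm, tr=config.tr)

    # per-ROI ground-truth coefficients
    hemi = config.hemispheres()
    pe_sign = 1.0 if encoding == config.encodings[0] else -1.0
    gain_maps = {}
    for p_idx, process in enumerate(("SLFO", "CP", "BM", "HM")):
        g = group_gains[process] * subject_params.gain_jitter[p_idx]
        if process == "BM":
            g = g * (1.0 + 0.5 * pe_sign * hemi)
        gain_maps[process] = g
    beta_true = np.zeros((config.n_rois, 25))
    col = 0
    for process in ("SLFO", "CP", "BM", "HM"):
        c = subject_params.process_coeffs[process]
        beta_true[:, col : col + c.size] = np.outer(gain_maps[process], c)
        col += c.size

    neural = _ar1_multivariate(
        subject_params.neural_cov, config.n_frames, config.neural_ar1, rng
    )
    bold = neural + design.values @ beta_true.T
    bold += rng.normal(0, config.noise_sd, size=bold.shape)
    roi_ts = ROITimeseries(
        values=bold, tr=config.tr, roi_labels=config.roi_labels,
        network_labels=dict(config.network_labels), encoding=encoding,
        subject=subject, session=session,
    )

    # WM voxels share the nuisance processes with voxel-specific per-process
    # gains, so the pool spans the nuisance subspace (plus WM-specific noise)
    beta_wm = np.zeros((config.n_wm_voxels, 25))
    col = 0
    for process in ("SLFO", "CP", "BM", "HM"):
        c = subject_params.process_coeffs[process]
        g_wm = np.abs(rng.normal(0.4, 0.15, size=config.n_wm_voxels))
        beta_wm[:, col : col + c.size] = np.outer(g_wm, c)
        col += c.size
    wm_ts = design.values @ beta_wm.T + rng.normal(0, 0.5, size=(config.n_frames, config.n_wm_voxels))

    truth = CohortGroundTruth(
        beta_true=beta_true,
        gain_maps=gain_maps,
        neural_cov=subject_params.neural_cov,
        subject_params={
            "hr_baseline": subject_params.hr_baseline,
            "hrv_sd": subject_params.hrv_sd,
            "breathing_rate": subject_params.breathing_rate,
            "prf_cardiac": list(subject_params.prf.cardiac_params),
            "prf_resp": list(subject_params.prf.resp_params),
        },
    )
    return ScanBundle(
        physio=physio, motion=motion, roi_ts=roi_ts, wm_ts=wm_ts,
        truth=truth, design=design, beat_times=beat_times,
    )


def _assert_psd(cov: np.ndarray) -> None:
    w = np.linalg.eigvalsh((cov + cov.T) / 2)
    if w.min() < -1e-8:
        raise ValueError("neural covariance is not positive semidefinite")


def _ar1_multivariate(
    cov: np.ndarray, n_frames: int, a1: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) draw with the given spatial covariance (unit variance
    per ROI when cov has unit diagonal)."""
    from scipy.signal import lfilter

    w, v = np.linalg.eigh((cov + cov.T) / 2)
    L = v * np.sqrt(np.maximum(w, 0.0))
    z = rng.standard_normal((n_frames, cov.shape[0])) @ L.T
    scale = np.sqrt(1 - a1**2)
    innov = scale * z
    innov[0] = z[0]
    return lfilter([1.0], [1.0, -a1], innov, axis=0)


# ---------------------------------------------------------------------------
# cohort orchestration


def build_manifest(config: SimConfig) -> dict:
    """Scan records for the full design: n_subjects x n_sessions x encodings."""
    scans = []
    for s in range(config.n_subjects):
        subject = f"sub-{s + 1:03d}"
        for session in config.sessions:
            for encoding in config.encodings:
                scans.append(
                    {
                        "subject": subject,
                        "session": session,
                        "encoding": encoding,
                        "scan_id": f"{subject}_{session}_{encoding}",
                    }
                )
    return {
        "n_subjects": config.n_subjects,
        "tr": config.tr,
        "n_frames": config.n_frames,
        "physio_fs": config.physio_fs,
        "seed": config.seed,
        "scans": scans,
    }


def iter_cohort(config: SimConfig):
    """Yield (scan_record, ScanBundle) for the whole cohort, deterministically
    under ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    gains_rng = np.random.default_rng(root.spawn(1)[0])
    group_gains = group_gain_maps(config, gains_rng)
    subject_seeds = root.spawn(config.n_subjects)
    manifest = build_manifest(config)
    for s in range(config.n_subjects):
        subj_root = subject_seeds[s]
        subject_params = draw_subject_params(config, np.random.default_rng(subj_root))
        scan_seeds = subj_root.spawn(config.n_sessions * len(config.encodings))
        k = 0
        subject = f"sub-{s + 1:03d}"
        for session in config.sessions:
            for encoding in config.encodings:
                record = manifest["scans"][
                    s * config.n_sessions * len(config.encodings) + k
                ]
                bundle = simulate_scan(
                    subject_params, config, session, encoding, group_gains,
                    seed=int(np.random.default_rng(scan_seeds[k]).integers(2**31)),
                    subject=subject,
                )
                yield record, bundle
                k += 1


def simulate_cohort(config: SimConfig, out_dir: str | Path) -> dict:
    """Simulate and serialize the whole cohort; returns the manifest."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {out_dir}: {exc}") from exc
    manifest = build_manifest(config)
    for record, bundle in iter_cohort(config):
        scan_dir = out_dir / record["scan_id"]
        scan_dir.mkdir(exist_ok=True)
        write_physio(bundle.physio, scan_dir / "physio.tsv")
        write_motion(bundle.motion, scan_dir / "motion.tsv")
        write_roi_timeseries(bundle.roi_ts, scan_dir / "roi_timeseries.tsv")
        np.savetxt(scan_dir / "wm_timeseries.tsv", bundle.wm_ts, delimiter="\t", fmt="%.6g")
        truth = {
            "beta_true": bundle.truth.beta_true.tolist(),
            "gain_maps": {k: v.tolist() for k, v in bundle.truth.gain_maps.items()},
            "neural_cov": bundle.truth.neural_cov.tolist(),
            "subject_params": bundle.truth.subject_params,
            "beat_times": bundle.beat_times.tolist(),
        }
        (scan_dir / "truth.json").write_text(json.dumps(truth))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# lightweight FC-only cohort (for fingerprinting nulls at full cohort size)


def simulate_fc_cohort(
    n_subjects: int,
    n_rois: int = 60,
    n_sessions: int = 2,
    n_frames: int = 150,
    seed: int = 0,
) -> dict[str, dict[str, FCMatrix]]:
    """Static FC matrices only: per subject, a modular covariance with subject
    jitter, sampled independently per session (covariance draw + sampling
    noise).  Cheap enough to run at the full 392-subject design."""
    root = np.random.SeedSequence(seed)
    networks = [DEFAULT_NETWORKS[i * len(DEFAULT_NETWORKS) // n_rois] for i in range(n_rois)]
    roi_labels = [f"roi_{i:03d}" for i in range(n_rois)]
    net_map = dict(zip(roi_labels, networks))
    out: dict[str, dict[str, FCMatrix]] = {}
    for s, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        cov = modular_covariance(n_rois, networks, rng=rng)
        sessions = {}
        for k in range(n_sessions):
            x = _ar1_multivariate(cov, n_frames, 0.3, rng)
            x += rng.normal(0, 0.5, size=x.shape)
            fc = static_fc(x)
            sessions[f"sess{k + 1}"] = FCMatrix(
                values=fc.values, roi_labels=roi_labels, network_labels=net_map
            )
        out[f"sub-{s + 1:03d}"] = sessions
    return out
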