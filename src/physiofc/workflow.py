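"""End-to-end orchestration: simulate -> physio -> regressors -> isolate ->
connect -> fingerprint -> surrogates.

Every stage reads its inputs from, and writes its outputs to, a run directory
so stages can be re-run independently.  A provenance JSON (config, seed,
package version) accompanies each stage's outputs.  One run seed expands into
independent per-stage substreams.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import physio_prep
from .cohort_sim import SimConfig, simulate_cohort
from .connectivity import fcd_matrix, static_fc
from .denoise import apply_pipeline, enumerate_registry
from .fingerprint import permutation_null, run_all_combinations, whole_brain_mask
from .io import (
    UniformSeries,
    read_motion,
    read_physio,
    read_roi_timeseries,
    write_matrix,
    write_roi_timeseries,
)
from .isolation import (
    compute_contributions,
    extract_components,
    fit_ar1_pool,
    fit_glm,
    synthesize_nuisance_dataset,
)
from .nuisance_model import (
    DESIGN_LABELS,
    PROCESS_TAGS,
    DesignMatrix,
    assemble_design,
    build_motion_regressors,
    build_slfo_regressor,
    cardiac_phase,
    estimate_prf,
    respiratory_phase,
    retroicor_regressors,
)
from .surrogate_stats import bh_fdr, null_contribution_distribution

logger = logging.getLogger("physiofc")

_version = "0.1.0"

STAGES = ("simulate", "physio", "regressors", "isolate", "connect", "fingerprint", "surrogates")


class RunConfig(BaseModel):
    """Validated run configuration (YAML-friendly)."""

    sim: dict = Field(default_factory=dict)
    prf_method: str = "canonical"
    window: int = 60
    step: int = 18
    n_reps_surrogate: int = 50
    n_perm_fingerprint: int = 200
    surrogate_processes: list[str] = ["SLFO"]
    seed: int = 0
    log_level: str = "INFO"

    def sim_config(self, seed: int | None = None) -> SimConfig:
        params = dict(self.sim)
        params.setdefault("seed", seed if seed is not None else self.seed)
        if seed is not None:
            params["seed"] = seed
        return SimConfig(**params)


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0] % 2**31)


def _provenance(out: Path, stage: str, config: RunConfig, seed: int) -> None:
    (out / "provenance.json").write_text(
        json.dumps(
            {"stage": stage, "seed": seed, "version": _version, "config": config.model_dump()},
            indent=1,
            sort_keys=True,
        )
    )


def load_manifest(path: str | Path) -> dict:
    """Load and validate a cohort manifest; index scans by id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    manifest = json.loads(path.read_text())
    missing = [k for k in ("scans", "tr", "n_frames") if k not in manifest]
    if missing:
        raise ValueError(f"manifest missing fields: {missing}")
    seen = set()
    for scan in manifest["scans"]:
        bad = [k for k in ("subject", "session", "encoding", "scan_id") if k not in scan]
        if bad:
            raise ValueError(f"scan record missing fields: {bad}")
        if scan["scan_id"] in seen:
            raise ValueError(f"duplicate scan key {scan['scan_id']!r}")
        seen.add(scan["scan_id"])
        scan_dir = path.parent / scan["scan_id"]
        if not scan_dir.exists():
            raise FileNotFoundError(f"scan directory missing: {scan_dir}")
    return manifest


def run_simulate(config: RunConfig, out_dir: str | Path) -> dict:
    out = Path(out_dir) / "cohort"
    seed = _stage_seed(config.seed, "simulate")
    manifest = simulate_cohort(config.sim_config(seed=seed), out)
    _provenance(out, "simulate", config, seed)
    return manifest


def run_physio(config: RunConfig, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    manifest = load_manifest(out_dir / "cohort" / "manifest.json")
    out = out_dir / "physio"
    out.mkdir(exist_ok=True)
    for scan in manifest["scans"]:
        scan_dir = out_dir / "cohort" / scan["scan_id"]
        rec = read_physio(scan_dir / "physio.tsv")
        beats = physio_prep.detect_cardiac_peaks(rec)
        hr = physio_prep.compute_heart_rate(beats)
        resp = physio_prep.preprocess_respiration(rec)
        rf = physio_prep.compute_respiratory_flow(resp)
        dst = out / scan["scan_id"]
        dst.mkdir(exist_ok=True)
        for name, series in (("hr", hr), ("rf", rf)):
            pd.DataFrame({"time": series.times, "value": series.values}).to_csv(
                dst / f"{name}.tsv", sep="\t", index=False, float_format="%.8g"
            )
        np.savetxt(dst / "resp_clean.tsv", resp.values, fmt="%.6g")
        (dst / "meta.json").write_text(
            json.dumps({"beat_times": beats.tolist(), "resp_fs": resp.fs})
        )
    _provenance(out, "physio", config, _stage_seed(config.seed, "physio"))


def _load_series(path: Path) -> UniformSeries:
    df = pd.read_csv(path, sep="\t")
    t = df["time"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 10.0
    return UniformSeries(values=df["value"].to_numpy(), fs=float(fs), start_time=float(t[0]))


def run_regressors(config: RunConfig, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    manifest = load_manifest(out_dir / "cohort" / "manifest.json")
    out = out_dir / "designs"
    out.mkdir(exist_ok=True)
    seed = _stage_seed(config.seed, "regressors")
    for scan in manifest["scans"]:
        scan_dir = out_dir / "cohort" / scan["scan_id"]
        phys_dir = out_dir / "physio" / scan["scan_id"]
        roi_ts = read_roi_timeseries(scan_dir / "roi_timeseries.tsv")
        meta = json.loads((phys_dir / "meta.json").read_text())
        beats = np.asarray(meta["beat_times"])
        hr = _load_series(phys_dir / "hr.tsv")
        rf = _load_series(phys_dir / "rf.tsv")
        resp = UniformSeries(
            values=np.loadtxt(phys_dir / "resp_clean.tsv"), fs=float(meta["resp_fs"])
        )
        gs = roi_ts.values.mean(axis=1)
        prf = estimate_prf(hr, rf, gs, roi_ts.tr, method=config.prf_method, seed=seed)
        frame_times = roi_ts.frame_times
        slfo = build_slfo_regressor(hr, rf, prf, roi_ts.tr, roi_ts.n_frames)
        cp = retroicor_regressors(cardiac_phase(beats, frame_times))
        bm = retroicor_regressors(respiratory_phase(resp, frame_times))
        motion = read_motion(scan_dir / "motion.tsv", tr=roi_ts.tr)
        hm = build_motion_regressors(motion, bm)
        design, report = assemble_design(slfo, cp, bm, hm, tr=roi_ts.tr)
        dst = out / scan["scan_id"]
        dst.mkdir(exist_ok=True)
        pd.DataFrame(design.values, columns=design.column_labels).to_csv(
            dst / "design.tsv", sep="\t", index=False, float_format="%.8g"
        )
        (dst / "prf.json").write_text(
            json.dumps(
                {
                    "cardiac_params": list(prf.cardiac_params),
                    "resp_params": list(prf.resp_params),
                    "weights": list(prf.weights),
                    "fit_quality": prf.fit_quality,
                    "method": prf.method,
                    "max_pairwise_r": report.max_pairwise_r,
                    "vif_warnings": report.warnings,
                },
            )
        )
    _provenance(out, "regressors", config, seed)


def _load_design(path: Path, tr: float) -> DesignMatrix:
    df = pd.read_csv(path, sep="\t")
    return DesignMatrix(values=df.to_numpy(), column_labels=list(df.columns), tr=tr)


def run_isolate(config: RunConfig, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    manifest = load_manifest(out_dir / "cohort" / "manifest.json")
    out = out_dir / "isolation"
    out.mkdir(exist_ok=True)
    seed = _stage_seed(config.seed, "isolate")
    # AR(1) pool from the parcellated series of the whole cohort
    pool_series = []
    scans = []
    for scan in manifest["scans"]:
        roi_ts = read_roi_timeseries(out_dir / "cohort" / scan["scan_id"] / "roi_timeseries.tsv")
        design = _load_design(out_dir / "designs" / scan["scan_id"] / "design.tsv", roi_ts.tr)
        scans.append((scan, roi_ts, design))
        pool_series.append(roi_ts.values)
    ar1 = fit_ar1_pool(np.hstack(pool_series))
    rng = np.random.default_rng(seed)
    for scan, roi_ts, design in scans:
        fit = fit_glm(roi_ts, design)
        dst = out / scan["scan_id"]
        dst.mkdir(exist_ok=True)
        rows = {}
        for process in PROCESS_TAGS:
            comps = extract_components(fit, design, roi_ts, process)
            contrib = compute_contributions(comps)
            nuis_ts, prov = synthesize_nuisance_dataset(
                comps, contrib, ar1, roi_ts, seed=int(rng.integers(2**31))
            )
            write_roi_timeseries(nuis_ts, dst / f"nuisance_{process}.tsv")
            (dst / f"nuisance_{process}_provenance.json").write_text(json.dumps(prov))
            rows[f"r_nuis_{process}"] = contrib.r_nuis
            rows[f"r_neur_{process}"] = contrib.r_neur
        pd.DataFrame({"roi": roi_ts.roi_labels, **rows}).to_csv(
            dst / "contributions.tsv", sep="\t", index=False, float_format="%.6g"
        )
        pd.DataFrame(fit.betas.T, columns=DESIGN_LABELS).assign(roi=roi_ts.roi_labels).to_csv(
            dst / "betas.tsv", sep="\t", index=False, float_format="%.6g"
        )
    _provenance(out, "isolate", config, seed)


def run_connect(config: RunConfig, out_dir: str | Path) -> int:
    """FC and FCD for the 4 nuisance datasets and the 12 denoising strategies
    (32 matrices per scan).  FIX slots consume the raw series as a stand-in for
    externally denoised input.  Returns matrices written per scan."""
    out_dir = Path(out_dir)
    manifest = load_manifest(out_dir / "cohort" / "manifest.json")
    out = out_dir / "connectivity"
    out.mkdir(exist_ok=True)
    registry = enumerate_registry()
    n_written = 0
    for scan in manifest["scans"]:
        scan_dir = out_dir / "cohort" / scan["scan_id"]
        roi_ts = read_roi_timeseries(scan_dir / "roi_timeseries.tsv")
        motion = read_motion(scan_dir / "motion.tsv", tr=roi_ts.tr)
        wm_ts = np.loadtxt(scan_dir / "wm_timeseries.tsv", delimiter="\t")
        dst = out / scan["scan_id"]
        dst.mkdir(exist_ok=True)
        n_written = 0
        for process in PROCESS_TAGS:
            nuis = read_roi_timeseries(
                out_dir / "isolation" / scan["scan_id"] / f"nuisance_{process}.tsv"
            )
            write_matrix(static_fc(nuis).values, dst / f"fc_nuisance_{process}.tsv")
            fcd = fcd_matrix(nuis, window=config.window, step=config.step)
            write_matrix(fcd.values, dst / f"fcd_nuisance_{process}.tsv")
            n_written += 2
        for spec in registry:
            neural = apply_pipeline(roi_ts, spec, motion=motion, wm_ts=wm_ts)
            write_matrix(static_fc(neural).values, dst / f"fc_neural_{spec.name}.tsv")
            fcd = fcd_matrix(neural, window=config.window, step=config.step)
            write_matrix(fcd.values, dst / f"fcd_neural_{spec.name}.tsv")
            n_written += 2
    (out / "window_meta.json").write_text(
        json.dumps({"window": config.window, "step": config.step})
    )
    _provenance(out, "connect", config, _stage_seed(config.seed, "connect"))
    return n_written


def run_fingerprint(config: RunConfig, out_dir: str | Path, dataset: str = "neural_raw") -> dict:
    """Whole-brain fingerprinting over all session pairs, plus the permuted-
    identity null, on one dataset's static FC matrices."""
    out_dir = Path(out_dir)
    manifest = load_manifest(out_dir / "cohort" / "manifest.json")
    seed = _stage_seed(config.seed, "fingerprint")
    from .io import read_matrix

    fc: dict[str, dict] = {}
    meta: dict[str, dict] = {}
    for scan in manifest["scans"]:
        from .connectivity import FCMatrix

        values = read_matrix(
            out_dir / "connectivity" / scan["scan_id"] / f"fc_{dataset}.tsv"
        )
        tag = f"{scan['session']}_{scan['encoding']}"
        labels = [str(i) for i in range(values.shape[0])]
        fc.setdefault(scan["subject"], {})[tag] = FCMatrix(values=values, roi_labels=labels)
        meta[tag] = {"day": scan["session"], "encoding": scan["encoding"]}
    mask = whole_brain_mask(next(iter(fc.values()))[next(iter(meta))].n_rois)
    results = run_all_combinations(fc, edge_mask=mask, session_meta=meta)
    null = permutation_null(fc, n_perm=config.n_perm_fingerprint, seed=seed, edge_mask=mask)
    out = out_dir / "fingerprint"
    out.mkdir(exist_ok=True)
    payload = {
        "dataset": dataset,
        "results": [
            {
                "database": r.database_session,
                "target": r.target_session,
                "edge_set": r.edge_set,
                "accuracy": r.accuracy,
                "same_day": r.same_day,
                "same_encoding": r.same_encoding,
            }
            for r in results
        ],
        "null_mean_accuracy": float(null.mean()),
        "n_perm": config.n_perm_fingerprint,
    }
    (out / f"{dataset}.json").write_text(json.dumps(payload, indent=1))
    pd.DataFrame(payload["results"]).to_csv(
        out / f"{dataset}.tsv", sep="\t", index=False
    )
    _provenance(out, "fingerprint", config, seed)
    return payload


def run_surrogates(config: RunConfig, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    manifest = load_manifest(out_dir / "cohort" / "manifest.json")
    seed = _stage_seed(config.seed, "surrogates")
    roi_list, designs, subjects = [], [], []
    for scan in manifest["scans"]:
        roi_ts = read_roi_timeseries(out_dir / "cohort" / scan["scan_id"] / "roi_timeseries.tsv")
        designs.append(_load_design(out_dir / "designs" / scan["scan_id"] / "design.tsv", roi_ts.tr))
        roi_list.append(roi_ts)
        subjects.append(scan["subject"])
    out = out_dir / "surrogates"
    out.mkdir(exist_ok=True)
    for process in config.surrogate_processes:
        null = null_contribution_distribution(
            roi_list, designs, subjects, process, n_reps=config.n_reps_surrogate, seed=seed
        )
        reject, _ = bh_fdr(null.p_values, q=0.05)
        pd.DataFrame(
            {
                "roi": roi_list[0].roi_labels,
                "observed": null.observed,
                "p": null.p_values,
                "q_flag": reject.astype(int),
            }
        ).to_csv(out / f"{process}.tsv", sep="\t", index=False, float_format="%.6g")
        (out / f"{process}_meta.json").write_text(
            json.dumps({"n_reps": config.n_reps_surrogate, "seed": seed, "process": process})
        )
    _provenance(out, "surrogates", config, seed)


def run_all(config: RunConfig, out_dir: str | Path) -> None:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for stage, fn in (
        ("simulate", run_simulate),
        ("physio", run_physio),
        ("regressors", run_regressors),
        ("isolate", run_isolate),
        ("connect", run_connect),
        ("fingerprint", run_fingerprint),
        ("surrogates", run_surrogates),
    ):
        logger.info("stage %s", stage)
        fn(config, out_dir)
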