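"""Inter-subject surrogate nulls and group statistics.

The significance of a nuisance process's contribution to BOLD is assessed by
re-running the isolation with the examined process's physiological/motion
regressors taken from a *different* subject's scan (all other regressors kept)
— an inter-subject surrogate.  Repeating this (default 1000 times) yields a
per-ROI null distribution of the cross-scan mean contribution, against which
the observed mean contribution is compared with an empirical one-sided p-value
(with the +1 correction so p > 0).  Multiple-comparison control uses
Benjamini-Hochberg FDR or Bonferroni; group comparisons use the two-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .isolation import compute_contributions, extract_components, fit_glm
from .nuisance_model import PROCESS_SLICES, DesignMatrix


@dataclass
class SurrogatePairing:
    """Donor scan index for each scan, crossing subjects (a derangement)."""

    donor_index: np.ndarray


@dataclass
class NullDistribution:
    null_values: np.ndarray  # reps x ROI
    observed: np.ndarray  # per ROI
    p_values: np.ndarray  # per ROI, one-sided right tail


def make_surrogate_pairings(
    subjects: list[str], n_reps: int, seed: int, max_tries: int = 1000
) -> list[SurrogatePairing]:
    """Per repetition, a donor assignment such that no scan receives signals
    from its own subject (a derangement over subjects, applied scan-wise)."""
    subjects = list(subjects)
    uniq = sorted(set(subjects))
    if len(uniq) < 2:
        raise ValueError("need at least two subjects for inter-subject surrogates")
    rng = np.random.default_rng(seed)
    subj_idx = {s: i for i, s in enumerate(uniq)}
    scans_by_subject: dict[str, list[int]] = {s: [] for s in uniq}
    for i, s in enumerate(subjects):
        scans_by_subject[s].append(i)
    pairings = []
    for _ in range(n_reps):
        for _ in range(max_tries):
            perm = rng.permutation(len(uniq))
            if not np.any(perm == np.arange(len(uniq))):
                break
        else:  # pragma: no cover - probability ~ (1/e)^max_tries
            raise RuntimeError("failed to draw a derangement")
        donor = np.empty(len(subjects), dtype=int)
        for i, s in enumerate(subjects):
            donor_subj = uniq[perm[subj_idx[s]]]
            donor_scans = scans_by_subject[donor_subj]
            donor[i] = donor_scans[rng.integers(len(donor_scans))]
        pairings.append(SurrogatePairing(donor_index=donor))
    return pairings


def _mean_r_nuis(
    roi_ts_list: list, designs: list[DesignMatrix], process: str
) -> np.ndarray:
    vals = []
    for roi_ts, design in zip(roi_ts_list, designs):
        fit = fit_glm(roi_ts, design)
        comps = extract_components(fit, design, roi_ts, process)
        vals.append(compute_contributions(comps).r_nuis)
    return np.mean(vals, axis=0)


def null_contribution_distribution(
    roi_ts_list: list,
    designs: list[DesignMatrix],
    subjects: list[str],
    process: str,
    n_reps: int,
    seed: int,
) -> NullDistribution:
    """Per-ROI null distribution of the cross-scan mean nuisance contribution.

    For each surrogate repetition, only the examined process's design columns
    are replaced by those of the donor scan; the GLM and contribution
    computation are re-run in full.
    """
    observed = _mean_r_nuis(roi_ts_list, designs, process)
    pairings = make_surrogate_pairings(subjects, n_reps, seed)
    sl = PROCESS_SLICES[process]
    null = np.empty((n_reps, observed.size))
    for rep, pairing in enumerate(pairings):
        surrogate_designs = []
        for i, design in enumerate(designs):
            values = design.values.copy()
            values[:, sl] = designs[pairing.donor_index[i]].values[:, sl]
            surrogate_designs.append(
                DesignMatrix(values=values, column_labels=design.column_labels, tr=design.tr)
            )
        null[rep] = _mean_r_nuis(roi_ts_list, surrogate_designs, process)
    p = (1 + np.sum(null >= observed[None, :], axis=0)) / (1 + n_reps)
    return NullDistribution(null_values=null, observed=observed, p_values=p)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up rejections and the largest rejected p."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold


def bonferroni(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p < alpha / p.size


def ranksum_compare(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test: exact enumeration for
    small untied samples, normal approximation with tie correction otherwise."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (max(a.size, b.size) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
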