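"""Connectome-based identification of individuals.

A database holds one static FC matrix per subject from one session; a target
matrix from another session is identified as the database subject whose FC
upper triangle correlates most strongly with it.  Accuracy is the fraction of
subjects identified correctly when each serves as target once.  With four
sessions per subject (2 days x 2 phase encodings) there are 4 x 3 = 12 ordered
database-target combinations.  Identification can be restricted to edges
within or between networks; networks with fewer than 10 ROIs are excluded.
The permutation null shuffles subject identity in the database, giving chance
accuracy 1/n_subjects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .connectivity import FCMatrix

TIE_TOL = 1e-12


@dataclass
class FingerprintResult:
    flags: np.ndarray  # 0/1 per subject
    accuracy: float
    database_session: str
    target_session: str
    edge_set: str
    same_day: bool | None = None
    same_encoding: bool | None = None


def _edge_vector(fc: FCMatrix, edge_mask: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(fc.n_rois, k=1)
    return fc.values[iu][edge_mask]


def whole_brain_mask(n_rois: int) -> np.ndarray:
    return np.ones(n_rois * (n_rois - 1) // 2, dtype=bool)


def network_edge_mask(
    network_labels: list[str],
    mode: str,
    nets: str | tuple[str, str],
    min_rois: int = 10,
) -> np.ndarray:
    """Boolean mask over upper-triangle edges restricted to one network
    (``within``) or a network pair (``between``).  Networks with fewer than
    ``min_rois`` ROIs are rejected."""
    labels = np.asarray(network_labels)
    counts = {n: int((labels == n).sum()) for n in np.unique(labels)}
    requested = (nets,) if isinstance(nets, str) else tuple(nets)
    for n in requested:
        if n not in counts:
            raise ValueError(f"unknown network {n!r}")
        if counts[n] < min_rois:
            raise ValueError(f"network {n!r} has {counts[n]} ROIs (< {min_rois}); excluded")
    iu, ju = np.triu_indices(labels.size, k=1)
    if mode == "within":
        (net,) = requested
        mask = (labels[iu] == net) & (labels[ju] == net)
    elif mode == "between":
        n1, n2 = requested
        if n1 == n2:
            raise ValueError("between-network mask needs two distinct networks")
        mask = ((labels[iu] == n1) & (labels[ju] == n2)) | (
            (labels[iu] == n2) & (labels[ju] == n1)
        )
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'within' or 'between'")
    if not mask.any():
        raise ValueError("empty edge mask")
    return mask


def identify(
    database: dict[str, FCMatrix], target: FCMatrix, edge_mask: np.ndarray
) -> tuple[str | None, dict[str, float]]:
    """Predicted subject for one target matrix: argmax Pearson correlation over
    masked edges.  A tied maximum (within 1e-12) returns prediction None."""
    if not np.any(edge_mask):
        raise ValueError("empty edge mask")
    tv = _edge_vector(target, edge_mask)
    corrs = {
        subj: float(np.corrcoef(tv, _edge_vector(fc, edge_mask))[0, 1])
        for subj, fc in database.items()
    }
    values = np.asarray(list(corrs.values()))
    subjects = list(corrs)
    best = values.max()
    ties = np.nonzero(values >= best - TIE_TOL)[0]
    predicted = subjects[ties[0]] if ties.size == 1 else None
    return predicted, corrs


def _identification_flags(corr_matrix: np.ndarray) -> np.ndarray:
    """Success flags from a target x database correlation matrix with matched
    subject ordering; ties count as failures."""
    n = corr_matrix.shape[0]
    flags = np.zeros(n)
    for i in range(n):
        row = corr_matrix[i]
        best = row.max()
        ties = np.nonzero(row >= best - TIE_TOL)[0]
        flags[i] = float(ties.size == 1 and ties[0] == i)
    return flags


def cross_correlation_matrix(
    database: dict[str, FCMatrix], targets: dict[str, FCMatrix], edge_mask: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """targets x database Pearson correlations over masked edges, with a shared
    subject ordering."""
    subjects = sorted(database)
    if sorted(targets) != subjects:
        raise ValueError("database and target sets must cover the same subjects")
    db = np.asarray([_edge_vector(database[s], edge_mask) for s in subjects])
    tg = np.asarray([_edge_vector(targets[s], edge_mask) for s in subjects])
    db = (db - db.mean(axis=1, keepdims=True)) / db.std(axis=1, keepdims=True)
    tg = (tg - tg.mean(axis=1, keepdims=True)) / tg.std(axis=1, keepdims=True)
    return tg @ db.T / db.shape[1], subjects


def identification_accuracy(
    database: dict[str, FCMatrix],
    targets: dict[str, FCMatrix],
    edge_mask: np.ndarray,
    database_session: str = "",
    target_session: str = "",
    edge_set: str = "whole-brain",
) -> FingerprintResult:
    corr, _ = cross_correlation_matrix(database, targets, edge_mask)
    flags = _identification_flags(corr)
    return FingerprintResult(
        flags=flags,
        accuracy=float(flags.mean()),
        database_session=database_session,
        target_session=target_session,
        edge_set=edge_set,
    )


def run_all_combinations(
    fc_by_subject_session: dict[str, dict[str, FCMatrix]],
    edge_mask: np.ndarray | None = None,
    edge_set: str = "whole-brain",
    session_meta: dict[str, dict] | None = None,
) -> list[FingerprintResult]:
    """All ordered (database, target) session pairs, database != target.

    ``fc_by_subject_session`` maps subject -> session tag -> FCMatrix; every
    subject must have the same session tags.  ``session_meta`` optionally maps
    a session tag to {"day": ..., "encoding": ...} for annotation.
    """
    subjects = sorted(fc_by_subject_session)
    sessions = sorted(fc_by_subject_session[subjects[0]])
    missing = {
        s: sorted(set(sessions) - set(fc_by_subject_session[s]))
        for s in subjects
        if set(fc_by_subject_session[s]) != set(sessions)
    }
    if missing:
        raise ValueError(f"missing sessions for subjects: {missing}")
    if edge_mask is None:
        n_rois = fc_by_subject_session[subjects[0]][sessions[0]].n_rois
        edge_mask = whole_brain_mask(n_rois)
    results = []
    for db_sess, tg_sess in itertools.permutations(sessions, 2):
        database = {s: fc_by_subject_session[s][db_sess] for s in subjects}
        targets = {s: fc_by_subject_session[s][tg_sess] for s in subjects}
        res = identification_accuracy(
            database, targets, edge_mask, db_sess, tg_sess, edge_set
        )
        if session_meta:
            res.same_day = session_meta[db_sess].get("day") == session_meta[tg_sess].get("day")
            res.same_encoding = (
                session_meta[db_sess].get("encoding") == session_meta[tg_sess].get("encoding")
            )
        results.append(res)
    return results


def permutation_null(
    fc_by_subject_session: dict[str, dict[str, FCMatrix]],
    n_perm: int,
    seed: int,
    edge_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Null identification accuracies with database subject identity permuted.

    The target-database correlation matrix for each session pair is computed
    once; each permutation only relabels the database, so a "success" is an
    argmax landing on the permuted identity.  Returns one mean accuracy (over
    session pairs and subjects) per permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    subjects = sorted(fc_by_subject_session)
    sessions = sorted(fc_by_subject_session[subjects[0]])
    if edge_mask is None:
        n_rois = fc_by_subject_session[subjects[0]][sessions[0]].n_rois
        edge_mask = whole_brain_mask(n_rois)
    corr_matrices = []
    for db_sess, tg_sess in itertools.permutations(sessions, 2):
        database = {s: fc_by_subject_session[s][db_sess] for s in subjects}
        targets = {s: fc_by_subject_session[s][tg_sess] for s in subjects}
        corr, _ = cross_correlation_matrix(database, targets, edge_mask)
        corr_matrices.append(corr)
    rng = np.random.default_rng(seed)
    n = len(subjects)
    null = np.empty(n_perm)
    argmaxes = [np.argmax(c, axis=1) for c in corr_matrices]
    for p in range(n_perm):
        accs = []
        for corr, am in zip(corr_matrices, argmaxes):
            perm = rng.permutation(n)  # database entry j relabelled perm[j]
            accs.append(float(np.mean(perm[am] == np.arange(n))))
        null[p] = float(np.mean(accs))
    return null
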