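"""Evaluation metrics for reconstructed structures.

Distance-space metrics (DPCC, DSCC, DRMSE) compare two aligned vectors of
pairwise bead distances — typically a model's distances against the wish
distances derived from the input contact matrix, or against a reference
structure's distances. Being functions of distances only, they are invariant
under any rigid motion of either structure.

Structure-space comparison uses least-squares superposition (Kabsch, with
optional uniform scaling and reflection: distance-only reconstruction fixes
neither the global scale nor the handedness of a model) followed by the
TM-score, a length-normalized similarity in (0, 1] where 1 means identical
shapes, ~0.17 is the random-pair baseline, and >0.5 indicates broadly the
same fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .hic_io import Structure, ValidationError

__all__ = [
    "EvaluationReport",
    "pairwise_distances",
    "dpcc",
    "dscc",
    "drmse",
    "kabsch_superpose",
    "tm_score",
    "evaluate_distances",
]


@dataclass
class EvaluationReport:
    """Bundle of evaluation metrics; ``tm_score`` is None when no reference
    structure exists (distance-only evaluation)."""

    dpcc: float
    dscc: float
    drmse: float
    tm_score: Optional[float] = None


def pairwise_distances(structure: Structure, pair_set=None) -> np.ndarray:
    """Euclidean bead-bead distances in lexicographic (i, j) order.

    ``pair_set`` restricts to the given ``(i_indices, j_indices)`` pairs
    (e.g. a WishDistances ``pair_set``); by default all i < j pairs.
    """
    coords = structure.coords
    n = structure.n_beads
    if pair_set is None:
        i, j = np.triu_indices(n, k=1)
    else:
        i, j = (np.asarray(x, dtype=int) for x in pair_set)
        if i.size and (i.min() < 0 or max(i.max(), j.max()) >= n):
            raise ValidationError("pair index out of range")
    diff = coords[i] - coords[j]
    return np.sqrt(np.einsum("pc,pc->p", diff, diff))


def _check_vectors(d, D, min_len):
    d = np.asarray(d, dtype=float)
    D = np.asarray(D, dtype=float)
    if d.shape != D.shape or d.ndim != 1:
        raise ValidationError(f"distance vectors misaligned: {d.shape} vs {D.shape}")
    if d.size < min_len:
        raise ValidationError(f"need at least {min_len} distances, got {d.size}")
    return d, D


def dpcc(d, D) -> float:
    """Distance Pearson correlation coefficient; higher is better."""
    d, D = _check_vectors(d, D, 3)
    if np.ptp(d) == 0 or np.ptp(D) == 0:
        raise ValidationError("correlation undefined for zero-variance distances")
    return float(stats.pearsonr(d, D).statistic)


def dscc(d, D) -> float:
    """Distance Spearman correlation (Pearson on midranks); higher is better."""
    d, D = _check_vectors(d, D, 3)
    if np.ptp(d) == 0 or np.ptp(D) == 0:
        raise ValidationError("correlation undefined for all-tied distances")
    return float(stats.spearmanr(d, D).statistic)


def drmse(d, D) -> float:
    """Root mean squared difference between two distance vectors."""
    d, D = _check_vectors(d, D, 1)
    return float(np.sqrt(np.mean((d - D) ** 2)))


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    allow_scaling: bool = True,
    allow_reflection: bool = True,
) -> tuple[Structure, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Centroids are removed, the optimal rotation found by SVD, and optionally
    an optimal uniform scale applied. With ``allow_reflection`` the optimal
    improper rotation (mirror) is used whenever it fits better — both are
    enabled by default because a structure reconstructed from distances
    alone has arbitrary scale and chirality.

    Returns the transformed copy of ``mobile`` and the RMSD to ``reference``.
    """
    X = np.asarray(mobile.coords, dtype=float)
    Y = np.asarray(reference.coords, dtype=float)
    if X.shape != Y.shape:
        raise ValidationError("structures must have equal bead counts")
    n = X.shape[0]
    if n < 3:
        raise ValidationError("superposition needs at least 3 beads")

    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(U @ Vt)
    D = np.ones(3)
    if det < 0 and not allow_reflection:
        D[-1] = -1.0  # force a proper rotation
    R = U @ np.diag(D) @ Vt

    if allow_scaling:
        varx = (X0**2).sum()
        scale = float((S @ D) / varx) if varx > 0 else 1.0
    else:
        scale = 1.0
    fitted = scale * X0 @ R + yc
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Y) ** 2, axis=1))))
    return Structure(fitted, labels=list(mobile.labels)), rmsd


def _d0(length: int) -> float:
    # standard length-dependent TM-score normalization, floored at 0.5
    return max(0.5, 1.24 * np.cbrt(length - 15.0) - 1.8)


def tm_score(model: Structure, reference: Structure) -> float:
    """TM-score of ``model`` against ``reference`` after internal superposition.

    All beads are treated as aligned (L_ali = L_target = L):

        TM = (1/L) * sum_i 1 / (1 + (d_i / d0(L))^2),

    with per-bead deviations d_i after scaling+reflection-aware Kabsch
    superposition and d0(L) = max(0.5, 1.24*(L-15)^(1/3) - 1.8). A score of
    1 means identical shapes; values are in (0, 1].
    """
    if model.n_beads != reference.n_beads:
        raise ValidationError("structures must have equal bead counts")
    fitted, _ = kabsch_superpose(model, reference)
    dev = np.sqrt(np.sum((fitted.coords - reference.coords) ** 2, axis=1))
    d0 = _d0(model.n_beads)
    return float(np.mean(1.0 / (1.0 + (dev / d0) ** 2)))


def evaluate_distances(
    model_d,
    reference_d,
    model: Optional[Structure] = None,
    reference: Optional[Structure] = None,
) -> EvaluationReport:
    """Assemble an EvaluationReport from aligned distance vectors, adding
    TM-score when both structures are given."""
    tm = tm_score(model, reference) if model is not None and reference is not None else None
    return EvaluationReport(
        dpcc=dpcc(model_d, reference_d),
        dscc=dscc(model_d, reference_d),
        drmse=drmse(model_d, reference_d),
        tm_score=tm,
    )
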