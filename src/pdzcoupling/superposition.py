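"""Least-squares rigid-body superposition (Kabsch) and pairwise RMSD."""

from __future__ import annotations

import dataclasses

import numpy as np

from .structure_io import CA_SELECTION, Selection, StructureModel, select

__all__ = ["SuperpositionResult", "kabsch", "apply_transform", "pairwise_rmsd"]


@dataclasses.dataclass
class SuperpositionResult:
    """Optimal proper rotation + translation mapping X onto Y.

    The transform is ``x -> rotation @ x + translation``; ``rmsd`` is the
    root-mean-square paired-atom deviation after the transform.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def kabsch(X: np.ndarray, Y: np.ndarray, weights: np.ndarray | None = None) -> SuperpositionResult:
    """Optimal superposition of paired coordinates X onto Y.

    Solves the weighted orthogonal Procrustes problem restricted to proper
    rotations (reflections excluded), via SVD of the weighted covariance.
    Requires >= 3 non-collinear pairs.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must be matching (N, 3) arrays")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    xbar = w @ X
    ybar = w @ Y
    Xc = X - xbar
    Yc = Y - ybar
    # collinearity: centered X (or Y) of rank < 2 leaves the rotation unidentified
    if np.linalg.matrix_rank(Xc, tol=1e-8) < 2 or np.linalg.matrix_rank(Yc, tol=1e-8) < 2:
        raise ValueError("paired coordinates are collinear; superposition is degenerate")

    H = (Xc * w[:, None]).T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ybar - R @ xbar
    diff = (X @ R.T + t) - Y
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_transform(result: SuperpositionResult, coords: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def pairwise_rmsd(models: list[StructureModel], sel: Selection = CA_SELECTION,
                  min_shared: int = 3) -> np.ndarray:
    """Symmetric Cα RMSD matrix over structure models.

    Residues are paired by (chain, residue index); residues unresolved in
    either model of a pair are dropped pairwise. Pairs sharing fewer than
    ``min_shared`` residues are flagged NaN.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    keyed: list[dict[tuple[str, int], np.ndarray]] = []
    for m in models:
        idx = select(m, sel)
        keyed.append({m.atoms[i].residue_key(): m.atoms[i].coords for i in idx})
    n = len(models)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            shared = sorted(set(keyed[a]) & set(keyed[b]))
            if len(shared) < min_shared:
                out[a, b] = out[b, a] = np.nan
                continue
            X = np.array([keyed[a][k] for k in shared])
            Y = np.array([keyed[b][k] for k in shared])
            out[a, b] = out[b, a] = kabsch(X, Y).rmsd
    return out
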