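"""Dynamical cross-correlation and sector decomposition.

The dynamical cross-correlation matrix (DCCM) over Ca displacement vectors,

    raw_ij = < dr_i(t) . dr_j(t) >_t,   dr = r - <r>,

summarises which residues move together; its normalised form is the Pearson
correlation of the displacement series. "Dynamical sectors" — clusters of
residues with mutually coupled motion — are extracted statistical-coupling-
analysis style: eigendecomposition of the coupling matrix, retention of
modes above a shuffle-null significance threshold (or a fixed count),
rotation of the retained eigenvectors by independent component analysis,
assignment of residues to their dominant component by loading magnitude,
and finally merging of components that remain strongly coupled to each
other into sectors.

The shuffle null destroys inter-residue coupling while preserving each
residue's displacement distribution: every residue's frame series is
permuted independently and the coupling matrix recomputed; a mode is
significant when its eigenvalue exceeds the largest eigenvalue seen across
``n_null`` such surrogates.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA

from .structure_io import CA_SELECTION, Selection, StructureModel, Trajectory, select
from .trajectory_analysis import superpose_frames

__all__ = ["CouplingMatrix", "SectorDecomposition", "dccm", "merge", "spectral_sectors"]


@dataclasses.dataclass
class CouplingMatrix:
    """n x n residue coupling matrix.

    ``mode`` is "raw" (displacement covariance, A^2) or "normalized"
    (dimensionless Pearson correlation in [-1, 1]). ``displacements`` holds
    the superposed displacement series (F, n, 3) the matrix was computed
    from, enabling the shuffle null in :func:`spectral_sectors`.
    """

    labels: list[str]
    values: np.ndarray
    mode: str
    displacements: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("coupling matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("coupling matrix must be symmetric")
        self.values = v


@dataclasses.dataclass
class SectorDecomposition:
    eigenvalues: np.ndarray
    n_retained: int
    components: np.ndarray            # (n_retained, n) IC loading vectors
    component_members: list[list[str]]
    sector_members: dict[str, list[str]]
    thresholds: dict[str, float]


def _raw_covariance(disp: np.ndarray) -> np.ndarray:
    """raw_ij = mean_t dr_i(t).dr_j(t) for displacement stack (F, n, 3)."""
    F = disp.shape[0]
    return np.einsum("fia,fja->ij", disp, disp) / F


def _normalize(raw: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(raw))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = raw / np.outer(d, d)
    out[~np.isfinite(out)] = 0.0
    np.fill_diagonal(out, np.where(d > 0, 1.0, 0.0))
    return out


def dccm(traj: Trajectory, sel: Selection = CA_SELECTION, mode: str = "normalized",
         fit: bool = True) -> CouplingMatrix:
    """Dynamical cross-correlation matrix over selected atoms (default Ca).

    Displacements are taken about the per-atom trajectory mean after
    optional iterative superposition onto the mean structure (as in RMSF);
    couplings are full 3-D dot products. Normalised entries where either
    variance vanishes are defined as 0.
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM needs at least two frames")
    if mode not in ("raw", "normalized"):
        raise ValueError(f"unknown mode {mode!r}")
    idx = select(traj, sel)
    if not idx:
        raise ValueError("DCCM selection is empty")
    frames = superpose_frames(traj, sel) if fit else traj.frames
    coords = frames[:, idx]
    disp = coords - coords.mean(axis=0)
    raw = _raw_covariance(disp)
    values = raw if mode == "raw" else _normalize(raw)
    labels = []
    for i in idx:
        a = traj.topology.atoms[i]
        labels.append(f"{a.chain_id}:{a.residue_index}:{a.residue_name}")
    return CouplingMatrix(labels=labels, values=values, mode=mode, displacements=disp)


def merge(trajs: Sequence[Trajectory]) -> Trajectory:
    """Concatenate replicate trajectories sharing one topology."""
    if not trajs:
        raise ValueError("nothing to merge")
    sig0 = trajs[0].topology.atom_signature()
    for i, t in enumerate(trajs[1:], start=2):
        if t.topology.atom_signature() != sig0:
            raise ValueError(f"replicate {i}: topology differs from replicate 1")
    return Trajectory(trajs[0].topology, np.concatenate([t.frames for t in trajs]),
                      frame_spacing=trajs[0].frame_spacing)


def _null_max_eigenvalue(disp: np.ndarray, mode: str, n_null: int,
                         rng: np.random.Generator) -> float:
    F, n, _ = disp.shape
    best = -np.inf
    for _ in range(n_null):
        perm = np.empty_like(disp)
        for i in range(n):
            perm[:, i] = disp[rng.permutation(F), i]
        raw = _raw_covariance(perm - perm.mean(axis=0))
        m = raw if mode == "raw" else _normalize(raw)
        best = max(best, float(np.linalg.eigvalsh(m).max()))
    return best


def _rotate_ica(V: np.ndarray, k: int, rng: np.random.Generator,
                n_restarts: int = 5) -> np.ndarray:
    """Rotate retained eigenvectors into independent components.

    Sector loading patterns are one-sided spikes (a minority of residues
    with large same-sign loadings), i.e. strongly *skewed*; the symmetric
    mixture of two sectors is bimodal and can score higher on kurtosis-type
    contrasts. FastICA therefore runs with the cubic contrast and several
    restarts, keeping the rotation whose loadings are most skewed.
    """
    best_S, best_score = None, -np.inf
    for _ in range(n_restarts):
        ica = FastICA(n_components=k, random_state=int(rng.integers(2**31 - 1)),
                      whiten="unit-variance", fun="cube", max_iter=2000, tol=1e-7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S_try = ica.fit_transform(V)
        score = float(np.abs(stats.skew(S_try, axis=0)).sum())
        if score > best_score:
            best_S, best_score = S_try, score
    assert best_S is not None
    return best_S


def spectral_sectors(cm: CouplingMatrix, n_components: int | str = "auto",
                     loading_quantile: float = 0.9, null: str = "shuffle",
                     n_null: int = 100, seed: int | None = None,
                     merge_ratio: float = 0.5) -> SectorDecomposition:
    """Decompose a coupling matrix into independent components and sectors.

    Modes retained are either a fixed ``n_components`` or, with "auto",
    those whose eigenvalue exceeds the largest eigenvalue across ``n_null``
    shuffle surrogates (requires the displacement series on ``cm``).
    Retained eigenvectors are rotated by FastICA; a residue joins the
    component of its largest |loading| when that loading reaches the
    ``loading_quantile`` quantile of all pooled |loadings|. Components whose
    member sets remain strongly coupled (mean inter-component |c_ij| above
    both the off-diagonal median and ``merge_ratio`` times the geometric
    mean of the intra-component couplings) are merged into one sector.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    C = cm.values
    n = C.shape[0]
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    thresholds: dict[str, float] = {"loading_quantile": loading_quantile,
                                    "merge_ratio": merge_ratio}
    if n_components == "auto":
        if null != "shuffle":
            raise ValueError(f"unknown null model {null!r}")
        if cm.displacements is None:
            raise ValueError("auto mode selection needs the displacement series "
                             "(compute the matrix with dccm())")
        lam_null = _null_max_eigenvalue(cm.displacements, cm.mode, n_null, rng)
        thresholds["null_max_eigenvalue"] = lam_null
        k = int(np.sum(eigval > lam_null))
    else:
        k = int(n_components)
        if not 1 <= k <= n:
            raise ValueError("n_components out of range")

    empty = SectorDecomposition(eigenvalues=eigval, n_retained=0,
                                components=np.empty((0, n)), component_members=[],
                                sector_members={}, thresholds=thresholds)
    if k == 0:
        return empty

    V = eigvec[:, :k]
    if k >= 2:
        S = _rotate_ica(V, k, rng)               # (n, k) IC loadings
    else:
        S = V.copy()
    # order by coupling energy of each component direction; fix signs
    energy = []
    for c in range(k):
        s = S[:, c]
        energy.append(float(s @ C @ s) / float(s @ s))
    comp_order = np.argsort(energy)[::-1]
    S = S[:, comp_order]
    for c in range(k):
        if S[np.argmax(np.abs(S[:, c])), c] < 0:
            S[:, c] *= -1

    absS = np.abs(S)
    tau = float(np.quantile(absS, loading_quantile))
    thresholds["loading_cutoff"] = tau
    members: list[list[int]] = [[] for _ in range(k)]
    for i in range(n):
        c = int(np.argmax(absS[i]))
        if absS[i, c] >= tau:
            members[c].append(i)

    # merge strongly inter-coupled components into sectors (union-find)
    absC = np.abs(C)
    off = absC[~np.eye(n, dtype=bool)]
    med = float(np.median(off)) if off.size else 0.0
    thresholds["matrix_median"] = med

    def intra(ms: list[int]) -> float:
        if len(ms) < 2:
            return float(np.mean(np.abs(np.diag(C)[ms]))) if ms else 0.0
        sub = absC[np.ix_(ms, ms)]
        return float(sub[~np.eye(len(ms), dtype=bool)].mean())

    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(k):
        for b in range(a + 1, k):
            if not members[a] or not members[b]:
                continue
            inter = float(absC[np.ix_(members[a], members[b])].mean())
            bar = max(med, merge_ratio * np.sqrt(max(intra(members[a]), 0.0)
                                                 * max(intra(members[b]), 0.0)))
            if inter > bar:
                parent[find(b)] = find(a)

    groups: dict[int, list[int]] = {}
    for c in range(k):
        if members[c]:
            groups.setdefault(find(c), []).extend(members[c])
    sector_members = {f"sector_{s + 1}": sorted({cm.labels[i] for i in idxs},
                                                key=lambda l: cm.labels.index(l))
                      for s, idxs in enumerate(groups.values())}
    return SectorDecomposition(
        eigenvalues=eigval, n_retained=k, components=S.T,
        component_members=[[cm.labels[i] for i in m] for m in members],
        sector_members=sector_members, thresholds=thresholds)
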