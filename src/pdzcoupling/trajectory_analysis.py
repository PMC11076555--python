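"""Per-residue trajectory statistics.

Implements the descriptive statistics used to characterise peptide-PDZ
complexes in simulation: root-mean-square fluctuation (RMSF) about the
trajectory mean, peptide-domain interaction propensity at a distance
cutoff, backbone-dihedral secondary-structure propensity, and residue-wise
deviation between two conformers after global superposition.

Conventions
-----------
* Interaction propensity of a (peptide residue, domain residue) pair is the
  fraction of frames in which the minimum distance between the peptide
  residue's side-chain heavy atoms and any heavy atom of the domain residue
  is strictly below the cutoff (default 4 Angstrom). Glycine contributes its
  CA as side-chain proxy.
* A residue is counted as beta-strand in a frame when its backbone dihedrals
  fall in phi in [-180, -45] and psi in [45, 180] or [-180, -120] degrees.
  Chain-terminal residues (no phi or no psi) are reported as NaN, not 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import (CA_SELECTION, Selection, StructureModel, Trajectory,
                           select)
from .superposition import apply_transform, kabsch

__all__ = [
    "ResidueProfile",
    "PropensityMatrix",
    "superpose_frames",
    "rmsf",
    "interaction_propensity",
    "ss_propensity",
    "residue_deviation",
    "dihedral",
]


@dataclasses.dataclass
class ResidueProfile:
    labels: list[str]
    values: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.values.tolist()))


@dataclasses.dataclass
class PropensityMatrix:
    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    cutoff: float


def _residue_label(model: StructureModel, key: tuple[str, int]) -> str:
    resname = next(a.residue_name for a in model.atoms if a.residue_key() == key)
    return f"{key[0]}:{key[1]}:{resname}"


def superpose_frames(traj: Trajectory, sel: Selection = CA_SELECTION,
                     n_passes: int = 2) -> np.ndarray:
    """Superpose every frame onto the iteratively refined mean structure.

    The mean over frames is itself frame-dependent, so the fit is iterated:
    align all frames to the current mean, recompute the mean, repeat
    (two passes by default). The Kabsch fit uses the selected atoms; the
    resulting rigid transform is applied to all atoms of the frame.
    """
    idx = select(traj, sel)
    if not idx:
        raise ValueError("superposition selection is empty")
    frames = traj.frames.copy()
    for _ in range(n_passes):
        mean = frames[:, idx].mean(axis=0)
        for f in range(frames.shape[0]):
            res = kabsch(frames[f, idx], mean)
            frames[f] = apply_transform(res, frames[f])
    return frames


def rmsf(traj: Trajectory, sel: Selection = CA_SELECTION, fit: bool = True) -> ResidueProfile:
    """Root-mean-square fluctuation of selected atoms about their mean.

    RMSF_i = sqrt(mean_t |r_i(t) - rbar_i|^2), computed after optional
    rigid-body superposition of every frame onto the mean structure. Atoms
    are grouped by residue; a residue's value is the RMS over its selected
    atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    idx = select(traj, sel)
    if not idx:
        raise ValueError("RMSF selection is empty")
    frames = superpose_frames(traj, sel) if fit else traj.frames
    coords = frames[:, idx]                       # (F, m, 3)
    disp = coords - coords.mean(axis=0)
    msf = np.einsum("fij,fij->i", disp, disp) / coords.shape[0]

    keys: list[tuple[str, int]] = []
    per_res: dict[tuple[str, int], list[float]] = {}
    for pos, i in enumerate(idx):
        k = traj.topology.atoms[i].residue_key()
        per_res.setdefault(k, []).append(msf[pos])
        if k not in keys:
            keys.append(k)
    labels = [_residue_label(traj.topology, k) for k in keys]
    values = np.array([np.sqrt(np.mean(per_res[k])) for k in keys])
    return ResidueProfile(labels=labels, values=values)


def _residue_atom_groups(traj: Trajectory, sel: Selection,
                         role: str) -> tuple[list[tuple[str, int]], list[list[int]]]:
    idx = select(traj, sel)
    groups: dict[tuple[str, int], list[int]] = {}
    order: list[tuple[str, int]] = []
    for i in idx:
        k = traj.topology.atoms[i].residue_key()
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(i)
    # residues inside the selection scope that contributed no atom at all
    scope = dataclasses.replace(sel, atom_names=None, sidechain=False)
    for i in select(traj, scope):
        k = traj.topology.atoms[i].residue_key()
        if k not in groups:
            raise ValueError(f"{role} residue {k} has no qualifying atoms")
    return order, [groups[k] for k in order]


def interaction_propensity(traj: Trajectory, peptide_residues: Selection,
                           domain_residues: Selection, cutoff: float = 4.0,
                           row_labels: list[str] | None = None) -> PropensityMatrix:
    """Fraction of frames with a sub-cutoff peptide/domain residue contact.

    Cell (i, j) counts frames where min distance between side-chain heavy
    atoms of peptide residue i and any heavy atom of domain residue j is
    strictly below ``cutoff``. Strict inequality: a pair exactly at the
    cutoff is not a contact.
    """
    pep_sel = dataclasses.replace(peptide_residues, sidechain=True)
    pep_keys, pep_groups = _residue_atom_groups(traj, pep_sel, "peptide")
    dom_keys, dom_groups = _residue_atom_groups(traj, domain_residues, "domain")
    if set(k for g in pep_groups for k in g) & set(k for g in dom_groups for k in g):
        raise ValueError("peptide and domain selections must be disjoint")

    F = traj.n_frames
    counts = np.zeros((len(pep_keys), len(dom_keys)), dtype=int)
    for f in range(F):
        frame = traj.frames[f]
        for i, gi in enumerate(pep_groups):
            pc = frame[gi]
            for j, gj in enumerate(dom_groups):
                if cdist(pc, frame[gj]).min() < cutoff:
                    counts[i, j] += 1
    rows = row_labels or [_residue_label(traj.topology, k) for k in pep_keys]
    cols = [_residue_label(traj.topology, k) for k in dom_keys]
    return PropensityMatrix(row_labels=rows, col_labels=cols,
                            values=counts / F, cutoff=cutoff)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle(s) in degrees; inputs broadcast over leading axes."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


_BETA_PHI = (-180.0, -45.0)
_BETA_PSI = ((45.0, 180.0), (-180.0, -120.0))


def _is_beta(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    in_phi = (phi >= _BETA_PHI[0]) & (phi <= _BETA_PHI[1])
    in_psi = np.zeros_like(psi, dtype=bool)
    for lo, hi in _BETA_PSI:
        in_psi |= (psi >= lo) & (psi <= hi)
    return in_phi & in_psi


def ss_propensity(traj: Trajectory, residues: Selection | None = None,
                  ss_class: str = "beta") -> ResidueProfile:
    """Fraction of frames each residue spends in the beta-strand region.

    Backbone dihedrals phi/psi are computed per frame from N, CA, C atoms.
    Residues lacking a neighbour (chain termini) have no phi or psi and are
    reported NaN.
    """
    if ss_class != "beta":
        raise ValueError(f"unsupported secondary-structure class {ss_class!r}")
    scope = residues or Selection()
    bb: dict[tuple[str, int], dict[str, int]] = {}
    order: list[tuple[str, int]] = []
    for i, a in enumerate(traj.topology.atoms):
        k = a.residue_key()
        if a.name in ("N", "CA", "C"):
            bb.setdefault(k, {})[a.name] = i
            if k not in order:
                order.append(k)
    wanted = []
    scope_no_names = dataclasses.replace(scope, atom_names=None, sidechain=False)
    scope_idx = {traj.topology.atoms[i].residue_key() for i in select(traj, scope_no_names)}
    for k in order:
        if k in scope_idx:
            wanted.append(k)
    for k in wanted:
        if set(bb.get(k, {})) != {"N", "CA", "C"}:
            raise ValueError(f"residue {k} lacks backbone atoms for dihedral computation")

    labels, values = [], []
    pos = {k: n for n, k in enumerate(order)}
    for k in wanted:
        labels.append(_residue_label(traj.topology, k))
        n = pos[k]
        prev_k = order[n - 1] if n > 0 and order[n - 1][0] == k[0] else None
        next_k = order[n + 1] if n + 1 < len(order) and order[n + 1][0] == k[0] else None
        if prev_k is None or next_k is None or \
                "C" not in bb.get(prev_k, {}) or "N" not in bb.get(next_k, {}):
            values.append(np.nan)
            continue
        F = traj.frames
        phi = dihedral(F[:, bb[prev_k]["C"]], F[:, bb[k]["N"]],
                       F[:, bb[k]["CA"]], F[:, bb[k]["C"]])
        psi = dihedral(F[:, bb[k]["N"]], F[:, bb[k]["CA"]],
                       F[:, bb[k]["C"]], F[:, bb[next_k]["N"]])
        values.append(float(np.mean(_is_beta(phi, psi))))
    return ResidueProfile(labels=labels, values=np.array(values))


def residue_deviation(a: StructureModel, b: StructureModel,
                      pairing: dict[tuple[str, int], tuple[str, int]] | None = None) -> ResidueProfile:
    """Per-residue Cα displacement after global Cα superposition.

    Residues are paired by (chain, residue index) unless an explicit pairing
    map (keys in ``a``, values in ``b``) is given; the Kabsch fit uses all
    paired Cα atoms and the per-residue |delta r| of Cα is reported.
    """
    ca_a = {at.residue_key(): at.coords for at in a.atoms if at.name == "CA"}
    ca_b = {at.residue_key(): at.coords for at in b.atoms if at.name == "CA"}
    if pairing is None:
        pairing = {k: k for k in ca_a if k in ca_b}
    pairs = [(ka, kb) for ka, kb in pairing.items() if ka in ca_a and kb in ca_b]
    if not pairs:
        raise ValueError("empty residue pairing")
    X = np.array([ca_a[ka] for ka, _ in pairs])
    Y = np.array([ca_b[kb] for _, kb in pairs])
    res = kabsch(X, Y)
    dev = np.linalg.norm(apply_transform(res, X) - Y, axis=1)
    labels = [_residue_label(a, ka) for ka, _ in pairs]
    return ResidueProfile(labels=labels, values=dev)
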