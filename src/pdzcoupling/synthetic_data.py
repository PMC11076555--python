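"""Ground-truth-bearing synthetic inputs for every pipeline stage.

Real inputs to these analyses are MD trajectories and wet-lab measurements;
this module generates statistically controlled stand-ins with *known*
ground truth, so every estimator in the package can be validated by
parameter recovery:

* Ca trajectories drawn from a planted displacement covariance whose
  correlated residue blocks are the sectors the coupling analysis should
  recover. Displacements are drawn i.i.d. across frames and independently
  per axis, so the normalised DCCM converges exactly to the correlation
  matrix of the planted covariance.
* Peptide-domain complex trajectories with scripted sub-cutoff contact
  events, so interaction propensities are exact frame counts by
  construction.
* Titration series and exchange traces from the binding models with
  multiplicative Gaussian noise and planted Kd / rate constants.
* Ortholog-like sequence sets embedding a motif at a recorded position
  under a per-column conservation level.

Every generator is reproducible given its seed, and returns its ground
truth alongside the data.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .binding_fits import ExchangeTrace, TitrationSeries, bound_fraction
from .sequence_motif import AMINO_ACIDS, ProteinSequence
from .structure_io import ONE_TO_THREE, Atom, StructureModel, Trajectory

__all__ = [
    "CovarianceBlock",
    "planted_sector_covariance",
    "gen_trajectory",
    "build_chain_structure",
    "build_backbone_model",
    "gen_complex_trajectory",
    "gen_titration",
    "gen_exchange_trace",
    "gen_ortholog_set",
]

_AA_LIST = sorted(AMINO_ACIDS)


@dataclasses.dataclass(frozen=True)
class CovarianceBlock:
    """A correlated residue block: 0-based member indices and the
    intra-block correlation."""

    members: tuple[int, ...]
    rho: float


def planted_sector_covariance(n_residues: int,
                              blocks: Sequence[CovarianceBlock] = (),
                              variances: float | Sequence[float] = 1.0) -> np.ndarray:
    """Block covariance: rho*sqrt(v_i v_j) within a block, 0 elsewhere.

    Blocks must be disjoint. If clipping is needed to restore positive
    semi-definiteness (possible for negative rho), negative eigenvalues are
    clipped to zero.
    """
    var = np.broadcast_to(np.asarray(variances, dtype=float), (n_residues,)).copy()
    if np.any(var <= 0):
        raise ValueError("variances must be positive")
    seen: set[int] = set()
    for b in blocks:
        ms = set(b.members)
        if ms & seen:
            raise ValueError("covariance blocks must be disjoint")
        if not ms <= set(range(n_residues)):
            raise ValueError("block member index out of range")
        seen |= ms
    cov = np.diag(var)
    sd = np.sqrt(var)
    for b in blocks:
        for i in b.members:
            for j in b.members:
                if i != j:
                    cov[i, j] = b.rho * sd[i] * sd[j]
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10:
        eigval, eigvec = np.linalg.eigh(cov)
        cov = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
    return cov


def gen_trajectory(cov: np.ndarray, n_frames: int, seed: int | None,
                   base: StructureModel) -> Trajectory:
    """Gaussian Ca trajectory with planted displacement covariance.

    For each Cartesian axis independently, ``n_frames`` vectors are drawn
    from N(0, cov) and added to the base coordinates, so the expected raw
    DCCM is 3*cov and the normalised DCCM converges to corr(cov).
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if cov.shape != (n, n):
        raise ValueError("covariance must be square")
    if len(base) != n:
        raise ValueError(f"base structure has {len(base)} atoms, covariance is {n}x{n}")
    rng = np.random.default_rng(seed)
    disp = np.stack([rng.multivariate_normal(np.zeros(n), cov, size=n_frames,
                                             method="eigh")
                     for _ in range(3)], axis=-1)      # (F, n, 3)
    return Trajectory(base, base.coords[None, :, :] + disp)


def build_chain_structure(sequence: str, mode: str = "ca-trace",
                          chain_id: str = "A", start_index: int = 1,
                          origin: np.ndarray | None = None) -> StructureModel:
    """Ca trace at 3.8 A spacing along a gently curving path.

    "pseudo-sidechain" mode adds one CB atom 1.5 A off-axis per non-glycine
    residue, giving every residue a side-chain proxy for contact fixtures.
    """
    sequence = sequence.upper()
    if mode not in ("ca-trace", "pseudo-sidechain"):
        raise ValueError(f"unknown mode {mode!r}")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)}")
    atoms: list[Atom] = []
    pos = np.zeros(3) if origin is None else np.asarray(origin, dtype=float).copy()
    for i, aa in enumerate(sequence):
        resname = ONE_TO_THREE[aa]
        resid = start_index + i
        atoms.append(Atom("CA", "C", resid, resname, chain_id, pos.copy()))
        if mode == "pseudo-sidechain" and aa != "G":
            perp = np.array([-np.sin(0.05 * i), np.cos(0.05 * i), 0.0])
            perp /= np.linalg.norm(perp)
            atoms.append(Atom("CB", "C", resid, resname, chain_id, pos + 1.5 * perp))
        step = np.array([np.cos(0.05 * i), np.sin(0.05 * i), 0.15])
        pos = pos + 3.8 * step / np.linalg.norm(step)
    return StructureModel(atoms)


# internal-coordinate backbone geometry (lengths in A, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 117.2, 121.7


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
           angle: float, torsion: float) -> np.ndarray:
    """NeRF placement of atom d from predecessors a-b-c."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(ang),
                   bond * np.sin(ang) * np.cos(tor),
                   bond * np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone_model(sequence: str, phi: float | Sequence[float],
                         psi: float | Sequence[float], chain_id: str = "A") -> StructureModel:
    """Backbone (N, CA, C) chain with prescribed phi/psi dihedrals.

    Built atom-by-atom from ideal internal coordinates with omega fixed at
    180 degrees; useful as a secondary-structure-propensity fixture where
    the Ramachandran angles are known exactly.
    """
    sequence = sequence.upper()
    nres = len(sequence)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (nres,))
    psi_arr = np.broadcast_to(np.asarray(psi, dtype=float), (nres,))
    coords: list[np.ndarray] = [
        np.array([0.0, 0.0, 0.0]),                       # N1
        np.array([_B_N_CA, 0.0, 0.0]),                   # CA1
    ]
    ang = np.radians(_A_N_CA_C)
    coords.append(coords[1] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0]))  # C1
    for i in range(1, nres):
        n_i = _place(coords[-3], coords[-2], coords[-1], _B_C_N, _A_CA_C_N, psi_arr[i - 1])
        ca_i = _place(coords[-2], coords[-1], n_i, _B_N_CA, _A_C_N_CA, 180.0)
        c_i = _place(coords[-1], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi_arr[i])
        coords.extend([n_i, ca_i, c_i])
    atoms = []
    for i, aa in enumerate(sequence):
        resname = ONE_TO_THREE[aa]
        for name, xyz in zip(("N", "CA", "C"), coords[3 * i:3 * i + 3]):
            atoms.append(Atom(name, name[0], i + 1, resname, chain_id, xyz))
    return StructureModel(atoms)


def gen_complex_trajectory(peptide: str, domain_size: int,
                           contact_schedule: Mapping[tuple[int, int], float],
                           cutoff: float = 4.0, n_frames: int = 10,
                           seed: int | None = None) -> tuple[Trajectory, dict]:
    """Peptide-domain trajectory with scripted contact fractions.

    ``contact_schedule`` maps (peptide residue index, domain residue index)
    — both 1-based — to the fraction of frames in contact. In a contact
    frame the peptide residue's side-chain proxy sits at 0.8*cutoff from
    the domain residue's CA; otherwise at 2*cutoff. Contact frames are
    chosen by seeded shuffle, so the realised propensity is exactly
    round(fraction * n_frames) / n_frames. A peptide residue scheduled
    against two domain residues in overlapping frames is infeasible and
    raises.
    """
    rng = np.random.default_rng(seed)
    peptide = peptide.upper()
    npep = len(peptide)
    for (pi, dj), frac in contact_schedule.items():
        if not (1 <= pi <= npep and 1 <= dj <= domain_size):
            raise ValueError(f"schedule pair ({pi}, {dj}) out of range")
        if not 0.0 <= frac <= 1.0:
            raise ValueError("contact fractions must lie in [0, 1]")

    spacing = max(10.0, 6.0 * cutoff)
    atoms: list[Atom] = []
    dom_ca: list[np.ndarray] = []
    for j in range(domain_size):
        p = np.array([j * spacing, 0.0, 0.0])
        dom_ca.append(p)
        atoms.append(Atom("CA", "C", j + 1, "ALA", "A", p))
        atoms.append(Atom("CB", "C", j + 1, "ALA", "A", p + np.array([0.0, 0.0, 1.5])))
    pep_proxy_idx: list[int] = []
    pep_rest: dict[int, int] = {}
    far = np.array([0.0, 1000.0, 0.0])
    for i, aa in enumerate(peptide):
        resname = ONE_TO_THREE[aa]
        base_p = far + np.array([i * spacing, 0.0, 0.0])
        if aa == "G":
            atoms.append(Atom("CA", "C", i + 1, resname, "B", base_p))
            pep_proxy_idx.append(len(atoms) - 1)
        else:
            atoms.append(Atom("CA", "C", i + 1, resname, "B",
                              base_p + np.array([0.0, 2.0, 0.0])))
            pep_rest[i] = len(atoms) - 1
            atoms.append(Atom("CB", "C", i + 1, resname, "B", base_p))
            pep_proxy_idx.append(len(atoms) - 1)
    topo = StructureModel(atoms)

    frames = np.tile(topo.coords, (n_frames, 1, 1))
    contact_frames: dict[tuple[int, int], set[int]] = {}
    by_residue: dict[int, list[int]] = {}
    for (pi, dj), frac in sorted(contact_schedule.items()):
        k = int(round(frac * n_frames))
        chosen = set(rng.permutation(n_frames)[:k].tolist())
        for other_dj in by_residue.get(pi, []):
            overlap = contact_frames[(pi, other_dj)] & chosen
            if overlap:
                raise ValueError(
                    f"peptide residue {pi} scheduled into overlapping contact "
                    f"frames {sorted(overlap)} with domain residues "
                    f"{other_dj} and {dj}; placements conflict")
        contact_frames[(pi, dj)] = chosen
        by_residue.setdefault(pi, []).append(dj)
    offset = np.array([0.0, 1.0, 0.0])
    for pi, partners in by_residue.items():
        proxy = pep_proxy_idx[pi - 1]
        for f in range(n_frames):
            dj_here = next((dj for dj in partners if f in contact_frames[(pi, dj)]), None)
            if dj_here is not None:
                pos = dom_ca[dj_here - 1] + 0.8 * cutoff * offset
            else:  # rest position: 2*cutoff off the first scheduled partner
                pos = dom_ca[partners[0] - 1] + 2.0 * cutoff * offset
            shift = pos - frames[f, proxy]
            frames[f, proxy] = pos
            if (pi - 1) in pep_rest:       # keep the residue's CA attached
                frames[f, pep_rest[pi - 1]] += shift
    ground_truth = {
        "contact_schedule": {f"{pi},{dj}": float(frac)
                             for (pi, dj), frac in contact_schedule.items()},
        "realized_fractions": {f"{pi},{dj}": len(fr) / n_frames
                               for (pi, dj), fr in contact_frames.items()},
        "cutoff": cutoff, "n_frames": n_frames, "seed": seed,
    }
    return Trajectory(topo, frames), ground_truth


def gen_titration(kd: float, concentrations: np.ndarray, receptor: float = 50e-9,
                  noise_frac: float = 0.02, seed: int | None = None,
                  unbound: float = 0.0, bound: float = 1.0) -> tuple[TitrationSeries, dict]:
    """Titration responses from the exact 1:1 model with multiplicative noise."""
    if kd <= 0 or receptor <= 0 or noise_frac < 0:
        raise ValueError("kd, receptor must be positive and noise_frac >= 0")
    rng = np.random.default_rng(seed)
    L = np.asarray(concentrations, dtype=float)
    clean = unbound + (bound - unbound) * bound_fraction(L, kd, receptor)
    noisy = clean * (1.0 + noise_frac * rng.standard_normal(L.shape))
    series = TitrationSeries(ligand_concentration=L, response=noisy,
                             receptor_concentration=receptor)
    return series, {"kd": kd, "receptor": receptor, "noise_frac": noise_frac,
                    "unbound": unbound, "bound": bound, "seed": seed}


def gen_exchange_trace(k: float, y0: float = 1.0, yinf: float = 0.2,
                       n_points: int = 200, t_max: float | None = None,
                       noise_frac: float = 0.01,
                       seed: int | None = None) -> tuple[ExchangeTrace, dict]:
    """Single-exponential fluorescence decay with multiplicative noise."""
    if k <= 0 or n_points < 5 or noise_frac < 0:
        raise ValueError("need k > 0, n_points >= 5, noise_frac >= 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max if t_max is not None else 5.0 / k, n_points)
    clean = yinf + (y0 - yinf) * np.exp(-k * t)
    noisy = clean * (1.0 + noise_frac * rng.standard_normal(t.shape))
    return (ExchangeTrace(time=t, signal=noisy),
            {"k": k, "y0": y0, "yinf": yinf, "noise_frac": noise_frac, "seed": seed})


def gen_ortholog_set(motif: str, n_seqs: int = 5, flank_len: int = 40,
                     motif_conservation: float = 1.0,
                     background_identity: float = 0.5,
                     seed: int | None = None) -> tuple[list[ProteinSequence], dict]:
    """Ortholog-like sequences embedding ``motif`` at a recorded position.

    A reference sequence (random flanks around the motif) is mutated per
    column: motif columns with probability 1 - motif_conservation, flank
    columns with probability 1 - background_identity.
    """
    motif = motif.upper()
    if not set(motif) <= AMINO_ACIDS:
        raise ValueError("motif contains invalid residues")
    if not (0.0 <= motif_conservation <= 1.0 and 0.0 <= background_identity <= 1.0):
        raise ValueError("conservation fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flank5 = "".join(rng.choice(_AA_LIST, size=flank_len))
    flank3 = "".join(rng.choice(_AA_LIST, size=flank_len))
    reference = flank5 + motif + flank3
    start = flank_len + 1      # 1-based motif start in every sequence
    seqs: list[ProteinSequence] = []
    for s in range(n_seqs):
        chars = []
        for c, ref_aa in enumerate(reference):
            in_motif = flank_len <= c < flank_len + len(motif)
            p_keep = motif_conservation if in_motif else background_identity
            if rng.random() < p_keep:
                chars.append(ref_aa)
            else:
                alternatives = [a for a in _AA_LIST if a != ref_aa]
                chars.append(alternatives[int(rng.integers(len(alternatives)))])
        seqs.append(ProteinSequence(id=f"ortholog_{s + 1}", residues="".join(chars)))
    return seqs, {"motif": motif, "motif_start": start,
                  "motif_end": start + len(motif) - 1,
                  "reference": reference, "seed": seed}
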