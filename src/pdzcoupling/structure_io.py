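"""Structures, trajectories and atom selections.

Coordinates are in Angstrom throughout; residue indices are 1-based as in
PDB files. Two trajectory containers are supported: multi-model PDB and the
package's plain-text "xyzt" format (header ``natoms nframes``, then per
frame one line per atom: ``name resid resname chain x y z``).

Insertion codes are not supported and raise on input; alternate locations
are resolved by highest occupancy (tie broken in favour of altloc 'A').
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sequence_motif import ProteinSequence

__all__ = [
    "Atom",
    "StructureModel",
    "Trajectory",
    "Selection",
    "BACKBONE_ATOMS",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "read_fasta",
    "write_fasta",
    "select",
]

#: Backbone heavy atoms; everything else heavy counts as side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclasses.dataclass
class Atom:
    """A single atom with PDB-style naming."""

    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            self.element = _guess_element(self.name)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        return ""
    # PDB convention: names like "1HB" or "HG1" are hydrogens
    first_alpha = next((c for c in stripped if c.isalpha()), "")
    if first_alpha.upper() == "H":
        return "H"
    return first_alpha.upper()


class StructureModel:
    """An ordered set of atoms forming one structural model."""

    def __init__(self, atoms: Sequence[Atom], model_id: int = 1,
                 allow_nonstandard: bool = False):
        atoms = list(atoms)
        seen: set[tuple[str, int, str]] = set()
        for a in atoms:
            if not allow_nonstandard and a.residue_name not in _STANDARD_RESIDUES:
                raise ValueError(
                    f"non-standard residue {a.residue_name!r}; pass "
                    f"allow_nonstandard=True to accept it")
            key = (a.chain_id, a.residue_index, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in model {model_id}")
            seen.add(key)
        self.atoms = atoms
        self.model_id = model_id

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(A, 3) coordinate array in atom order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [dataclasses.replace(a, coords=c) for a, c in zip(self.atoms, coords)]
        out = StructureModel.__new__(StructureModel)
        out.atoms = atoms
        out.model_id = self.model_id if model_id is None else model_id
        return out

    def atom_signature(self) -> list[tuple[str, int, str, str]]:
        return [(a.chain_id, a.residue_index, a.residue_name, a.name) for a in self.atoms]

    def residue_keys(self) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        for a in self.atoms:
            k = a.residue_key()
            if not out or out[-1] != k:
                if k in out:
                    raise ValueError(f"atoms of residue {k} are not contiguous")
                out.append(k)
        return out


class Trajectory:
    """Frames sharing one topology; frame coordinates in Angstrom."""

    def __init__(self, topology: StructureModel, frames: np.ndarray,
                 frame_spacing: float = 1.0):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1] != len(topology) or frames.shape[2] != 3:
            raise ValueError(
                f"frames must have shape (F, {len(topology)}, 3); got {frames.shape}")
        if frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        self.topology = topology
        self.frames = frames
        self.frame_spacing = frame_spacing

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_model(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.frames[i], model_id=i + 1)


@dataclasses.dataclass
class Selection:
    """Declarative atom selection.

    ``sidechain=True`` selects heavy atoms outside the backbone set; for
    glycine (which has no heavy side-chain atom) the CA atom stands in when
    ``gly_proxy`` is "CA", otherwise glycine contributes nothing.
    """

    chain_id: str | None = None
    residue_range: tuple[int, int] | None = None
    residue_indices: frozenset[int] | None = None
    atom_names: frozenset[str] | None = None
    sidechain: bool = False
    heavy_only: bool = True
    gly_proxy: str | None = "CA"

    def matches(self, atom: Atom) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= atom.residue_index <= hi):
                return False
        if self.residue_indices is not None and atom.residue_index not in self.residue_indices:
            return False
        if self.heavy_only and not atom.is_heavy:
            return False
        if self.sidechain:
            if atom.residue_name == "GLY":
                return self.gly_proxy is not None and atom.name == self.gly_proxy
            if atom.is_backbone:
                return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        return True


#: Convenience: Cα atoms of every residue.
CA_SELECTION = Selection(atom_names=frozenset({"CA"}), sidechain=False)


def select(model_or_traj: StructureModel | Trajectory, selection: Selection) -> list[int]:
    """Return sorted, stable atom indices matching ``selection``."""
    model = model_or_traj.topology if isinstance(model_or_traj, Trajectory) else model_or_traj
    return [i for i, a in enumerate(model.atoms) if selection.matches(a)]


# ---------------------------------------------------------------------------
# PDB

def read_pdb(path: str | Path, allow_nonstandard: bool = False) -> list[StructureModel]:
    """Parse a (possibly multi-model) PDB file into structure models.

    Alternate locations keep the highest-occupancy conformer (tie -> 'A');
    insertion codes raise; hydrogen records are kept (distance computations
    filter them downstream).
    """
    path = Path(path)
    models: list[StructureModel] = []
    current: list[tuple[Atom, str, float]] = []  # atom, altloc, occupancy
    model_id = 1
    in_model = False

    def flush() -> None:
        nonlocal current
        if not current:
            return
        best: dict[tuple[str, int, str], tuple[Atom, str, float]] = {}
        order: list[tuple[str, int, str]] = []
        for atom, altloc, occ in current:
            key = (atom.chain_id, atom.residue_index, atom.name)
            if key not in best:
                best[key] = (atom, altloc, occ)
                order.append(key)
            else:
                _, alt0, occ0 = best[key]
                if occ > occ0 or (occ == occ0 and altloc == "A" and alt0 != "A"):
                    best[key] = (atom, altloc, occ)
        models.append(StructureModel([best[k][0] for k in order], model_id,
                                     allow_nonstandard=allow_nonstandard))
        current = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if current:
                    flush()
                try:
                    model_id = int(line[10:14])
                except ValueError:
                    model_id = len(models) + 1
                in_model = True
            elif rec == "ENDMDL":
                flush()
                in_model = False
                model_id = len(models) + 1
            elif rec in ("ATOM", "HETATM"):
                try:
                    name = line[12:16].strip()
                    altloc = line[16].strip()
                    resname = line[17:20].strip()
                    chain = line[21].strip() or " "
                    resseq = int(line[22:26])
                    icode = line[26].strip()
                    xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                    occ_field = line[54:60].strip()
                    occ = float(occ_field) if occ_field else 1.0
                    element = line[76:78].strip() if len(line) >= 78 else ""
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed ATOM record: {exc}") from exc
                if icode:
                    raise ValueError(
                        f"{path}:{lineno}: insertion codes are not supported")
                atom = Atom(name=name, element=element, residue_index=resseq,
                            residue_name=resname, chain_id=chain, coords=np.array(xyz))
                current.append((atom, altloc, occ))
    if current:
        flush()
    if not models:
        raise ValueError(f"{path}: no ATOM records found")
    # silence unused warning for in_model bookkeeping
    del in_model
    return models


def write_pdb(path: str | Path, models: StructureModel | Iterable[StructureModel]) -> None:
    if isinstance(models, StructureModel):
        models = [models]
    models = list(models)
    multi = len(models) > 1
    with open(path, "w") as fh:
        for m in models:
            if multi:
                fh.write(f"MODEL     {m.model_id:4d}\n")
            for serial, a in enumerate(m.atoms, start=1):
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.coords
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s} {a.residue_name:<3s} "
                    f"{a.chain_id:1s}{a.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectories

def read_trajectory(path: str | Path, format: str = "xyzt",
                    allow_nonstandard: bool = False) -> Trajectory:
    """Read a trajectory from multi-model PDB or the text "xyzt" format."""
    if format == "pdb-multimodel":
        models = read_pdb(path, allow_nonstandard=allow_nonstandard)
        sig0 = models[0].atom_signature()
        for i, m in enumerate(models[1:], start=2):
            if m.atom_signature() != sig0:
                raise ValueError(f"{path}: frame {i} atom order/count differs from frame 1")
        frames = np.stack([m.coords for m in models])
        return Trajectory(models[0], frames)
    if format != "xyzt":
        raise ValueError(f"unknown trajectory format {format!r}")

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: header must be 'natoms nframes'")
        natoms, nframes = int(header[0]), int(header[1])
        frames = np.empty((nframes, natoms, 3), dtype=float)
        sig: list[tuple[str, int, str, str]] | None = None
        topology: StructureModel | None = None
        for f in range(nframes):
            atoms: list[Atom] = []
            frame_sig: list[tuple[str, int, str, str]] = []
            for i in range(natoms):
                line = fh.readline()
                if not line:
                    raise ValueError(f"{path}: frame {f + 1} is truncated")
                parts = line.split()
                if len(parts) != 7:
                    raise ValueError(
                        f"{path}: frame {f + 1} atom {i + 1}: expected 7 fields")
                name, resid, resname, chain = parts[0], int(parts[1]), parts[2], parts[3]
                xyz = np.array([float(parts[4]), float(parts[5]), float(parts[6])])
                frame_sig.append((chain, resid, resname, name))
                frames[f, i] = xyz
                if f == 0:
                    atoms.append(Atom(name=name, element="", residue_index=resid,
                                      residue_name=resname, chain_id=chain, coords=xyz))
            if f == 0:
                sig = frame_sig
                topology = StructureModel(atoms, model_id=1,
                                          allow_nonstandard=allow_nonstandard)
            elif frame_sig != sig:
                raise ValueError(f"{path}: frame {f + 1} atom order/count differs from frame 1")
    assert topology is not None
    return Trajectory(topology, frames)


def write_trajectory(path: str | Path, traj: Trajectory, format: str = "xyzt") -> None:
    if format == "pdb-multimodel":
        write_pdb(path, [traj.frame_model(i) for i in range(traj.n_frames)])
        return
    if format != "xyzt":
        raise ValueError(f"unknown trajectory format {format!r}")
    with open(path, "w") as fh:
        fh.write(f"{traj.n_atoms} {traj.n_frames}\n")
        for f in range(traj.n_frames):
            for a, (x, y, z) in zip(traj.topology.atoms, traj.frames[f]):
                fh.write(f"{a.name} {a.residue_index} {a.residue_name} "
                         f"{a.chain_id} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return [ProteinSequence(id=r.id, residues=str(r.seq)) for r in records]


def write_fasta(path: str | Path, seqs: Iterable[ProteinSequence]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    seqio_write(records, str(path), "fasta")
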