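"""In-memory frame containers and plain-text frame I/O.

Lengths are nanometres throughout; boxes are orthorhombic with periodic
boundaries in all three directions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = ["AtomisticFrame", "CGFrame", "minimum_image", "write_cg_frame", "read_cg_frame"]


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    box = np.asarray(box, dtype=float)
    return vectors - box * np.round(vectors / box)


@dataclass
class AtomisticFrame:
    """One atomistic configuration: positions (nm), masses (amu), identity."""

    positions: np.ndarray  # (N, 3) nm
    masses: np.ndarray  # (N,) amu
    names: np.ndarray  # (N,) atom names
    resids: np.ndarray  # (N,) molecule ids
    resnames: np.ndarray  # (N,) residue names
    box: np.ndarray  # (3,) nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.names = np.asarray(self.names)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @classmethod
    def from_mdanalysis(cls, universe) -> "AtomisticFrame":
        """Build a frame from an ``MDAnalysis.Universe`` (Å -> nm)."""
        ag = universe.atoms
        return cls(
            positions=ag.positions / 10.0,
            masses=ag.masses,
            names=np.array(ag.names),
            resids=np.array(ag.resids),
            resnames=np.array(ag.resnames),
            box=np.asarray(universe.dimensions[:3], dtype=float) / 10.0,
        )


def iter_mdanalysis_frames(topology: str, trajectory: str | None = None):
    """Yield :class:`AtomisticFrame` objects from standard coordinate and
    trajectory files (PDB/GRO, XTC/DCD/...) via MDAnalysis."""
    import MDAnalysis as mda

    u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    for _ in u.trajectory:
        yield AtomisticFrame.from_mdanalysis(u)


@dataclass
class CGFrame:
    """A CG configuration: bead positions, types, molecule ids, box.

    ``mol_species`` carries the species label per bead so metrics can make
    per-species selections without a side table.
    """

    positions: np.ndarray  # (M, 3) nm
    bead_types: np.ndarray  # (M,) bead type names
    mol_ids: np.ndarray  # (M,) molecule id per bead
    mol_species: np.ndarray  # (M,) species per bead
    box: np.ndarray  # (3,) nm
    periodic: tuple[bool, bool, bool] = (True, True, True)
    masses: np.ndarray | None = None  # (M,) amu, optional per-instance masses

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.bead_types = np.asarray(self.bead_types)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        self.mol_species = np.asarray(self.mol_species)
        self.box = np.asarray(self.box, dtype=float)
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite bead coordinates")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be > 0")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def bead_masses(self, registry=None) -> np.ndarray:
        """Per-bead masses: explicit if present, else nominal type masses."""
        if self.masses is not None:
            return self.masses
        from .topology import BEAD_TYPES

        return np.array([BEAD_TYPES[t].mass for t in self.bead_types])

    def select(self, mask: np.ndarray) -> "CGFrame":
        return CGFrame(
            positions=self.positions[mask],
            bead_types=self.bead_types[mask],
            mol_ids=self.mol_ids[mask],
            mol_species=self.mol_species[mask],
            box=self.box,
            periodic=self.periodic,
            masses=None if self.masses is None else self.masses[mask],
        )

    def molecules(self):
        """Yield (mol_id, species, bead index array) per molecule, in id order."""
        order = np.argsort(self.mol_ids, kind="stable")
        ids = self.mol_ids[order]
        bounds = np.flatnonzero(np.diff(ids)) + 1
        for chunk in np.split(order, bounds):
            yield self.mol_ids[chunk[0]], str(self.mol_species[chunk[0]]), chunk


# ---------------------------------------------------------------------------
# plain-text frame format
# ---------------------------------------------------------------------------

_HEADER = "# cglamella CG frame v1"


def write_cg_frame(frame: CGFrame, path_or_buf) -> None:
    """Write a CG frame as plain text (one bead per row)."""
    buf = io.StringIO()
    buf.write(f"{_HEADER}\n")
    buf.write(f"# box_nm {frame.box[0]:.8g} {frame.box[1]:.8g} {frame.box[2]:.8g}\n")
    buf.write("# mol_id species bead_type x_nm y_nm z_nm mass_amu\n")
    masses = frame.bead_masses()
    for i in range(frame.n_beads):
        x, y, z = frame.positions[i]
        buf.write(
            f"{frame.mol_ids[i]} {frame.mol_species[i]} {frame.bead_types[i]} "
            f"{x:.6f} {y:.6f} {z:.6f} {masses[i]:.4f}\n"
        )
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_cg_frame(path_or_buf) -> CGFrame:
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(_HEADER):
        raise ValueError("not a cglamella CG frame file")
    box = np.array([float(x) for x in lines[1].split()[2:5]])
    mol_ids, species, types, pos, masses = [], [], [], [], []
    for ln in lines[3:]:
        if not ln.strip() or ln.startswith("#"):
            continue
        f = ln.split()
        mol_ids.append(int(f[0]))
        species.append(f[1])
        types.append(f[2])
        pos.append([float(f[3]), float(f[4]), float(f[5])])
        masses.append(float(f[6]))
    return CGFrame(
        positions=np.array(pos),
        bead_types=np.array(types),
        mol_ids=np.array(mol_ids),
        mol_species=np.array(species),
        box=box,
        masses=np.array(masses),
    )
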