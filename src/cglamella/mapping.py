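"""Forward mapping of atomistic frames to CG beads and bonded-sample harvest.

Beads sit at the mass-weighted centre of their atom group, which preserves
the system centre of mass and total mass — the convention the density
profiles and Boltzmann-inversion targets rely on.  Bond samples are
harvested with the minimum-image convention and reported in Å; angles in
degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .frames import AtomisticFrame, CGFrame, minimum_image
from .topology import MoleculeTemplate

__all__ = ["MappingError", "TermSamples", "map_frame", "map_water", "bonded_samples"]


class MappingError(ValueError):
    """Atomistic frame cannot be resolved against the template registry."""


def _unwrap(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Make a molecule whole relative to its first atom (minimum image)."""
    return pos[0] + minimum_image(pos - pos[0], box)


def map_frame(
    frame: AtomisticFrame,
    registry: Mapping[str, MoleculeTemplate],
    assignment: Mapping[str, str],
    unwrap: bool = False,
) -> CGFrame:
    """Map an atomistic frame to CG beads (mass-weighted group centres).

    ``assignment`` maps residue names to species in ``registry``.  Molecules
    broken across the periodic boundary raise unless ``unwrap=True``.
    """
    out_pos, out_types, out_mids, out_species, out_masses = [], [], [], [], []
    resids = frame.resids
    order = np.argsort(resids, kind="stable")
    bounds = np.flatnonzero(np.diff(resids[order])) + 1
    for chunk in np.split(order, bounds):
        resid = int(resids[chunk[0]])
        resname = str(frame.resnames[chunk[0]])
        if resname not in assignment:
            raise MappingError(f"residue {resname!r} (id {resid}) has no species assignment")
        species = assignment[resname]
        if species not in registry:
            raise MappingError(f"species {species!r} not in registry")
        t = registry[species]
        pos = frame.positions[chunk]
        name_to_row = {str(n): i for i, n in enumerate(frame.names[chunk])}
        spread = pos.max(axis=0) - pos.min(axis=0)
        if np.any(spread > frame.box / 2):
            if not unwrap:
                raise MappingError(
                    f"molecule {resid} ({resname}) spans more than half the box; "
                    "pass unwrap=True if it is wrapped across the boundary"
                )
            pos = _unwrap(pos, frame.box)
        for bi, grp in enumerate(t.atom_groups):
            rows, masses = [], []
            for a in grp:
                if a.name not in name_to_row:
                    raise MappingError(
                        f"molecule {resid} ({resname}): atom {a.name!r} required by "
                        f"bead {t.beads[bi]} is missing"
                    )
                rows.append(name_to_row[a.name])
                masses.append(frame.masses[chunk[rows[-1]]])
            m = np.asarray(masses)
            out_pos.append(np.average(pos[rows], axis=0, weights=m))
            out_types.append(t.beads[bi])
            out_mids.append(resid)
            out_species.append(species)
            out_masses.append(m.sum())
    return CGFrame(
        positions=np.array(out_pos),
        bead_types=np.array(out_types),
        mol_ids=np.array(out_mids),
        mol_species=np.array(out_species),
        box=frame.box.copy(),
        masses=np.array(out_masses),
    )


def map_water(
    water_positions: np.ndarray, ratio: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster water molecules into CG beads of ``ratio`` waters each.

    Dynamic mapping is realised as greedy nearest-neighbour clustering:
    repeatedly seed a cluster with the lowest-index unassigned water and
    absorb its ``ratio - 1`` nearest unassigned neighbours (greedy
    minimisation of within-cluster dispersion).  Returns bead positions
    (cluster centroids; waters are identical so the mass-weighted centre
    is the centroid) and a boolean "short cluster" flag per bead — the
    last cluster is short when the water count is not divisible by ratio.
    """
    pos = np.asarray(water_positions, dtype=float)
    if pos.ndim != 2 or (len(pos) and pos.shape[1] != 3):
        raise ValueError("water_positions must be (N, 3)")
    n = len(pos)
    if n == 0:
        return np.empty((0, 3)), np.empty(0, dtype=bool)
    unassigned = list(range(n))
    beads, short = [], []
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed]
        if unassigned:
            d2 = np.sum((pos[unassigned] - pos[seed]) ** 2, axis=1)
            take = min(ratio - 1, len(unassigned))
            for j in np.argsort(d2, kind="stable")[:take]:
                members.append(unassigned[j])
            for m in members[1:]:
                unassigned.remove(m)
        beads.append(pos[members].mean(axis=0))
        short.append(len(members) < ratio)
    return np.array(beads), np.array(short, dtype=bool)


@dataclass
class TermSamples:
    """Samples for one bonded term: bond lengths in Å or angles in degrees."""

    kind: str  # "bond" | "angle"
    values: np.ndarray

    def extend(self, more: np.ndarray) -> None:
        self.values = np.concatenate([self.values, more])


def _term_key(names: Sequence[str]) -> str:
    names = list(names)
    if list(reversed(names)) < names:
        names = list(reversed(names))
    return "-".join(names)


def bonded_samples(
    frames: Iterable[CGFrame], template: MoleculeTemplate
) -> dict[str, TermSamples]:
    """Harvest bond-length (Å) and angle (degree) samples for a template.

    One sample per molecule per frame per term; samples are pooled across
    term instances with the same bead-type signature (e.g. all chain
    TAIL-TAIL bonds).  Bond vectors use the minimum-image convention.
    """
    acc: dict[str, tuple[str, list[float]]] = {}
    n_mols = 0
    for frame in frames:
        for mid, species, rows in frame.molecules():
            if species != template.name:
                continue
            n_mols += 1
            pos = frame.positions[rows]
            if len(rows) != template.n_beads:
                raise MappingError(
                    f"molecule {mid}: {len(rows)} beads, template "
                    f"{template.name} has {template.n_beads}"
                )
            for i, j in template.bonds:
                vec = minimum_image(pos[j] - pos[i], frame.box)
                key = _term_key((template.beads[i], template.beads[j]))
                acc.setdefault(key, ("bond", []))[1].append(np.linalg.norm(vec) * 10.0)
            for i, j, k in template.angles:
                v1 = minimum_image(pos[i] - pos[j], frame.box)
                v2 = minimum_image(pos[k] - pos[j], frame.box)
                c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
                key = _term_key((template.beads[i], template.beads[j], template.beads[k]))
                acc.setdefault(key, ("angle", []))[1].append(ang)
    if n_mols == 0:
        raise MappingError(f"no molecules of species {template.name!r} in the frames")
    return {k: TermSamples(kind, np.array(vals)) for k, (kind, vals) in acc.items()}
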