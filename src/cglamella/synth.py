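"""Synthetic gel-phase lamellae and bonded samples with known ground truth.

The generators build idealized CG configurations that emulate the ordered
lamellar structures the analysis suite targets: lipids on a hexagonal
in-plane lattice at an exact area per lipid, straight chains at a uniform
tilt, headgroup beads clustered at the leaflet interface planes, a
controllable terminal-bead overlap at each pair midplane, a controllable
fraction of tail-splayed (extended) ceramides, and Gaussian positional
noise.  Every generator returns a ``(frame, truth)`` pair so each metric
can be validated against construction parameters — the module's purpose
is ground truth, not thermodynamic realism.

Geometry conventions: the lamella is normal to z; chain beads advance by
a fixed rise along the tilted chain axis, the rise being derived from the
requested pair thickness and midplane overlap so that the longest chains
(8 beads: the ceramide acyl chain and FFA) terminate exactly
``overlap/2`` past the pair midplane.  Shorter chains (5-bead sphingoid,
6-bead cholesterol body) use the same rise and end short of the midplane,
as their shorter physical length dictates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .frames import CGFrame
from .inversion import HarmonicParams, sample_term
from .mapping import TermSamples
from .topology import (
    CompositionSpec,
    MoleculeTemplate,
    TopologyError,
    composition_counts,
    default_registry,
)

__all__ = ["BilayerRecipe", "gen_bilayer", "gen_multilayer", "gen_bonded_dataset"]

_HEAD_OFFSET = 0.25  # nm, headgroup plane -> first chain bead (along chain)
_CHAIN_BEADS = 8  # beads in the longest chains (CER acyl, FFA)


@dataclass
class BilayerRecipe:
    """Construction parameters for a synthetic lamella.

    ``pair_thickness`` is the headgroup-plane to headgroup-plane distance
    of one leaflet pair (the peak-to-peak thickness the density profile
    recovers); ``overlap`` the interdigitation width at the pair midplane.
    """

    composition: CompositionSpec
    apl: float = 0.40  # nm²
    tilt: float = 0.0  # degrees
    pair_thickness: float = 5.3  # nm
    overlap: float = 0.8  # nm
    extended_pct: float = 0.0  # % of CERs tail-splayed
    noise_sigma: float = 0.03  # nm
    pair_gap: float = 1.0  # nm between adjacent pairs' headgroup planes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.apl <= 0:
            raise ValueError("apl must be > 0")
        if not 0.0 <= self.tilt <= 45.0:
            raise ValueError("tilt must be in [0°, 45°]")
        if not 0.0 <= self.extended_pct <= 100.0:
            raise ValueError("extended_pct must be in [0, 100]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.overlap < 0 or self.overlap >= self.pair_thickness:
            raise ValueError(
                "infeasible recipe: overlap must be in [0, pair_thickness)"
            )

    @property
    def bead_rise(self) -> float:
        """Per-bead z-rise derived from thickness/overlap.

        Chains carry a coherent per-chain phase jitter of one bead rise
        (see ``_place_molecule``), which turns the bead comb into a flat
        density slab whose edge sits half a rise beyond the terminal
        bead; the rise is chosen so that edge lands exactly overlap/2
        past the pair midplane.
        """
        rise = (self.pair_thickness / 2 - _HEAD_OFFSET + self.overlap / 2) / (
            _CHAIN_BEADS - 0.5
        )
        if rise <= 0.05:
            raise ValueError(
                "infeasible recipe: pair thickness too small for the chain length"
            )
        return rise


def _hex_lattice(n: int, area: float) -> tuple[np.ndarray, float, float]:
    """n sites of a hexagonal lattice inside a box of exactly `area` nm².

    Returns (xy positions, Lx, Ly).  The lattice may hold more sites than
    lipids; the box area (hence the measured APL) is exact regardless.
    """
    nx = max(int(math.floor(math.sqrt(n))), 1)
    ny = int(math.ceil(n / nx))
    # hexagonal row spacing: ay = ax * sqrt(3)/2
    ax = math.sqrt(2.0 * area / (math.sqrt(3.0) * nx * ny))
    ay = ax * math.sqrt(3.0) / 2.0
    lx, ly = nx * ax, ny * ay
    sites = []
    for j in range(ny):
        for i in range(nx):
            x = (i + 0.25 + 0.5 * (j % 2)) * ax
            sites.append((x % lx, (j + 0.5) * ay))
            if len(sites) == n:
                return np.array(sites), lx, ly
    raise AssertionError("lattice underfilled")  # pragma: no cover


def _headgroup_layout(species: str) -> list[tuple[str, float, float]]:
    """Per-headgroup-bead (name, lateral dx, depth along inward normal).

    Depths are zero by construction: all headgroup mass sits exactly on
    the leaflet plane, so the density peak (the reference for thickness
    and leaflet clustering) coincides with the plane."""
    if species.startswith("CER"):
        layout = [("MHEAD2", 0.0, 0.0), ("OH1", -0.08, 0.0), ("OH2", 0.08, 0.0),
                  ("AMIDE", 0.02, 0.0)]
        if species in ("CER_NP", "CER_AP"):
            layout.append(("OH3", -0.05, 0.0))
        if species in ("CER_AS", "CER_AP"):
            layout.append(("OH4", 0.08, 0.0))
        return layout
    if species == "FFA_C24":
        return [("HEAD", 0.0, 0.0)]
    if species == "CHOL":
        return [("CHEAD", 0.0, 0.0)]
    raise TopologyError(f"no layout for species {species!r}")


def _chain_anchors(species: str) -> dict[str, float]:
    """Lateral x-offset of each chain's anchor.

    Both ceramide chains anchor on the same axis: any perpendicular
    offset between the two unequal-length chains would rotate the
    lipid's minimum-inertia axis away from the intended tilt, breaking
    the generator's exactness guarantee."""
    if species.startswith("CER"):
        return {"sphingoid": 0.0, "acyl": 0.0}
    if species == "FFA_C24":
        return {"acyl": 0.0}
    if species == "CHOL":
        return {"body": 0.0}
    raise TopologyError(f"no chains for species {species!r}")


def _place_molecule(
    template: MoleculeTemplate,
    site: np.ndarray,
    plane_z: float,
    inward: int,
    rise: float,
    tan_tilt: float,
    extended: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bead positions for one lipid, in template bead order.

    Each chain is rigidly shifted along its own axis by a uniform phase
    u ∈ (−rise/2, rise/2): across many lipids the bead comb convolves
    into an exactly flat density slab with sharp edges half a rise
    beyond the first/last bead planes, while the chain direction (hence
    tilt and S2) is untouched.
    """
    pos = np.empty((template.n_beads, 3))
    bead_at = {}
    for name, dx, depth in _headgroup_layout(template.name):
        i = template.beads.index(name)
        bead_at[i] = (site[0] + dx, site[1], plane_z + inward * depth)
    anchors = _chain_anchors(template.name)
    for chain_name, idx in template.chains.items():
        dx0 = anchors[chain_name]
        s = inward
        if extended and chain_name == "acyl":
            s = -inward  # splayed: acyl runs into the adjacent leaflet
        u = rng.uniform(-rise / 2, rise / 2)
        for j, bi in enumerate(idx):
            d = _HEAD_OFFSET + j * rise + u
            bead_at[bi] = (site[0] + dx0 + d * tan_tilt, site[1], plane_z + s * d)
    for i in range(template.n_beads):
        pos[i] = bead_at[i]
    return pos


def _gen_lamella(recipe: BilayerRecipe, n_pairs: int) -> tuple[CGFrame, dict]:
    spec = recipe.composition
    n_leaflets = 2 * n_pairs
    if spec.n_leaflets != n_leaflets:
        raise ValueError(
            f"composition declares {spec.n_leaflets} leaflets, generator builds {n_leaflets}"
        )
    if spec.n_lipids % n_leaflets:
        raise ValueError("n_lipids must divide evenly over the leaflets")
    n_per_leaflet = spec.n_lipids // n_leaflets
    registry = default_registry()
    rng = np.random.default_rng(recipe.seed)

    per_leaflet_counts = composition_counts(
        CompositionSpec(spec.ratios, n_per_leaflet, 2, spec.water_beads_per_lipid)
    )
    area = recipe.apl * n_per_leaflet
    sites, lx, ly = _hex_lattice(n_per_leaflet, area)

    t = recipe.pair_thickness
    rise = recipe.bead_rise
    tan_tilt = math.tan(math.radians(recipe.tilt))
    # outer margin holds the water slab and any outward-splayed chains
    chain_drop = _HEAD_OFFSET + (_CHAIN_BEADS - 1) * rise
    margin = 2.0 if recipe.extended_pct == 0 else chain_drop + 1.0
    lz = n_pairs * t + (n_pairs - 1) * recipe.pair_gap + 2 * margin

    species_list: list[str] = []
    for sp, c in per_leaflet_counts.items():
        species_list += [sp] * c

    positions, types, mids, specs_arr, masses = [], [], [], [], []
    mol_id = 0
    ext_per_leaflet = []
    planes = []
    for pair in range(n_pairs):
        z_lo = margin + pair * (t + recipe.pair_gap)
        z_hi = z_lo + t
        planes += [z_lo, z_hi]
        for plane_z, inward in ((z_lo, +1), (z_hi, -1)):
            order = rng.permutation(n_per_leaflet)
            leaflet_species = [species_list[i] for i in order]
            cer_slots = [i for i, sp in enumerate(leaflet_species) if sp.startswith("CER")]
            n_ext = int(round(recipe.extended_pct / 100.0 * len(cer_slots)))
            ext_slots = set(cer_slots[:n_ext])
            ext_per_leaflet.append((n_ext, len(cer_slots)))
            for slot, sp in enumerate(leaflet_species):
                tmpl = registry[sp]
                pos = _place_molecule(
                    tmpl,
                    sites[slot],
                    plane_z,
                    inward,
                    rise,
                    tan_tilt,
                    extended=slot in ext_slots,
                    rng=rng,
                )
                if recipe.noise_sigma > 0:
                    pos = pos + rng.normal(0.0, recipe.noise_sigma, pos.shape)
                positions.append(pos)
                types += tmpl.beads
                mids += [mol_id] * tmpl.n_beads
                specs_arr += [sp] * tmpl.n_beads
                masses += tmpl.bead_masses
                mol_id += 1

    # water: outer slabs only (inner leaflets see no bulk water)
    n_w = int(round(spec.water_beads_per_lipid * spec.n_lipids))
    wtmpl = registry["WATER"]
    slab_lo = (0.3, max(margin - 0.4, 0.31))
    slab_hi = (min(lz - margin + 0.4, lz - 0.31), lz - 0.3)
    for i in range(n_w):
        lo, hi = slab_lo if i % 2 == 0 else slab_hi
        positions.append(
            np.array([[rng.uniform(0, lx), rng.uniform(0, ly), rng.uniform(lo, hi)]])
        )
        types.append("W")
        mids.append(mol_id)
        specs_arr.append("WATER")
        masses += wtmpl.bead_masses
        mol_id += 1

    frame = CGFrame(
        positions=np.vstack(positions),
        bead_types=np.array(types),
        mol_ids=np.array(mids),
        mol_species=np.array(specs_arr),
        box=np.array([lx, ly, lz]),
        masses=np.array(masses),
    )
    n_ext_tot = sum(n for n, _ in ext_per_leaflet)
    n_cer_tot = sum(c for _, c in ext_per_leaflet)
    inner = ext_per_leaflet[1:-1]
    # opposing leaflets tilt in mirrored directions, so at tilt θ the
    # director set is two delta peaks ±θ from z: S2 = (3 cos²θ − 1)/2
    cos_t = math.cos(math.radians(recipe.tilt))
    truth = {
        "apl": recipe.apl,
        "tilt_deg": recipe.tilt,
        "s2": (3.0 * cos_t**2 - 1.0) / 2.0,
        "pair_thickness": t,
        "interdigitation": recipe.overlap,
        "extended_pct": (100.0 * n_ext_tot / n_cer_tot) if n_cer_tot else float("nan"),
        "extended_pct_inner": (
            100.0 * sum(n for n, _ in inner) / sum(c for _, c in inner)
            if inner and sum(c for _, c in inner)
            else float("nan")
        ),
        "n_leaflets": n_leaflets,
        "n_lipids": spec.n_lipids,
        "counts_per_leaflet": per_leaflet_counts,
        "headgroup_planes": planes,
        "box": [lx, ly, lz],
        "bead_rise": rise,
        "seed": recipe.seed,
    }
    return frame, truth


def gen_bilayer(recipe: BilayerRecipe) -> tuple[CGFrame, dict]:
    """A two-leaflet lamella with known ground truth."""
    return _gen_lamella(recipe, n_pairs=1)


def gen_multilayer(recipe: BilayerRecipe) -> tuple[CGFrame, dict]:
    """A stacked six-leaflet lamella (three leaflet pairs, water outside)."""
    if recipe.composition.n_leaflets != 6:
        raise ValueError("multilayer generation requires a 6-leaflet composition")
    return _gen_lamella(recipe, n_pairs=3)


def gen_bonded_dataset(
    params: list[HarmonicParams], n_per_term: int, seed: int
) -> tuple[dict[str, TermSamples], list[HarmonicParams]]:
    """Gaussian bond/angle samples for each harmonic term, plus the truth
    table, for inversion round-trip testing."""
    if n_per_term < 1:
        raise ValueError("n_per_term must be >= 1")
    rng = np.random.default_rng(seed)
    out = {
        p.term: TermSamples(p.kind, sample_term(p, n_per_term, rng)) for p in params
    }
    return out, list(params)
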