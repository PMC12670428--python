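"""Coarse-grained bead types, molecule templates, and system compositions.

The CG models cover the dominant stratum-corneum lipids: four ceramide
subclasses (CER NS, NP, AS, AP, all with a 24-carbon acyl chain and an
18-carbon sphingoid base), cholesterol, lignoceric acid (FFA C24) and a
4:1 mapped water bead.  Each template records, per bead, the chemical
formula of the atom group it represents, so bead masses close exactly on
the molecular formula.

Mapping conventions
-------------------
* Alkyl chains map 3 carbons to a TAIL bead; a chain whose carbon count
  leaves a remainder of 2 terminates in a TER2 bead (2 carbons).  A
  remainder of 1 is unmappable.
* The ceramide headgroup maps to MHEAD2 (backbone carbons C1-C3), AMIDE
  (N-H plus the acyl carbonyl C=O) and one bead per hydroxyl: OH1 (C1-OH),
  OH2 (C3-OH), OH3 (phytosphingosine C4-OH; NP and AP only) and OH4
  (alpha-hydroxy C2'-OH; AS and AP only).  Counting the carbonyl carbon in
  AMIDE leaves 23 acyl carbons -> 7 TAIL + TER2; the sphingoid base keeps
  C1-C3 in MHEAD2, leaving 15 carbons -> 5 TAIL (terminal TAIL).
* The FFA carboxyl group maps to a HEAD bead (COOH); the remaining 23
  carbons follow the chain rule.
* Cholesterol maps to CHEAD (hydroxyl + 2 ring carbons) and six body
  beads; the partition is inherited from prior CG cholesterol work and is
  figure-derived (per-bead hydrogen counts are bookkeeping, not structure).
* One W bead represents four water molecules.

Per-bead atom groups are generated with systematic atom names (C1..,
H1.., O1.., N1) so synthetic atomistic frames can be built from, and
mapped against, the same table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "ATOMIC_MASSES",
    "BeadType",
    "AtomSpec",
    "MoleculeTemplate",
    "CompositionSpec",
    "TopologyError",
    "UnmappableChainError",
    "UnknownSpeciesError",
    "BEAD_TYPES",
    "SPECIES",
    "TAIL_FACTORS",
    "tail_bead_sequence",
    "build_template",
    "default_registry",
    "composition_counts",
    "mean_effective_tails",
    "template_to_yaml",
    "template_from_yaml",
]

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}


class TopologyError(ValueError):
    """Inconsistent topology definition or composition."""


class UnmappableChainError(TopologyError):
    """Chain length incompatible with the 3:1 / 2:1 terminal-bead rule."""


class UnknownSpeciesError(TopologyError, KeyError):
    """Species not present in the template registry."""


def formula_mass(formula: Mapping[str, int]) -> float:
    return sum(ATOMIC_MASSES[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class BeadType:
    """A CG bead type: nominal mass, heavy-atom count and structural role."""

    name: str
    mass: float  # amu, nominal (instances may differ slightly by formula)
    heavy_atoms: int
    role: str  # "headgroup" | "tail" | "water"

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise TopologyError(f"bead {self.name}: mass must be > 0")
        if self.heavy_atoms < 1:
            raise TopologyError(f"bead {self.name}: heavy_atoms must be >= 1")
        if self.role not in ("headgroup", "tail", "water"):
            raise TopologyError(f"bead {self.name}: unknown role {self.role!r}")


def _bt(name: str, formula: dict[str, int], heavy: int, role: str) -> BeadType:
    return BeadType(name, formula_mass(formula), heavy, role)


#: Registry of bead types used across all templates (names unique).
BEAD_TYPES: dict[str, BeadType] = {
    bt.name: bt
    for bt in [
        _bt("MHEAD2", {"C": 3, "H": 4}, 3, "headgroup"),
        _bt("AMIDE", {"C": 1, "H": 1, "N": 1, "O": 1}, 3, "headgroup"),
        _bt("OH1", {"O": 1, "H": 1}, 1, "headgroup"),
        _bt("OH2", {"O": 1, "H": 1}, 1, "headgroup"),
        _bt("OH3", {"O": 1, "H": 1}, 1, "headgroup"),
        _bt("OH4", {"O": 1, "H": 1}, 1, "headgroup"),
        _bt("TAIL", {"C": 3, "H": 6}, 3, "tail"),
        _bt("TER2", {"C": 2, "H": 5}, 2, "tail"),
        _bt("HEAD", {"C": 1, "H": 1, "O": 2}, 3, "headgroup"),
        _bt("CHEAD", {"C": 1, "H": 2, "O": 1}, 2, "headgroup"),
        _bt("CRING1", {"C": 4, "H": 6}, 4, "tail"),
        _bt("CRING2", {"C": 5, "H": 7}, 5, "tail"),
        _bt("CRING3", {"C": 4, "H": 6}, 4, "tail"),
        _bt("CRING4", {"C": 5, "H": 8}, 5, "tail"),
        _bt("CTAIL1", {"C": 4, "H": 8}, 4, "tail"),
        _bt("CTAIL2", {"C": 4, "H": 9}, 4, "tail"),
        _bt("W", {"O": 4, "H": 8}, 4, "water"),
    ]
}

SPECIES = ("CER_NS", "CER_NP", "CER_AS", "CER_AP", "FFA_C24", "CHOL", "WATER")

#: Effective number of hydrocarbon tails per lipid, used by the normalized
#: lipid area: 1 for FFA, 2 for CER, 1.9 for CHOL.
TAIL_FACTORS = {
    "CER_NS": 2.0,
    "CER_NP": 2.0,
    "CER_AS": 2.0,
    "CER_AP": 2.0,
    "FFA_C24": 1.0,
    "CHOL": 1.9,
}


@dataclass(frozen=True)
class AtomSpec:
    name: str
    element: str

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES[self.element]


@dataclass
class MoleculeTemplate:
    """A CG molecule: ordered beads, per-bead atom groups, bonds and angles.

    ``chains`` names the hydrocarbon chains (ordered bead indices from the
    headgroup attachment outward); ceramides have two ("sphingoid",
    "acyl"), which the extended-conformation metric relies on.
    """

    name: str
    beads: list[str]  # bead type names, ordered
    bead_formulas: list[dict[str, int]]
    atom_groups: list[list[AtomSpec]] = field(repr=False)
    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]]
    chains: dict[str, list[int]] = field(default_factory=dict)
    tail_factor: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def bead_masses(self) -> list[float]:
        """Per-instance bead masses from the assigned atom groups."""
        return [formula_mass(f) for f in self.bead_formulas]

    @property
    def molecular_mass(self) -> float:
        return sum(self.bead_masses)

    @property
    def molecular_formula(self) -> dict[str, int]:
        total: dict[str, int] = {}
        for f in self.bead_formulas:
            for el, n in f.items():
                total[el] = total.get(el, 0) + n
        return total

    def bead_role(self, i: int) -> str:
        return BEAD_TYPES[self.beads[i]].role

    @property
    def headgroup_indices(self) -> list[int]:
        return [i for i in range(self.n_beads) if self.bead_role(i) == "headgroup"]

    @property
    def tail_indices(self) -> list[int]:
        return [i for i in range(self.n_beads) if self.bead_role(i) == "tail"]

    @property
    def is_lipid(self) -> bool:
        return self.tail_factor is not None

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = self.n_beads
        if not (len(self.bead_formulas) == len(self.atom_groups) == n):
            raise TopologyError(f"{self.name}: bead/formula/group length mismatch")
        for bn in self.beads:
            if bn not in BEAD_TYPES:
                raise TopologyError(f"{self.name}: unknown bead type {bn!r}")
        # formulas consistent with atom groups (atom partition, mass closure)
        seen: set[str] = set()
        for i, (f, grp) in enumerate(zip(self.bead_formulas, self.atom_groups)):
            counts: dict[str, int] = {}
            for a in grp:
                if a.name in seen:
                    raise TopologyError(f"{self.name}: atom {a.name} in two beads")
                seen.add(a.name)
                counts[a.element] = counts.get(a.element, 0) + 1
            if counts != {el: c for el, c in f.items() if c}:
                raise TopologyError(
                    f"{self.name} bead {i} ({self.beads[i]}): formula/group mismatch"
                )
        for b in self.bonds:
            if not all(0 <= i < n for i in b):
                raise TopologyError(f"{self.name}: bond index out of range {b}")
        for a in self.angles:
            if not all(0 <= i < n for i in a):
                raise TopologyError(f"{self.name}: angle index out of range {a}")
        if n > 1 and not self._connected():
            raise TopologyError(f"{self.name}: bead graph is not connected")

    def _connected(self) -> bool:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_beads)}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        stack, seen = [0], {0}
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_beads


# ---------------------------------------------------------------------------
# chain rule
# ---------------------------------------------------------------------------


def tail_bead_sequence(n_carbons: int, carbons_in_headgroup: int = 0) -> list[str]:
    """Bead sequence for an alkyl chain under the 3:1 / 2:1 terminal rule.

    ``n_carbons - carbons_in_headgroup`` carbons are mapped to TAIL beads
    (3 carbons each); a remainder of 2 becomes a terminal TER2 bead, a
    remainder of 0 means the chain terminates in a TAIL bead.

    Raises
    ------
    UnmappableChainError
        If the remaining carbon count is < 2 or congruent to 1 mod 3.
    """
    rem = n_carbons - carbons_in_headgroup
    if rem < 2:
        raise UnmappableChainError(
            f"{rem} tail carbons left after headgroup; need at least 2"
        )
    if rem % 3 == 1:
        raise UnmappableChainError(
            f"{rem} tail carbons cannot be split into 3-carbon TAIL beads "
            "with a 2-carbon TER2 terminus (remainder 1 mod 3)"
        )
    if rem % 3 == 0:
        return ["TAIL"] * (rem // 3)
    return ["TAIL"] * ((rem - 2) // 3) + ["TER2"]


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------


class _AtomNamer:
    """Systematic per-molecule atom names: C1.., H1.., O1.., N1.."""

    def __init__(self) -> None:
        self.counts: dict[str, int] = {}

    def group(self, formula: dict[str, int]) -> list[AtomSpec]:
        atoms = []
        for el in ("C", "N", "O", "H"):
            for _ in range(formula.get(el, 0)):
                self.counts[el] = self.counts.get(el, 0) + 1
                atoms.append(AtomSpec(f"{el}{self.counts[el]}", el))
        return atoms


def _chain_formulas(beads: list[str], first: dict[str, int] | None = None) -> list[dict[str, int]]:
    """Standard chain formulas: TAIL=C3H6, terminal TAIL=C3H7, TER2=C2H5.

    ``first`` overrides the formula of the attachment bead (used when the
    first chain carbon carries a hydroxyl or a double bond).
    """
    out = []
    for i, b in enumerate(beads):
        if b == "TER2":
            f = {"C": 2, "H": 5}
        elif i == len(beads) - 1:
            f = {"C": 3, "H": 7}  # terminal TAIL carries the methyl
        else:
            f = {"C": 3, "H": 6}
        out.append(dict(f))
    if first is not None:
        out[0] = dict(first)
    return out


def _consecutive_bonds(idx: list[int]) -> list[tuple[int, int]]:
    return [(idx[i], idx[i + 1]) for i in range(len(idx) - 1)]


def _consecutive_angles(idx: list[int]) -> list[tuple[int, int, int]]:
    return [(idx[i], idx[i + 1], idx[i + 2]) for i in range(len(idx) - 2)]


def _build_ceramide(name: str, oh3: bool, oh4: bool) -> MoleculeTemplate:
    beads: list[str] = ["MHEAD2", "OH1", "OH2", "AMIDE"]
    formulas: list[dict[str, int]] = [
        {"C": 3, "H": 4},
        {"O": 1, "H": 1},
        {"O": 1, "H": 1},
        {"C": 1, "H": 1, "N": 1, "O": 1},
    ]
    if oh3:
        beads.append("OH3")
        formulas.append({"O": 1, "H": 1})
    if oh4:
        beads.append("OH4")
        formulas.append({"O": 1, "H": 1})
    i_oh3 = beads.index("OH3") if oh3 else None
    i_oh4 = beads.index("OH4") if oh4 else None

    # sphingoid base: 18 C, 3 in MHEAD2 -> 5 TAIL.  CER NS keeps the 4,5
    # double bond (first TAIL = C3H4); phytosphingosine (NP/AP) is saturated
    # with the C4 hydroxyl mapped to OH3 (first TAIL = C3H5).
    sph_beads = tail_bead_sequence(18, 3)
    sph_first = {"C": 3, "H": 5} if oh3 else {"C": 3, "H": 4}
    sph_formulas = _chain_formulas(sph_beads, first=sph_first)
    sph_idx = list(range(len(beads), len(beads) + len(sph_beads)))
    beads += sph_beads
    formulas += sph_formulas

    # acyl chain: 24 C, carbonyl carbon counted in AMIDE -> 23 C -> 7 TAIL
    # + TER2.  The alpha-hydroxy subclasses (AS/AP) put the C2' hydroxyl in
    # OH4 (first TAIL = C3H5).
    acyl_beads = tail_bead_sequence(24, 1)
    acyl_first = {"C": 3, "H": 5} if oh4 else None
    acyl_formulas = _chain_formulas(acyl_beads, first=acyl_first)
    acyl_idx = list(range(len(beads), len(beads) + len(acyl_beads)))
    beads += acyl_beads
    formulas += acyl_formulas

    bonds = [(0, 1), (0, 2), (0, 3), (0, sph_idx[0]), (3, acyl_idx[0])]
    bonds += _consecutive_bonds(sph_idx) + _consecutive_bonds(acyl_idx)
    angles = [(1, 0, 3), (0, sph_idx[0], sph_idx[1]), (3, acyl_idx[0], acyl_idx[1])]
    angles += _consecutive_angles(sph_idx) + _consecutive_angles(acyl_idx)
    if oh3:
        bonds.append((sph_idx[0], i_oh3))  # TAIL-OH3
        angles.append((0, sph_idx[0], i_oh3))  # MHEAD2-TAIL-OH3
        angles.append((sph_idx[1], sph_idx[0], i_oh3))  # TAIL-TAIL-OH3
    if oh4:
        bonds.append((acyl_idx[0], i_oh4))  # TAIL-OH4
        angles.append((3, acyl_idx[0], i_oh4))  # AMIDE-TAIL-OH4
        angles.append((acyl_idx[1], acyl_idx[0], i_oh4))  # TAIL-TAIL-OH4

    namer = _AtomNamer()
    groups = [namer.group(f) for f in formulas]
    return MoleculeTemplate(
        name=name,
        beads=beads,
        bead_formulas=formulas,
        atom_groups=groups,
        bonds=bonds,
        angles=angles,
        chains={"sphingoid": sph_idx, "acyl": acyl_idx},
        tail_factor=TAIL_FACTORS[name],
    )


def _build_ffa() -> MoleculeTemplate:
    beads = ["HEAD"] + tail_bead_sequence(24, 1)
    formulas = [{"C": 1, "H": 1, "O": 2}] + _chain_formulas(beads[1:])
    chain_idx = list(range(1, len(beads)))
    bonds = [(0, 1)] + _consecutive_bonds(chain_idx)
    angles = [(0, 1, 2)] + _consecutive_angles(chain_idx)
    namer = _AtomNamer()
    return MoleculeTemplate(
        name="FFA_C24",
        beads=beads,
        bead_formulas=formulas,
        atom_groups=[namer.group(f) for f in formulas],
        bonds=bonds,
        angles=angles,
        chains={"acyl": chain_idx},
        tail_factor=TAIL_FACTORS["FFA_C24"],
    )


def _build_chol() -> MoleculeTemplate:
    # Inherited, figure-derived partition of C27H46O: hydroxyl + ring
    # carbons C2-C4 -> CHEAD region; remaining ring/tail carbons in six
    # body beads.  Hydrogen placement within a bead is bookkeeping only.
    beads = ["CHEAD", "CRING1", "CRING2", "CRING3", "CRING4", "CTAIL1", "CTAIL2"]
    formulas = [
        {"C": 1, "H": 2, "O": 1},
        {"C": 4, "H": 6},
        {"C": 5, "H": 7},
        {"C": 4, "H": 6},
        {"C": 5, "H": 8},
        {"C": 4, "H": 8},
        {"C": 4, "H": 9},
    ]
    idx = list(range(7))
    namer = _AtomNamer()
    return MoleculeTemplate(
        name="CHOL",
        beads=beads,
        bead_formulas=formulas,
        atom_groups=[namer.group(f) for f in formulas],
        bonds=_consecutive_bonds(idx),
        angles=_consecutive_angles(idx),
        chains={"body": idx[1:]},
        tail_factor=TAIL_FACTORS["CHOL"],
    )


def _build_water() -> MoleculeTemplate:
    namer = _AtomNamer()
    f = {"O": 4, "H": 8}
    return MoleculeTemplate(
        name="WATER",
        beads=["W"],
        bead_formulas=[f],
        atom_groups=[namer.group(f)],
        bonds=[],
        angles=[],
        chains={},
        tail_factor=None,
    )


def build_template(species: str) -> MoleculeTemplate:
    """Construct the CG template for one of the supported species."""
    builders = {
        "CER_NS": lambda: _build_ceramide("CER_NS", oh3=False, oh4=False),
        "CER_NP": lambda: _build_ceramide("CER_NP", oh3=True, oh4=False),
        "CER_AS": lambda: _build_ceramide("CER_AS", oh3=False, oh4=True),
        "CER_AP": lambda: _build_ceramide("CER_AP", oh3=True, oh4=True),
        "FFA_C24": _build_ffa,
        "CHOL": _build_chol,
        "WATER": _build_water,
    }
    try:
        return builders[species]()
    except KeyError:
        raise UnknownSpeciesError(
            f"unknown species {species!r}; supported: {', '.join(SPECIES)}"
        ) from None


def default_registry() -> dict[str, MoleculeTemplate]:
    """Templates for all supported species, keyed by species name."""
    return {s: build_template(s) for s in SPECIES}


# ---------------------------------------------------------------------------
# compositions
# ---------------------------------------------------------------------------


@dataclass
class CompositionSpec:
    """Molar composition of a lamellar system.

    ``ratios`` maps species to molar ratios (e.g. CER:CHOL:FFA = 1:0.5:1);
    water is specified separately as CG beads per lipid.
    """

    ratios: dict[str, float]
    n_lipids: int
    n_leaflets: int = 2
    water_beads_per_lipid: float = 10.0

    def __post_init__(self) -> None:
        if not self.ratios:
            raise TopologyError("composition has no species")
        for sp, r in self.ratios.items():
            if r <= 0:
                raise TopologyError(f"ratio for {sp} must be > 0")
        if self.n_lipids <= 0:
            raise TopologyError("n_lipids must be > 0")
        if self.n_leaflets not in (2, 6):
            raise TopologyError("n_leaflets must be 2 or 6")


def composition_counts(spec: CompositionSpec, rounding: str = "largest_remainder") -> dict[str, int]:
    """Resolve molar ratios to integer molecule counts summing to n_lipids.

    With ``rounding="error"`` non-integral ideal counts raise; the default
    largest-remainder policy distributes the residue to the species with
    the largest fractional parts and errors if any species drifts by more
    than one lipid.
    """
    total_r = sum(spec.ratios.values())
    ideal = {sp: spec.n_lipids * r / total_r for sp, r in spec.ratios.items()}
    if rounding == "error":
        counts = {}
        for sp, x in ideal.items():
            if abs(x - round(x)) > 1e-9:
                raise TopologyError(
                    f"count for {sp} is non-integral ({x:.4f}); "
                    "use largest-remainder rounding"
                )
            counts[sp] = int(round(x))
        return counts
    floors = {sp: math.floor(x + 1e-9) for sp, x in ideal.items()}
    residue = spec.n_lipids - sum(floors.values())
    by_frac = sorted(ideal, key=lambda sp: ideal[sp] - floors[sp], reverse=True)
    counts = dict(floors)
    for sp in by_frac[:residue]:
        counts[sp] += 1
    for sp in counts:
        if abs(counts[sp] - ideal[sp]) > 1.0 + 1e-9:
            raise TopologyError(f"rounding drift for {sp} exceeds 1 lipid")
    return counts


def mean_effective_tails(
    spec: CompositionSpec, tail_factors: Mapping[str, float] | None = None
) -> float:
    """Mole-fraction-weighted mean effective tail count of the mixture.

    The tail factors (FFA 1, CER 2, CHOL 1.9) estimate each lipid's
    cross-section in saturated-chain equivalents; the result converts an
    area per lipid into a normalized lipid area.
    """
    tf = TAIL_FACTORS if tail_factors is None else tail_factors
    total_r = sum(spec.ratios.values())
    out = 0.0
    for sp, r in spec.ratios.items():
        if sp not in tf:
            raise TopologyError(f"no effective-tail factor for species {sp!r}")
        out += r * tf[sp]
    return out / total_r


# ---------------------------------------------------------------------------
# serialization (structured text, one template per document)
# ---------------------------------------------------------------------------


def template_to_yaml(t: MoleculeTemplate) -> str:
    doc = {
        "name": t.name,
        "tail_factor": t.tail_factor,
        "beads": [
            {
                "type": bn,
                "formula": f,
                "atoms": [a.name for a in grp],
            }
            for bn, f, grp in zip(t.beads, t.bead_formulas, t.atom_groups)
        ],
        "bonds": [list(b) for b in t.bonds],
        "angles": [list(a) for a in t.angles],
        "chains": {k: list(v) for k, v in t.chains.items()},
    }
    return yaml.safe_dump(doc, sort_keys=False)


def template_from_yaml(text: str) -> MoleculeTemplate:
    doc = yaml.safe_load(text)
    beads, formulas, groups = [], [], []
    for b in doc["beads"]:
        beads.append(b["type"])
        formulas.append({el: int(n) for el, n in b["formula"].items()})
        groups.append([AtomSpec(n, n.rstrip("0123456789")) for n in b["atoms"]])
    return MoleculeTemplate(
        name=doc["name"],
        beads=beads,
        bead_formulas=formulas,
        atom_groups=groups,
        bonds=[tuple(b) for b in doc["bonds"]],
        angles=[tuple(a) for a in doc["angles"]],
        chains={k: list(v) for k, v in doc.get("chains", {}).items()},
        tail_factor=doc.get("tail_factor"),
    )
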