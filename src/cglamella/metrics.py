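"""Lamellar structure metrics for CG (or mapped) frames.

Implements the standard gel-phase bilayer/multilayer property suite:

* area per lipid (APL) and normalized lipid area (NLA = APL divided by
  the mixture's mean effective tail count),
* leaflet assignment by 1-D clustering of headgroup z,
* mass density profiles along z and peak-to-peak thickness,
* per-lipid tilt from the minimum-inertia axis of the tail beads,
* nematic order parameter S2 from the largest eigenvalue of the
  Q-tensor of molecular directors,
* interdigitation λ = 4∫ ρ_top ρ_bot / (ρ_top + ρ_bot)² dz,
* fraction of ceramides in the extended (tail-splayed) conformation,
* water content between a leaflet pair,

plus the leaflet → frame → replicate averaging conventions used for
reporting (replicate SD for everything except tilt, whose spread is the
pooled per-molecule standard deviation).

Analysis assumes the lamella is normal to z and not wrapped across the
z boundary (generators and mapped trajectories are arranged that way).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .frames import CGFrame
from .topology import BEAD_TYPES, TAIL_FACTORS, CompositionSpec, MoleculeTemplate, mean_effective_tails

__all__ = [
    "MetricsError",
    "LeafletError",
    "LeafletAssignment",
    "DensityProfile",
    "StructureReport",
    "assign_leaflets",
    "apl",
    "nla",
    "density_profile",
    "thickness",
    "lipid_directors",
    "tilt_angles",
    "nematic_order",
    "interdigitation",
    "extended_fraction",
    "water_per_lipid",
    "analyze_frame",
    "aggregate",
]


class MetricsError(ValueError):
    pass


class LeafletError(MetricsError):
    """Leaflet clustering failed; carries the cluster count found."""

    def __init__(self, msg: str, found: int):
        super().__init__(msg)
        self.found = found


def _lipid_mask(frame: CGFrame) -> np.ndarray:
    return np.array([sp in TAIL_FACTORS for sp in frame.mol_species])


def _role_mask(frame: CGFrame, role: str) -> np.ndarray:
    return np.array([BEAD_TYPES[t].role == role for t in frame.bead_types])


# ---------------------------------------------------------------------------
# leaflets
# ---------------------------------------------------------------------------


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet indices, ordered bottom (0) to top (n-1)."""

    lipid_ids: np.ndarray  # molecule ids
    leaflet_index: np.ndarray  # per lipid
    leaflet_z: np.ndarray  # mean headgroup z per leaflet, ascending

    @property
    def n_leaflets(self) -> int:
        return len(self.leaflet_z)

    @property
    def inner_leaflets(self) -> list[int]:
        """All leaflets except the two outermost (multilayer convention)."""
        return list(range(1, self.n_leaflets - 1))

    @property
    def central_pair(self) -> tuple[int, int]:
        k = self.n_leaflets
        return (k // 2 - 1, k // 2)

    def lipids_in(self, leaflets: int | Sequence[int]) -> np.ndarray:
        if np.isscalar(leaflets):
            leaflets = [int(leaflets)]
        mask = np.isin(self.leaflet_index, list(leaflets))
        return self.lipid_ids[mask]

    def counts(self) -> np.ndarray:
        return np.bincount(self.leaflet_index, minlength=self.n_leaflets)


def assign_leaflets(
    frame: CGFrame,
    n_leaflets: int,
    headgroup_beads: Sequence[str] | None = None,
    min_gap: float = 0.3,
) -> LeafletAssignment:
    """Group lipids into leaflets by 1-D clustering of headgroup z.

    Sorted per-lipid mean headgroup z values are split at gaps larger
    than ``min_gap`` (nm).  If that yields a different number of clusters
    than requested, a :class:`LeafletError` carrying the found count is
    raised — typical for disordered or unassembled systems.
    """
    if n_leaflets < 2:
        raise MetricsError("n_leaflets must be >= 2")
    if headgroup_beads is None:
        head = _role_mask(frame, "headgroup")
    else:
        head = np.isin(frame.bead_types, list(headgroup_beads))
    head &= _lipid_mask(frame)
    if not head.any():
        raise MetricsError("no headgroup beads in frame")
    sub = frame.select(head)
    ids, z = [], []
    for mid, _sp, rows in sub.molecules():
        ids.append(mid)
        z.append(sub.positions[rows, 2].mean())
    ids = np.array(ids)
    z = np.array(z)
    order = np.argsort(z, kind="stable")
    zs = z[order]
    gaps = np.diff(zs)
    split = gaps > min_gap
    found = int(split.sum()) + 1
    if found != n_leaflets:
        raise LeafletError(
            f"found {found} headgroup z-clusters (gap > {min_gap} nm), "
            f"expected {n_leaflets}",
            found=found,
        )
    labels_sorted = np.concatenate([[0], np.cumsum(split)])
    leaflet_index = np.empty(len(ids), dtype=int)
    leaflet_index[order] = labels_sorted
    leaflet_z = np.array([zs[labels_sorted == i].mean() for i in range(n_leaflets)])
    return LeafletAssignment(lipid_ids=ids, leaflet_index=leaflet_index, leaflet_z=leaflet_z)


# ---------------------------------------------------------------------------
# areas
# ---------------------------------------------------------------------------


def apl(
    frame: CGFrame,
    leaflets: LeafletAssignment,
    subset: Sequence[int] | None = None,
) -> tuple[np.ndarray, float]:
    """Area per lipid: box cross-section / lipids per leaflet.

    Returns per-leaflet APLs (nm²) for the requested subset (default all
    leaflets) and their mean.
    """
    area = frame.box[0] * frame.box[1]
    if area <= 0:
        raise MetricsError("box cross-sectional area must be > 0")
    counts = leaflets.counts()
    subset = list(range(leaflets.n_leaflets)) if subset is None else list(subset)
    vals = []
    for i in subset:
        if counts[i] == 0:
            raise MetricsError(f"leaflet {i} is empty")
        vals.append(area / counts[i])
    vals = np.array(vals)
    return vals, float(vals.mean())


def nla(apl_value: float, spec: CompositionSpec) -> float:
    """Normalized lipid area: APL / mean effective tails of the mixture."""
    return apl_value / mean_effective_tails(spec)


# ---------------------------------------------------------------------------
# density profiles, thickness, interdigitation
# ---------------------------------------------------------------------------


@dataclass
class DensityProfile:
    """Mass density (amu/nm³) vs z (nm) for a selection, frame-averaged."""

    z: np.ndarray  # bin centres, spanning [0, Lz]
    density: np.ndarray
    bin_width: float
    area: float  # box cross-section nm²
    label: str = ""
    n_frames: int = 1

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise MetricsError("negative density")

    @property
    def total_mass(self) -> float:
        """∫ ρ·A dz (amu) — closes on the selection mass."""
        return float(self.density.sum() * self.bin_width * self.area)


def density_profile(
    frames: CGFrame | Iterable[CGFrame],
    mask: np.ndarray | None = None,
    bin_width: float = 0.1,
    label: str = "",
) -> DensityProfile:
    """Mass histogram along z divided by bin volume, averaged over frames.

    ``mask`` selects beads (same mask applied to every frame); z is wrapped
    into [0, Lz).
    """
    if isinstance(frames, CGFrame):
        frames = [frames]
    frames = list(frames)
    box = frames[0].box
    n_bins = max(int(round(box[2] / bin_width)), 1)
    edges = np.linspace(0.0, box[2], n_bins + 1)
    h = edges[1] - edges[0]
    area = box[0] * box[1]
    acc = np.zeros(n_bins)
    for fr in frames:
        m = np.ones(fr.n_beads, dtype=bool) if mask is None else mask
        if not m.any():
            raise MetricsError("empty selection for density profile")
        zw = np.mod(fr.positions[m, 2], box[2])
        hist, _ = np.histogram(zw, bins=edges, weights=fr.bead_masses()[m])
        acc += hist
    density = acc / (len(frames) * area * h)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, density, h, area, label=label, n_frames=len(frames))


def _refine_peak(z: np.ndarray, y: np.ndarray, i: int) -> float:
    """3-point parabolic interpolation of a peak position."""
    if i == 0 or i == len(y) - 1:
        return float(z[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(z[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(z[i] + delta * (z[1] - z[0]))


def thickness(profile: DensityProfile, min_prominence: float = 0.05) -> float:
    """Peak-to-peak distance (nm) between the two dominant density peaks
    flanking the midplane (the profile's mass-weighted centre).

    Peak positions are refined by 3-point parabolic interpolation.
    """
    from scipy.signal import find_peaks

    y = profile.density
    if y.sum() <= 0:
        raise MetricsError("empty profile")
    peaks, _ = find_peaks(y, prominence=min_prominence * y.max())
    if len(peaks) < 2:
        raise MetricsError(f"need >= 2 density peaks, found {len(peaks)}")
    center = float(np.sum(profile.z * y) / y.sum())
    below = [p for p in peaks if profile.z[p] < center]
    above = [p for p in peaks if profile.z[p] >= center]
    if not below or not above:
        raise MetricsError("no density peak on one side of the midplane")
    p_lo = max(below, key=lambda p: y[p])
    p_hi = max(above, key=lambda p: y[p])
    z_lo = _refine_peak(profile.z, y, p_lo)
    z_hi = _refine_peak(profile.z, y, p_hi)
    return z_hi - z_lo


def interdigitation(rho_top: DensityProfile, rho_bot: DensityProfile) -> float:
    """Overlap length λ = 4∫ ρ_top ρ_bot / (ρ_top + ρ_bot)² dz (nm).

    The integrand is defined as 0 wherever both densities vanish.
    """
    if rho_top.z.shape != rho_bot.z.shape or not np.allclose(rho_top.z, rho_bot.z):
        raise MetricsError("density profiles are on different z grids")
    a, b = rho_top.density, rho_bot.density
    s = a + b
    integrand = np.zeros_like(a)
    nz = s > 0
    integrand[nz] = 4.0 * a[nz] * b[nz] / s[nz] ** 2
    return float(np.trapezoid(integrand, rho_top.z))


# ---------------------------------------------------------------------------
# directors: tilt and nematic order
# ---------------------------------------------------------------------------


def _min_inertia_axis(pos: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the minimum eigenvalue of the inertia tensor."""
    com = np.average(pos, axis=0, weights=masses)
    r = pos - com
    inertia = float(np.sum(masses * np.sum(r**2, axis=1))) * np.eye(3) - np.einsum(
        "i,ij,ik->jk", masses, r, r
    )
    w, v = np.linalg.eigh(inertia)
    return v[:, 0]


def lipid_directors(
    frame: CGFrame,
    subset_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lipid directors: the minimum-inertia axis of the tail beads.

    The sign points from the headgroup centre toward the tail centre.
    Lipids with fewer than 2 tail beads are excluded with a warning.
    Returns (molecule ids, unit directors).
    """
    tail = _role_mask(frame, "tail")
    head = _role_mask(frame, "headgroup")
    lipid = _lipid_mask(frame)
    wanted = None if subset_ids is None else set(np.asarray(subset_ids).tolist())
    ids, dirs = [], []
    masses = frame.bead_masses()
    for mid, _sp, rows in frame.molecules():
        if not lipid[rows[0]]:
            continue
        if wanted is not None and mid not in wanted:
            continue
        trows = rows[tail[rows]]
        if len(trows) < 2:
            warnings.warn(f"lipid {mid}: fewer than 2 tail beads; excluded from directors")
            continue
        u = _min_inertia_axis(frame.positions[trows], masses[trows])
        hrows = rows[head[rows]]
        if len(hrows):
            away = frame.positions[trows].mean(axis=0) - frame.positions[hrows].mean(axis=0)
            if np.dot(u, away) < 0:
                u = -u
        ids.append(mid)
        dirs.append(u)
    if not ids:
        raise MetricsError("no lipids with directors in selection")
    return np.array(ids), np.array(dirs)


def tilt_angles(
    frame: CGFrame,
    subset_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lipid tilt: angle between the z axis and the tail director,
    folded to [0°, 90°] (director symmetry).  Returns (ids, degrees)."""
    ids, dirs = lipid_directors(frame, subset_ids=subset_ids)
    ang = np.degrees(np.arccos(np.clip(np.abs(dirs[:, 2]), 0.0, 1.0)))
    return ids, ang


def nematic_order(directors: np.ndarray) -> float:
    """S2: largest eigenvalue of Q = (3/2)⟨u⊗u⟩ − I/2 over directors."""
    u = np.asarray(directors, dtype=float)
    if u.ndim != 2 or u.shape[0] < 2:
        raise MetricsError("need at least 2 directors")
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    q = 1.5 * (u[:, :, None] * u[:, None, :]).mean(axis=0) - 0.5 * np.eye(3)
    return float(np.linalg.eigvalsh(q)[-1])


# ---------------------------------------------------------------------------
# ceramide conformation and hydration
# ---------------------------------------------------------------------------


def extended_fraction(
    frame: CGFrame,
    registry: Mapping[str, MoleculeTemplate],
    subset_ids: np.ndarray | None = None,
) -> float:
    """Percentage of ceramides in the extended (tail-splayed) conformation.

    Each tail's directional vector runs from its attachment bead (first
    chain bead) to the chain's centre of mass; a ceramide is extended when
    the two vectors subtend more than 90°.  Non-two-chain species in the
    selection raise.
    """
    masses = frame.bead_masses()
    wanted = None if subset_ids is None else set(np.asarray(subset_ids).tolist())
    n_cer = n_ext = 0
    for mid, sp, rows in frame.molecules():
        if wanted is None:
            # implicit selection: every ceramide in the frame
            if not sp.startswith("CER"):
                continue
        else:
            if mid not in wanted:
                continue
            if not sp.startswith("CER"):
                raise MetricsError(f"molecule {mid} ({sp}) is not a ceramide")
        t = registry[sp]
        if len(t.chains) != 2:
            raise MetricsError(f"{sp}: extended conformation needs exactly 2 chains")
        vecs = []
        for chain in t.chains.values():
            crows = rows[np.array(chain)]
            com = np.average(frame.positions[crows], axis=0, weights=masses[crows])
            vecs.append(com - frame.positions[crows[0]])
        c = np.dot(vecs[0], vecs[1]) / (np.linalg.norm(vecs[0]) * np.linalg.norm(vecs[1]))
        n_cer += 1
        if np.degrees(np.arccos(np.clip(c, -1.0, 1.0))) > 90.0:
            n_ext += 1
    if n_cer == 0:
        raise MetricsError("no ceramides in selection")
    return 100.0 * n_ext / n_cer


def water_per_lipid(
    frame: CGFrame,
    z_lo: float,
    z_hi: float,
    n_lipids: int,
    waters_per_bead: float = 4.0,
) -> float:
    """Water molecules per lipid between two leaflet headgroup planes."""
    if not z_hi > z_lo:
        raise MetricsError("undefined region: z_hi must exceed z_lo")
    if n_lipids <= 0:
        raise MetricsError("n_lipids must be > 0")
    w = _role_mask(frame, "water")
    z = frame.positions[w, 2]
    inside = int(np.count_nonzero((z > z_lo) & (z < z_hi)))
    return waters_per_bead * inside / n_lipids


# ---------------------------------------------------------------------------
# per-frame analysis and aggregation
# ---------------------------------------------------------------------------


def analyze_frame(
    frame: CGFrame,
    spec: CompositionSpec,
    registry: Mapping[str, MoleculeTemplate],
    bin_width: float = 0.1,
    min_gap: float = 0.3,
) -> dict:
    """All structural metrics for one frame.

    Bilayers use both leaflets for every metric.  Six-leaflet multilayers
    follow the reporting convention of the self-assembly study: APL, NLA
    and extended fraction over the four inner leaflets; tilt, thickness,
    S2, interdigitation and hydration for the central leaflet pair.
    """
    leaflets = assign_leaflets(frame, spec.n_leaflets, min_gap=min_gap)
    inner = leaflets.inner_leaflets if spec.n_leaflets > 2 else [0, 1]
    pair = leaflets.central_pair

    _, apl_mean = apl(frame, leaflets, subset=inner)
    rec: dict = {
        "apl": apl_mean,
        "nla": nla(apl_mean, spec),
    }

    pair_ids = leaflets.lipids_in(pair)
    pair_bead_mask = np.isin(frame.mol_ids, pair_ids)
    profile = density_profile(frame, mask=pair_bead_mask, bin_width=bin_width)
    rec["thickness"] = thickness(profile)

    ids, angles = tilt_angles(frame, subset_ids=pair_ids)
    rec["tilt_mean"] = float(angles.mean())
    # per-leaflet groups for pooled-variance aggregation
    lf_of = dict(zip(leaflets.lipid_ids.tolist(), leaflets.leaflet_index.tolist()))
    groups = []
    for lf in pair:
        a = angles[np.array([lf_of[i] == lf for i in ids])]
        if len(a) > 1:
            groups.append((len(a), float(a.mean()), float(a.var(ddof=1))))
    rec["tilt_groups"] = groups

    _, dirs = lipid_directors(frame, subset_ids=pair_ids)
    rec["s2"] = nematic_order(dirs)

    # interdigitation: split central-pair lipids top/bottom by headgroup z
    # relative to the pair midpoint (recomputed per frame)
    mid_z = float(leaflets.leaflet_z[list(pair)].mean())
    bot_ids = leaflets.lipids_in(pair[0])
    top_ids = leaflets.lipids_in(pair[1])
    rho_bot = density_profile(
        frame, mask=np.isin(frame.mol_ids, bot_ids), bin_width=bin_width, label="bottom"
    )
    rho_top = density_profile(
        frame, mask=np.isin(frame.mol_ids, top_ids), bin_width=bin_width, label="top"
    )
    rec["interdigitation"] = interdigitation(rho_top, rho_bot)

    inner_ids = leaflets.lipids_in(inner)
    cer_mask = np.array(
        [sp.startswith("CER") for sp in frame.mol_species]
    ) & np.isin(frame.mol_ids, inner_ids)
    cer_ids = np.unique(frame.mol_ids[cer_mask])
    if len(cer_ids):
        rec["extended_pct"] = extended_fraction(frame, registry, subset_ids=cer_ids)
    else:
        rec["extended_pct"] = float("nan")

    z_pair = np.sort(leaflets.leaflet_z[list(pair)])
    rec["water_per_lipid"] = water_per_lipid(frame, z_pair[0], z_pair[1], len(pair_ids))
    rec["midplane_z"] = mid_z
    return rec


@dataclass
class StructureReport:
    """Aggregated structural metrics with replicate statistics."""

    per_frame: pd.DataFrame  # one row per frame (replicate, metrics)
    mean: dict[str, float]
    sd: dict[str, float | None]  # replicate SD; None with a single replicate
    tilt_sd_pooled: float | None  # pooled per-molecule SD

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, v in self.mean.items():
            rows.append({"metric": k, "mean": v, "sd": self.sd.get(k)})
        return pd.DataFrame(rows)


_SCALAR_METRICS = (
    "apl",
    "nla",
    "tilt_mean",
    "thickness",
    "s2",
    "interdigitation",
    "extended_pct",
    "water_per_lipid",
)


def aggregate(frame_records: Sequence[dict], replicates: Sequence | None = None) -> StructureReport:
    """Average leaflet→frame→replicate and attach replicate SDs.

    ``replicates`` labels each frame record; frames sharing a label are
    averaged first, then the replicate means are averaged.  SDs are the
    (ddof=1) spread across replicate means, reported as None when only a
    single replicate is present — except tilt, whose spread is the pooled
    per-molecule variance across all leaflets, frames and replicates.
    """
    if not frame_records:
        raise MetricsError("no frames to aggregate")
    if replicates is None:
        replicates = [0] * len(frame_records)
    if len(replicates) != len(frame_records):
        raise MetricsError("replicate labels must match the frame count")
    df = pd.DataFrame(
        [
            {**{k: r.get(k, np.nan) for k in _SCALAR_METRICS}, "replicate": lab}
            for r, lab in zip(frame_records, replicates)
        ]
    )
    rep_means = df.groupby("replicate").mean()
    mean = {k: float(rep_means[k].mean()) for k in _SCALAR_METRICS if not rep_means[k].isna().all()}
    n_rep = len(rep_means)
    sd: dict[str, float | None] = {}
    for k in mean:
        sd[k] = float(rep_means[k].std(ddof=1)) if n_rep > 1 else None

    # pooled per-molecule tilt variance across all (leaflet, frame, replicate)
    num = den = 0.0
    for r in frame_records:
        for n, _m, v in r.get("tilt_groups", []):
            num += (n - 1) * v
            den += n - 1
    tilt_sd = float(np.sqrt(num / den)) if den > 0 else None
    if tilt_sd is not None:
        sd["tilt_mean"] = tilt_sd
    return StructureReport(per_frame=df, mean=mean, sd=sd, tilt_sd_pooled=tilt_sd)
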