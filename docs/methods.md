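# Methods

## Scope and model

`cglamella` implements the computational machinery around a
coarse-grained (CG) model family for stratum-corneum (SC) lipids:
ceramides NS, NP, AS and AP (24-carbon acyl chain, 18-carbon sphingoid
base), cholesterol (CHOL), lignoceric acid (FFA C24) and 4:1 mapped
water.  It covers four layers of that machinery:

1. **Topology** — bead types and molecule templates, with explicit
   per-bead chemical formulas.
2. **Forward mapping** — atomistic frames to CG beads (mass-weighted
   group centres) and harvesting of bond/angle samples.
3. **Boltzmann inversion** — Gaussian fits of bonded distributions and
   conversion of widths to harmonic force constants.
4. **Structure metrics** — the gel-phase lamellar property suite (APL,
   NLA, thickness, tilt, S₂, interdigitation, extended-conformation
   fraction, hydration) with leaflet → frame → replicate averaging,
   plus protocol arithmetic for the self-assembly schedule.

Molecular dynamics itself (atomistic or CG), nonbonded-potential
optimization (MS-IBI) and hydrogen-bond analysis are out of scope: the
package analyses configurations, it does not produce trajectories.

## CG mapping conventions

Alkyl chains map 3 carbons per TAIL bead; a chain whose carbon count
leaves remainder 2 ends in a 2-carbon TER2 bead, remainder 1 is
unmappable.  The ceramide headgroup maps to MHEAD2 (backbone C1–C3),
AMIDE (N–H plus the acyl carbonyl C=O), and one bead per hydroxyl
(OH1: C1-OH, OH2: C3-OH, OH3: phytosphingosine C4-OH, OH4: α-hydroxy
C2′-OH).  Counting the carbonyl carbon in AMIDE makes the 24-carbon
acyl chain map to 7×TAIL + TER2; keeping C1–C3 in MHEAD2 leaves the
18-carbon sphingoid base as 5×TAIL, terminating in a TAIL bead under
the 3:1 rule.  One W bead represents four water molecules
(4 × 18.015 = 72.06 amu from standard atomic masses).

Published mapping diagrams are pictorial; the per-bead atom tables in
`topology.py` are therefore the package's single source of truth.  Each
bead records the chemical formula of its atom group, and the per-species
formulas sum exactly to the molecular formulas (CER NS C₄₂H₈₃NO₃,
NP C₄₂H₈₅NO₄, AS C₄₂H₈₃NO₄, AP C₄₂H₈₅NO₅, FFA C₂₄H₄₈O₂, CHOL C₂₇H₄₆O),
so template masses close on the molecular masses to < 0.01 amu by
construction.  The cholesterol body partition (CHEAD + three ring + two
tail beads) is inherited from earlier CG cholesterol work; the per-bead
hydrogen counts there are bookkeeping, not resolved structure.

Forward mapping uses mass-weighted (not geometric) centres, which makes
the map conserve total mass and the system centre of mass — the
invariants the density profiles rely on.  Water "dynamic mapping" is
realized as greedy nearest-neighbour clustering (seed the lowest-index
unassigned water, absorb its three nearest unassigned neighbours); the
clustering objective is a documented implementation choice, since only
the 4:1 ratio is physically prescribed.

## Boltzmann inversion

A harmonic bonded term k(x−x₀)²/2 at temperature T yields a Gaussian
coordinate distribution y ∝ exp[−k(x−x₀)²/(2k_BT)], so σ² = k_BT/k and

    k = k_B T / σ²,     k_B = 0.0019872041 kcal/(mol·K).

The width is estimated by a least-squares Gaussian fit to the binned
density, seeded by sample moments.  The fit model is the **bin-averaged**
Gaussian (erf differences), so the fitted σ does not inherit the h²/12
histogram broadening — at the default bin widths (0.01 Å bonds, 1°
angles) a naive fit of the stiffest bond term (σ ≈ 0.033 Å) would
otherwise bias k by ≈ 1.5%.  k is taken from the fitted variance rather
than from log-density regression: exact for a true Gaussian and robust
to tail noise.  Angle distributions are fitted as plain Gaussians in
degrees without a sin θ Jacobian, matching the plain-Gaussian harmonic
form; angle force constants are reported in kcal/(mol·rad²) (widths are
converted to radians before inversion — the published tables do not
print angle units, so this is recorded as an assumption).

Multimodality (seen in mapped atomistic distributions for the TAIL–OH4
bond and for the MHEAD2–TAIL–OH3 and TAIL–TAIL–OH4 angles) is detected
by peak search on a lightly smoothed density (2-bin Gaussian kernel,
second peak prominence > 20% of the maximum).  Flagged terms keep the
single-Gaussian compromise fit — multi-harmonic fitting is deliberately
not offered, trading fidelity of the bimodal shape for CG simulation
speed, as is standard for these models.  Smoothing is used for peak
detection only, never for fitting.  Terms backed by fewer than 100
samples are excluded with a warning; zero-variance input is an error.

## Structure metrics

All metrics consume `CGFrame` objects (bead positions, types, molecule
ids, orthorhombic periodic box) and assume the lamella is normal to z
and not wrapped across the z boundary.

* **Leaflets** — per-lipid mean headgroup z, sorted and split at gaps
  larger than `min_gap` (0.3 nm default).  This sorted-gap clustering is
  exact for the well-separated planes of gel-phase lamellae and fully
  deterministic; if the number of clusters found differs from the
  request (disordered systems), the error carries the found count.  In
  six-leaflet stacks the "inner" subset excludes the two outermost
  leaflets; the central pair is the middle two.
* **APL** — box cross-section divided by lipids per leaflet, averaged
  over the requested leaflets.  **NLA** — APL divided by the
  mole-fraction-weighted mean effective tail count (FFA 1, CER 2,
  CHOL 1.9); for the 1:0.5:1 CER:CHOL:FFA mixture this mean is 1.58.
  NLA is computed per frame from the frame APL and then averaged.
* **Thickness** — peak-to-peak distance of the two dominant mass-density
  peaks flanking the profile's mass-weighted centre, with 3-point
  parabolic peak refinement; default bin width 0.1 nm.  The total mass
  density of the selection is used (headgroup-only profiles are easy to
  form by masking but are not the default).
* **Tilt** — per lipid, the angle between z and the eigenvector of the
  minimum eigenvalue of the tail-bead inertia tensor, folded to
  [0°, 90°] (director symmetry).  The same minimum-inertia axis, sign
  pointed away from the headgroup, serves as the molecular director for
  **S₂**, the largest eigenvalue of Q = (3/2)⟨u⊗u⟩ − I/2.
* **Interdigitation** — λ = 4∫ρ_top ρ_bot/(ρ_top+ρ_bot)² dz by
  trapezoidal integration over the box, integrand zero where both
  densities vanish.  Top/bottom are the central-pair lipids with
  headgroups above/below the pair midpoint, recomputed per frame.
* **Extended fraction** — a ceramide is extended when its two tail
  directional vectors (first chain bead → chain centre of mass) subtend
  more than 90°.  The first-tail-bead anchor is a documented choice; the
  headgroup-bead variant differs only for strongly bent headgroups.
* **Hydration** — 4 × (W beads between the pair's headgroup planes) per
  lipid in the pair.
* **Aggregation** — leaflet → frame → replicate averaging; the reported
  spread is the SD across replicate means (absent, not zero, for a
  single replicate) for every metric except tilt, whose spread is the
  standard pooled per-molecule variance across all (leaflet, frame,
  replicate) groups.

## Synthetic ground truth

The generator builds idealized gel-phase lamellae: lipids on a hexagonal
in-plane lattice inside a box whose cross-section is exactly
APL × lipids-per-leaflet, straight chains at a uniform tilt (mirrored
between opposing leaflets), headgroup beads exactly on the leaflet
planes, Gaussian positional noise, and water slabs only at the outer
faces (inner leaflets of a multilayer see no bulk water).  Three
constructions make the ground truth exact rather than approximate:

* Both ceramide chains anchor on one axis — a perpendicular offset
  between the unequal-length chains would rotate the minimum-inertia
  axis off the intended tilt.
* Each chain carries a coherent uniform phase jitter of one bead rise
  along its own axis.  Across many lipids this convolves the bead comb
  into an exactly flat density slab with sharp edges half a rise beyond
  the terminal bead plane, without touching the chain direction.  The
  per-bead rise is then derived from the requested pair thickness t and
  midplane overlap w so the 8-bead chains' slab edge lands exactly w/2
  past the pair midplane: rise = (t/2 − 0.25 + w/2)/7.5 nm.  Opposing
  slabs are equal and flat in the overlap, so the measured λ ≈ w (edge
  smearing of order the noise σ plus one profile bin remains; for
  w ≲ 0.4 nm that residual is no longer small against w).
* Extended ceramides are placed by exact count per leaflet (acyl chain
  reflected through the headgroup plane), so the extended fraction is
  recovered exactly, not statistically.

Recorded truth values: APL and extended fraction are exact; thickness
is the headgroup plane separation; λ is the constructed overlap; tilt
is the chain angle; S₂ = (3cos²θ − 1)/2 for the mirrored ±θ director
set.  Known interactions: combining nonzero tilt with a nonzero extended
fraction skews the inertia axes of splayed molecules (two antiparallel
chains at ±θ), so tilt truth is only quoted for recipes with one of the
two at zero — the validation recipes respect this.

What the generator does **not** emulate: thermal chain disorder
(gauche defects, per-lipid tilt spread), azimuthal tilt disorder,
headgroup roughness, partial water penetration, and any energetics.
Passing recovery tests therefore demonstrates the correctness of the
metric implementations on configurations with known answers, not the
physical accuracy of any force field.

## Default study conditions

Defaults mirror the simulated systems the suite is meant to analyse:
305 K; CER:CHOL:FFA ratio 1:0.5:1 (half-equimolar CHOL, the composition
that avoids CHOL phase separation); 500 lipids for pure-CER bilayers and
1800 for mixtures and six-leaflet multilayers; 10 CG water beads per
lipid (40 water molecules per lipid); APL 0.40 nm² (pure, gel phase)
/ 0.34 nm² (mixtures); leaflet-pair thickness 5.3 nm; tilt 0–15°;
interdigitation overlap 0.8 nm; extended fraction 30%; positional noise
σ = 0.03 nm (small against the 0.1 nm profile bin, large enough to
decorrelate lattice artefacts).  Validation suites run in seconds at
these sizes.

## Protocol arithmetic

The self-assembly schedule is emitted as data: initial box from lipid
volume at 0.8 g/cm³ plus water at 1.0 g/cm³ over the target
cross-section; A_est = APL_est·N_lipids/N_leaflets (APL_est 0.34 nm²,
raised to 0.44 nm² for pure AS/AP multilayers to avoid eight-leaflet
formation); NVT expansion to 2.5·A_est over 150 ns at 500 K; NVT
compression back to A_est with a linear 500→305 K ramp over 150 ns;
NPT heating 305→400 K (100 ns) and cooling back (50 ns); 150 ns NPT
production at 305 K and 1 bar.  The equilibration preludes (two 10 ps
NVE runs, 10 ns NPT) are listed as phases but not counted in the 600 ns
anneal-plus-production total; the NVE displacement cap (~0.1 Å/step) is
engine-specific and appears as an annotation only.

## Numerical choices and limitations

* Histogram defaults: 0.01 Å (bonds), 1° (angles), 0.1 nm (density).
* Ratio-to-count rounding: largest remainder, hard error beyond one
  lipid of drift per species.
* Degenerate inputs raise rather than return NaN: zero-variance
  samples, empty selections, single-peak profiles, leaflet-count
  mismatches (the latter carrying the found count).
* Interdigitation accuracy on synthetic frames degrades for overlaps
  comparable to the edge-smearing scale (noise σ + one bin); validation
  uses w = 0.8 nm.
* The CG frame text format is the only serialization; it is lossless
  for positions to 10⁻⁶ nm and carries per-bead masses.
* The atomistic reader goes through MDAnalysis (PDB/GRO topology,
  XTC/DCD trajectories) and is an optional dependency; all core
  functionality operates on in-memory frames.
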