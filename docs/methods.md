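# Methods

This note documents the models, conventions and numerical choices behind
`ccorigami`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The Crick coiled-coil model

A coiled-coil helix is generated as a minor α-helix (radius `r1`, frequency
`w1` deg/residue, phase `phi1`) wound around a superhelical axis (radius `r0`,
frequency `w0` deg/residue, phase `phi0`) with an axial rise per residue
`rise`. All angles are degrees. Canonical left-handed dimer values are used
as defaults throughout: `r0 = 4.9 Å`, `w0 = −3.6°/res`, `r1 = 2.26 Å`,
`w1 = 102.857°/res` (= 720/7, two turns per heptad), `rise = 1.51 Å`. With
these values consecutive Cα are ≈3.8 Å apart.

Phase convention: minor phase 0 points radially **outward** from the
superhelical axis. Heptad position *a* is anchored at 180° + 360/14° so that
positions *a* and *d* straddle the inward (dimer-interface) direction — the
geometric statement of hydrophobic-core packing. A dimer's second helix is
the first rotated 180° about the superhelical axis, with its own minor phase.

### Fitting

`fit_crick` estimates the superhelix frame from the window-7 centroid
polyline of the pooled chains, then refines all parameters (plus a rigid
frame correction) by Levenberg–Marquardt least squares, multi-started over a
90°-grid of minor phases. Two gauge freedoms are inherent and documented
rather than suppressed:

- rotation about the fitted axis trades against `phi0`, so only `phi1`,
  `r0`, `w0`, `r1`, `w1` and `rise` are identifiable from coordinates;
- at `r0 = 0` the superhelical and minor frequencies act through their sum
  only, so a straight helix constrains `w0 + w1`, not each separately.

On exact synthetic dimers the fit recovers all identifiable parameters to
better than 1e-3 relative with residual RMSD < 1e-6 Å. With 0.3 Å Gaussian
coordinate noise the expected residual is ≈ σ√3 ≈ 0.52 Å minus what the
model's degrees of freedom absorb; the measured value is ≈ 0.45–0.48 Å and
parameters stay within 5%.

## The synthetic triangle builder

The builder is the package's stand-in for the crystal structure of the
triangular origami and defines the study conditions used by the tests and
the acceptance script:

- three parallel CC dimers on the edges of a triangle with measured edge
  lengths 47 / 34 / 47 Å (the GCN homodimer on the short edge);
- chain order P1 → GCN-a → P4 → P2 → GCN-b → P3, i.e. the chain traverses
  the triangle contour **twice**, placing the two helices of each dimer
  three segments apart;
- GSG linkers (five of them) between consecutive segments;
- segment lengths `n = round(L/rise) + 7` so that the window-7-trimmed dimer
  axis equals the requested edge length `L` (the window trims 3 residues per
  end, hence the +7).

**Knotted fold.** Each edge is modelled as a tube of radius `r0` around the
edge midline. Along every segment the dimer pair plane rotates by 180°
(a supercoil of the dimer about the edge), so each helix axis crosses the
triangle plane and successive segments alternate between packing on the
inner and the outer side of the triangle. Over six segments the tube phase
advances by 3×360° while the chain loops the contour twice — a (2,3) torus
curve, i.e. a trefoil. This is a geometric statement, so the knot call is
stable under ±10% parameter jitter (tested).

**Planar control.** The unknotted control keeps every helix axis in the
triangle plane. An in-plane chain that still *alternates* inner/outer
necessarily weaves over/under at the vertices and is not topologically
trivial (empirically it closes into a higher torus knot); the genuinely
trivial in-plane arrangement is the **nested** one — first pass on the inner
ring, second pass on the outer ring — and that is what
`default_topology(plane_crossing=False)` builds.

Practical geometry: segments are inset 5.5 Å from the vertices and the first
and last sweeps are phase-trimmed by 25° so termini do not collide; linkers
follow circular arcs (uniform ≈3.2 Å spacing) bulging away from the
centroid; a single C-terminal glycine cap steps back toward the N terminus,
reproducing the near-cyclic closeness of the designed termini. The built
chain has no non-consecutive Cα–Cα contact under 3.0 Å.

The models are Cα-only. Analyses that need side chains (knobs-into-holes,
hydrogen bonds) are exercised on two-chain dimer fixtures carrying stub
side-chain centroids placed 2.0 Å outside the Cα, directed away from the
minor-helix axis — roughly where a side-chain centroid sits on an ideal
helix.

What the builder does *not* emulate: real side-chain packing and rotamers,
sequence-specific interactions, linker disorder, crystal-environment
deformations. Tests passing on builder output therefore validate the
geometry, register and topology machinery, not side-chain-level predictions
about real crystals.

## Heptad registers and knobs-into-holes

A knob is a residue whose side-chain centroid lies within the packing cutoff
(default 7.0 Å, the SOCKET convention) of at least four partner side-chain
centroids; those four nearest partners are the hole. Register assignment
offers two routes that agree on ideal dimers: (i) anchoring knobs to
positions *a*/*d* — the 3,4,3,4 knob spacing fixes the offset uniquely — and
(ii) binning each residue's fitted minor phase to the nearest canonical
letter phase. Ties take the lowest offset.

Helicity is a Cα-only criterion (not DSSP): residue windows with i→i+3
distance in [4.5, 6.0] Å and per-residue twist about the local axis in
[85°, 115°] count as helical.

## Knot analysis

Open chains are closed through a sphere of 10× the maximal extent:
deterministically (both termini extended radially from the centroid, joined
by a great-circle arc — the default) or stochastically (both termini
extended in parallel along a uniformly random direction, 100 votes,
seeded). The closed curve is simplified by KMT triangle elimination
(a vertex is deleted when no other segment pierces its triangle) and
classified by the Alexander determinant |Δ(−1)| computed exactly (integer
Bareiss elimination) from the crossing diagram of a generic projection;
degenerate projections are detected and re-randomized. At t = −1 the
crossing sign drops out of the Alexander matrix, which is why the
determinant — 1 (unknot), 3 (trefoil), 5 (figure-eight), reported
numerically otherwise — cannot resolve chirality.

Knot depth is the minimal number of residues trimmed from one terminus that
unties the chain (coarse stride 5, refined to single residues); the knotted
core is the minimal subchain interval that remains knotted under the same
closure. Both depend on the closure convention, which is stated here because
"depth" has no closure-free definition for open chains. On the built
triangle the depth is ≈9% of the chain and the core spans both passes of the
contour — removing an entire terminal segment unties it.

Random-closure agreement on the built triangle is ≈86–92% depending on the
vote seed (92% at seed 0, the documented condition); the residual ambiguity
comes from closure ribbons that straddle the strands converging at the
terminal vertex, which is expected for a shallow knot.

## Geometry

Edge length: window-7 centroid polyline of the pooled (index-paired) dimer
Cα; length = first-to-last axis-point distance. Pooling the two antipodal
helices puts the axis on the edge midline, so the measure is insensitive to
the supercoil.

Cavity area: heavy atoms are projected on the best-fit plane of all Cα and
drawn as disks of radius vdW + 1.4 Å on a 0.5 Å grid; the cavity is the
empty region not connected to the exterior (flood fill from the border).
The cavity is reported as a projected 2-D area because that is the natural
measure for a planar ring-shaped fold; rotation invariance holds to grid
tolerance.

Contacts: hydrogen bonds use donor–acceptor heavy-atom distance ≤ 3.5 Å
plus a D–A–antecedent angle ≥ 90° as the hydrogen-free proxy (crystal
structures at ~2 Å carry no hydrogens); salt bridges use side-chain
N⁺···O⁻ ≤ 4.0 Å. Vertices are defined combinatorially as unordered pairs of
dimers, not spatial spheres; intra-dimer contacts are excluded. On Cα-only
models the vertex inventory degrades to proximity records (≤ 6 Å).

## Crystal packing

Only space group P1 is supported, by design: the deposited crystal form of
the triangle is P1 and all symmetry mates are pure lattice translations.
Neighbors are enumerated over ±1 cell (configurable), retained when the
buried area [sasa(A)+sasa(B)−sasa(A∪B)]/2 exceeds 10 Å². SASA is
Shrake–Rupley with a deterministic golden-spiral point set (960 points;
self-converged to <2% against 4000 points). Interfaces pair t with −t;
an interface is heterologous when the two contacting residue sets differ.
Matthews coefficient Vm = V_cell/(mass·Z) in Å³/Da and solvent fraction
1 − 1.23/Vm (standard protein partial specific volume convention, stated so
the solvent-content check is reproducible).

## SAXS

Debye sum over one scatterer per residue (Cα position, weight = residue
electron count), blocked over q to bound memory. No hydration layer or
excluded-volume term is included, so χ² against a *measured* curve is not
comparable to CRYSOL-class models; the module's contract is internal
consistency (I(0) = (Σf)², Guinier Rg within a few percent of the direct
Rg) and the fitting algebra (closed-form scale, reduced χ²). Model curves
are interpolated linearly onto the experimental grid; extrapolation is
refused.

## Problem sizes and tolerances

The test suite and acceptance script run entirely on synthetic inputs:
a 228-residue triangle, 28–35-residue dimers, 60–120-point parametric
curves, 100 closure votes. Knot-matrix scans default to stride 5. Numerical
tolerances used in tests reflect the mechanisms above: 1e-3 relative for
exact Crick round trips, 5% for σ=0.3 Å noisy recovery, 10% for the
analytic cavity fixture (grid discretization), 2% SASA self-convergence.

## Known limitations

- Checks against the deposited crystal entry and the designed sequence
  require those inputs locally (`data/`); they are not redistributed with
  the package and the corresponding acceptance tests fail until provided.
- The Alexander determinant does not distinguish knots with equal |Δ(−1)|
  and is blind to chirality; for the trefoil-vs-unknot question this is
  sufficient.
- Knot depth/core values are closure-convention dependent.
- The Crick fit assumes a shared straight superhelical axis per dimer;
  strongly bent dimers (as on the swept triangle edges) are summarized by
  an effective fit with a correspondingly larger residual.
- `average_mass` uses average (not monoisotopic) masses, matching how
  solution molecular weights are quoted.
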