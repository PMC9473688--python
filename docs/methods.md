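# Methods

## The rotation-angle statistic

Two porphyrin rings are compared through the 25 non-hydrogen atoms of the
porphyrin core — Fe, the four pyrrole nitrogens NA–ND, the sixteen pyrrole
carbons C1A–C4D and the four methine bridges CHA–CHD — in a fixed canonical
order.  Vinyl and propionate substituents are excluded: they are flexible
and would blur an orientation statistic that is about the rigid aromatic
plane.  Correspondence between two rings is by atom *name*, never by
nearest neighbour: the four pyrrole rings are chemically distinct, so
name-matching breaks the geometric 4-fold pseudo-symmetry of the porphyrin
and makes the superposition rotation unique.

Ring A is superposed onto ring B by least squares (Kabsch, SVD form, with
the determinant correction so only proper rotations are returned; a
collinear point set raises — it cannot occur for a real porphyrin).  The
rotation angle is

θ = arccos((tr **R** − 1)/2), θ ∈ [0°, 180°],

with the argument clamped to [−1, 1].  Numerically the same quantity is
evaluated as atan2(‖**R** − **R**ᵀ‖_F / (2√2), (tr **R** − 1)/2), which is
exact on [0°, 180°] and avoids the precision loss of arccos near its
endpoints (arccos alone costs ~1e−6 degrees of accuracy at θ ≈ 0°, the
atan2 form keeps ~1e−13).  θ is symmetric in the pair (the angle of **R**
and **R**ᵀ coincide) and invariant under any common rigid transform; both
properties are asserted in the test suite.

Edge-to-edge distance is the minimum over the 625 atom–atom distances of
the two cores, regardless of atom type.  Fe can never realize the minimum
but is kept so a single atom set serves both the distance and the
superposition.  Contact pairs use a 6 Å cutoff on this minimum; the same
cutoff feeds the topology graph.  Whether reported contact filters in the
literature include substituent atoms is usually unstated; this package
uses ring atoms only, so pair sets may differ at the margin for structures
where only a propionate crosses the cutoff.

### Motif classification

Fig-style qualitative clusters are discretized as: parallel θ < 40°,
antiparallel θ > 140°, T-shaped when the angle between ring-plane normals
lies in [60°, 120°], otherwise intermediate.  The θ thresholds are this
package's own choice of boundaries for clusters that are conventionally
drawn, not numerically defined; they should not be treated as published
values.  The plane normal is the smallest right-singular vector of the 24
centred non-Fe atoms, signed along (NA→C1A) × (NA→C1B).

### Pruned best-subset superposition

For whole-model comparisons where only a conserved core aligns (e.g.
heme-binding motifs of otherwise dissimilar folds), `pruned_superposition`
iterates: fit, drop correspondences with residual > prune_factor × rmsd
(default 2.0), refit, until stable or fewer than four pairs would remain.
Dropping only above-threshold residuals makes the surviving rmsd
monotonically non-increasing.  A fit with rmsd below 1e−8 Å stops pruning
outright — at that level residual ordering is numerical noise.  The
default prune factor is a design choice; published "best aligned N atom
pairs" numbers were produced by unspecified procedures, so agreement in
n_pairs_used should not be over-interpreted.

## Chain topology

Hemes are nodes; contacts (≤ 6 Å minimum ring distance) are edges, parallel
edges collapsed to the smallest distance.  The *main chain* is defined as
the longest simple path in the largest connected component — a definition,
not a published algorithm: filament heme chains are near-linear, so the
longest path coincides with the visually traced chain.  Components of ≤ 24
nodes (two to three subunits of an octaheme filament) are searched
exhaustively by DFS backtracking with deterministic lexicographic
tie-breaks; larger components fall back to a BFS double sweep from an
extremal-degree node, which is exact on trees and near-exact on the
near-path graphs this package targets.  Off-chain hemes are reported with
their attachment node(s); a degree-1 off-chain heme is the canonical
"branched heme".

## Solvent accessibility

Shrake–Rupley with a deterministic golden-spiral lattice (default 960
points per atom, probe 1.4 Å, van der Waals radii C 1.70, N 1.55, O 1.52,
S 1.80, Fe 1.80 Å, unknown elements 1.70 Å).  No published algorithm
parameters exist for the heme-exposure figures this package is compared
against, so these field-standard defaults are fixed and all comparisons to
reported areas are tolerance-based.  Verified behaviour: an isolated
carbon atom reproduces 4π(1.70+1.40)² = 120.76 Å² to <0.1%; two
intersecting spheres match the analytic cap formula to 2%; 10-atom random
clusters match a 1.5·10⁵-sample Monte-Carlo rejection oracle to 2% and an
independent library implementation (biotite) with matched radii to 2%;
doubling the lattice changes totals by <0.5%.

Per-heme areas sum over **all** atoms of the heme residue, substituents
included, because reported whole-heme exposures are most consistent with
whole-ligand areas; `ring_atoms_only=True` restricts to the 25-atom core.
Heme exposure in a filament should be computed with the heme's own subunit
plus both flanking subunits present (the package's deposited-model test
uses full-model context); exposure values are context quantities, not
properties of the isolated cofactor.

Interface burial between two chain selections is
(SASA_A + SASA_B − SASA_AB)/2 — the per-side (PISA-style) convention —
with `per_side=False` giving the undivided total, since reported "buried
area" figures do not always state the convention.

## Helical model

Rise Δz (Å/subunit) and signed twist Δφ (deg/subunit) define a screw about
z; pitch = rise × 360/|twist| (sign-independent), meridional layer line at
1/rise, 1-start layer line at 1/pitch.  With rise 58.1 Å and twist −158.2°
the pitch is 132.2 Å — the package's one parameter-arithmetic check against
a published table that needs no coordinates.  Expansion applies copy j the
rotation j·Δφ and translation j·Δz, suffixes chain ids with j, and warns
(not errors) on inter-copy contacts below 1 Å, since marginally clashing
expansions are still useful diagnostics.  Deposited filament models follow
the z-axis convention and are used as-is; `align_principal_axis` is
available for arbitrary inputs.

## Synthetic generator

The idealized porphyrin is planar and exactly 4-fold symmetric: Fe at the
origin, N at 2.00 Å along ±x/±y, pyrrole and methine carbons at idealized
in-plane positions with 1.35–1.44 Å bonds (max ring radius 4.28 Å).
Geometric idealization is harmless here because pair correspondence is by
name.

`make_pair` rotates a copy by the designed θ about a chosen axis through
Fe, then translates along the ring normal (plus optional lateral offset);
when a target minimum distance is given the normal offset is solved by
Brent root finding to machine precision, so designed (θ, d) are exact
ground truth, not approximate ones.

`make_filament` stacks chain rings along the helical axis with planes
perpendicular to it, orientations alternating 0°/180° about x, and derives
the rise so the terminal rings of adjacent subunits sit exactly at the
designed interface distance.  Because every designed contact is a pure
translation along the ring normal (chain and interface) or a pure in-plane
offset (pendant branches), all designed distances are *exact*, which is
what makes the 1e−6 generator→analyzer round trips meaningful.  Real heme
chains rock their rings into T-shaped contacts; a 90°-rocked ring stacked
on the chain normal at ≤ 6 Å spacing would physically collide with its
neighbours (ring radius ≈ 4.3 Å), so the default chain uses
parallel/antiparallel alternation only — T-shaped geometry is exercised
through `make_pair`, and an `orientation_pattern` argument allows T-shaped
stacks at wider spacings.  The default subunit emulates the octaheme
architecture studied by the package's acceptance checks: eight hemes,
seven in the chain at 4.0 Å spacing, one pendant at 4.6 Å from chain
heme 5, interface pairs antiparallel at 4.5 Å, twist −158.2°.  With this
geometry the derived rise is 28.5 Å, not the published 58.1 Å of the real
filament — an axis-aligned chain cannot span a 58.1 Å rise in six 4 Å
steps; the real chain zig-zags.  The generator therefore treats rise as
derived by default and accepts an explicit rise (re-deriving the spacing)
when the caller wants published parameters, warning implicitly through
broken chain contact if they are geometrically incompatible.

What the generator does **not** emulate: protein scaffolds (no occluding
residues, so synthetic SASA values are not comparable to in-protein heme
exposures — SASA is validated on analytic sphere clusters instead), heme
ruffling/doming, substituent atoms, and coordinate noise.  Passing the
round trips shows the analysis recovers designed geometry exactly; it says
nothing about model-building error in experimental structures.

## Numerical choices and limitations

- Alternate conformers: highest occupancy wins, ties to altloc 'A'.  How
  published surveys handled altlocs is unstated; this is a choice.
- PDB output carries 3 decimals, so file round trips limit recovery to
  ~5·10⁻⁴ Å (the in-memory path is exact); multi-character chain ids from
  filament expansion are deterministically remapped to single characters
  on PDB write.
- Hemes missing any canonical ring atom are skipped with a warning, never
  imputed.
- Surveys are intra-structure, first model only; re-running a survey is
  byte-identical (no randomness, deterministic ordering).
- Deposited-model checks (heme counts, rare-pair angles 56°/82°, branch
  contact 4.6 Å, chain distance range 3.6–5.7 Å, heme exposures 326/292 Å²,
  interface ~1200 Å²) run only when the user supplies the coordinate files
  under `data/`; the package performs no network access.
- Problem sizes used by the test suite and acceptance script — three-subunit
  toy filaments (24 hemes), 10-atom SASA clusters, 1.5·10⁵ Monte-Carlo
  samples per atom — were chosen as the smallest sizes at which every
  designed feature (interface pairs, per-subunit branches, multi-neighbour
  occlusion) is present.
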