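# Methods

This note records how `platemetry` defines its measurements, what the
synthetic phantoms do and do not emulate, and the numerical choices made
where the procedure was genuinely open.

## Reference frame and conventions

The main base plane (MBP) passes through the three base-plate landmarks IP,
Q1, Q2. Three conventions are fixed here because nothing about the workflow
pins them down, and every downstream number depends on them:

- the plane normal n̂ is oriented so (END − IP)·n̂ > 0, which makes every
  effective-section offset positive and the drop D = (END − IP)·n̂ > 0;
- the sagittal axis ŝ is the normalized in-plane component of IP→END (always
  defined unless END lies exactly above IP, which is rejected), rather than
  the Q1/Q2 bisector, so it does not depend on how symmetrically the tuber
  points were picked;
- the mediolateral axis m̂ = ŝ × n̂ completes a right-handed frame. Widths
  are measured along m̂ and thicknesses along ŝ for effective sections
  (along n̂ for the cleft section): appliance widths exceed thicknesses,
  and the cleft section's thinnest dimension is its vertical one.

With these choices the frame is invariant to swapping Q1 and Q2 exactly.

Landmark files carry approximate coordinates; each landmark is snapped to
the nearest mesh vertex (limit 2 mm), emulating on-screen vertex picking.
Snapping happens on the welded full-resolution mesh, *before* decimation:
snapping on the 3000-face mesh would tie the reference frame to the face
budget (decimated vertex spacing is several mm) and break the stability of
the record across budgets.

## Canonical pose and determinism

After snapping, mesh and landmarks are re-expressed in the landmark frame
(IP at the origin, ŝ = +x, m̂ = +y, −n̂ = +z), coordinates are rounded to a
1e-6 mm grid, and vertices/faces are re-sorted into a canonical order.
Greedy decimation is extremely sensitive to last-bit coordinate changes and
to input ordering; measuring in a canonical pose makes the entire pipeline
bit-identical under any rigid motion or re-serialization of the input. The
first-face-centre recentering of the original workflow is still available
as a preparation step (`recenter_mesh`); all measurements are invariant
to it by construction.

## Mesh preparation

- **Weld**: positional vertex merging at 1e-6 mm. (An angle-π crease weld
  merges every coincident vertex; positional merging reaches the same end
  state and is well defined on STL facet soup.) Area is preserved exactly;
  degenerate faces are dropped with a warning.
- **Decimation**: quadric edge collapse to a hard face-count cap
  (default 3000), implemented as vectorized passes: all edge costs are
  evaluated from per-vertex quadrics (area-weighted face planes plus
  strongly weighted boundary-constraint planes), edges are sorted, and a
  vertex-disjoint batch of at most 1/12 of the edges is collapsed per pass
  at the quadric-optimal points. Collapses must satisfy the link condition
  (checked vectorized via a sparse adjacency product) and face fins created
  by a collapse are removed in pairs, so watertight input stays watertight.
  Small batches keep the sequence close to true greedy collapse, which is
  what lets thin tubular features retain enough faces out of the budget.
- **Join/clean**: connected components below 0.1% of total surface area are
  scan artefacts and are dropped; everything else is concatenated into one
  entity (multi-part files are legitimate inputs).

## Sectioning

Plane–mesh intersection segments (from trimesh) are chained into loops by
merging endpoints within 1e-6 mm using union-find over close pairs — grid
rounding is *not* used, because coincident endpoints routinely straddle
rounding-cell borders and would tear closed loops open. Open chains with an
end gap under 0.5 mm are closed (non-watertight scan meshes); longer open
chains are discarded with a warning. On watertight input all loops close.

One loop per section is attributed to the extension: the loop whose
centroid lies nearest an anchor on the line through the projected END along
n̂. Loops under 0.5 mm² are ignored during selection (a section plane that
grazes the part tangentially emits near-zero-area slivers); ties break by
smaller area, then lexicographic centroid, so runs are reproducible.

Area and centroid are the unsigned shoelace area and first-moment centroid
of the planar polygon (cross-checked against shapely in the tests). Width
and thickness take the *extreme* pair of boundary intersections of the
centroid line — on concave loops the line can cross more than twice, and
the extreme pair matches the published four-point construction.

## Cleft section S0

The cleft sub-mesh is found by clipping above the MBP. Fragments protruding
less than 3 mm above the plane are not cleft material: the plate's surface
texture and the extension's plane-crossing collar both poke slightly above
the plane on real and synthetic scans alike. Among the remaining
components, the one whose attachment loop at the plane lies nearest the
projected END is the cleft extension. Its sagittal extent is divided into
five equal spans; the four interior boundaries define candidate planes with
normal ŝ. Candidates slice the **full** mesh (their loops then close even
where the cleft tube crosses the base plane near its ends) and the
smallest-area candidate becomes S0, anterior-most on ties. A phantom
without cleft material yields a missing S0 (NA in the record) rather than
an error.

## Angles and volume

Skeleton angles are unsigned 3D turn angles of the chain IP→PS₁→…→PS₅ in
[0°, 180°]; a signed sagittal-projection variant (clockwise positive) is
available behind a flag but magnitudes are what the record stores. Note
that PS₅ is the END landmark itself, so α₄ inherits the picking precision
of END directly — this is a property of the definition, not of the
implementation.

V_eff clips the mesh below the MBP, caps each planar cut boundary with a
triangle fan from the loop centroid (exact for the divergence-theorem
volume of a planar cap, and topologically closed for any loop shape), and
selects the solid nearest the anchor line — considering only components
whose depth extent reaches at least D/2, since the effective extension by
definition spans the drop and cut slivers do not. Boundary loops away from
the clip plane mean the scan was open there; the volume is then reported
missing rather than fabricated.

## Synthetic phantoms

The generator emulates the *geometry class* of scanned appliances, not any
patient: an elliptical base plate (default 41 × 29 mm) with a downward
vault bulge, a low-amplitude surface ripple (0.05 mm, wavelength 9 mm)
standing in for scan texture, and a tubular extension with elliptical
cross-section (default semi-axes 3 × 2 mm) that arches over the plane from
the posterior plate edge (the cleft portion, with a smooth compactly
supported neck, default scale 0.62) and descends to a tip at drop D
(default 21 mm) with bend 65° and further turns of 8°, 6°, 15°. Defaults
sit in the neonatal range of published appliance dimensions (drops
~20–27 mm, widths 3–8 mm, thicknesses 2.5–5 mm, V_eff ~370–550 mm³).

Choices that make the ground truth exact:

- landmarks sit on nodal lines of the ripple, so the landmark plane is
  exactly z = 0 in canonical coordinates;
- tube segments join at miter (bisector) planes and collinear knots are
  merged — butt-jointed slabs would put a degenerate zero-level-set
  membrane on the shared cap plane, which marching cubes renders as a dent
  ring (observed as a 6% area deficit before the fix). Miter joints also
  make the swept volume exactly π·w·h·(path length), which is the V_eff
  ground truth;
- the effective axis bends at depths 3D/8, 5D/8, 7D/8, *between* the
  section planes, so every measured section cuts the interior of a straight
  segment: A_k = π·w·h/sin β, T_k = 2h/sin β, W_k = 2w in closed form, and
  section centroids lie exactly on the axis. Skeleton-angle truth is
  computed from the exact centroid chain (chords straddle the bends, so
  only α₁ equals the nominal bend parameter exactly);
- the surface is a marching-cubes level set (grid pitch 0.7 mm by default,
  scaled down for thin tubes; the generator refuses a pitch coarser than
  0.4× the thinnest feature), hence watertight by construction. The grid
  origin carries a fixed fractional offset so no sample lands exactly on
  the landmark plane.

Scan degradation is explicit and seeded: Gaussian vertex jitter along
normals and disconnected artefact icospheres. What the phantoms do *not*
emulate: real palatal anatomy (the plate is stylized), scanner-specific
noise spectra and holes, wire clips, and hand-finished surface detail — so
passing tests demonstrate the correctness and stability of the *measurement
procedure*, not clinical accuracy on any particular scanner.

Generator truth declares per-quantity tolerances (2% lengths, 5% widths and
thicknesses, 6% areas, 3° angles, 5% volume, 15% for the S0 family); they
cover marching-cubes faceting, decimation to the 3000-face budget and
landmark quantization, as measured on held-out geometry during development.

## Stability tolerances

Stability suites (decimation budgets 3000–30000, base-plane landmark jitter)
assert each of the 32 values within 2% relative with a 0.3-unit absolute
floor. The floor is forced by the schema itself: EL₁ is identically 0 and
the small skeleton angles (a few degrees) move by more than 2% of
themselves under any sub-millimetre landmark change. Jitter is applied to
the three base-plane landmarks (0.75 mm, the middle of the picking-error
range the workflow is expected to tolerate); sagittal lengths absorb IP
jitter one-to-one by definition, so their bound is jitter + 2%. END is not
jittered: moving the tip landmark moves the measured tip.

## Problem sizes

The default test and acceptance runs use phantoms of ~14–40k raw faces
(pitch 0.5–0.7 mm) decimated to 3000, a 21-phantom recovery grid, and one
~165k-face sphere exercising the decimator at scan-like density; the full
suite and the acceptance script each complete in a few minutes on one CPU.

## Known limitations

- Width/thickness are measured on the decimated polygon, not a smoothed
  curve; on 3000-face meshes this biases extreme chords low by ~1–4%
  (worst for the thinnest tubes).
- The cleft/effective split assumes the extension crosses the MBP once;
  appliances whose extension re-crosses the plane would need a different
  attribution rule.
- The S0 search measures at the four interior boundaries only (as the
  five-segment division prescribes); a neck lying between candidates is
  seen slightly off its minimum.
- Volumes require the clipped solid to close; scans with holes in the
  effective segment report V_eff as missing by design.
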