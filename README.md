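# platemetry

Automated morphometry of personalized palatal-plate appliances from surface
scans.

Palatal plates used to treat upper-airway obstruction in Robin sequence (the
Tübingen Palatal Plate and its relatives) carry a velopharyngeal extension
whose shape is tuned per patient by hand. Quantifying fabricated appliances
retrospectively — how long, wide, thick and bent the extension ended up —
is what makes standardization and quality control possible, but the organic
shape defeats callipers. `platemetry` turns a scanned appliance (an STL
triangle mesh in mm) plus four anatomical landmarks into a reproducible
32-value morphometric record, with no interactive CAD work.

## The measurement

Four landmarks anchor everything: the incisive papilla **IP**, the two
tuber-maxilla points **Q1**, **Q2**, and the extension tip **END**. The
*main base plane* (MBP) passes through IP, Q1, Q2, with its unit normal
**n̂** oriented toward END; the in-plane sagittal axis **ŝ** points toward
the projection of END, and **m̂** = ŝ × n̂ is mediolateral. The drop
D = (END − IP)·n̂ is the depth of the tip below the plane.

- **Effective sections S1–S5.** Planes parallel to the MBP at offsets
  (k−1)·D/4 cut the extension. Each section k yields a closed loop with
  area A_k, centroid PS_k, width W_k (extreme boundary intersections of the
  centroid line along m̂) and thickness T_k (along ŝ). S5 is the tip itself
  (PS₅ := END), so it carries only lengths.
- **Cleft section S0.** The material above the MBP (the cleft-side portion
  of the extension) is divided into five equal spans along ŝ; of the four
  interior cross-sections (normal ŝ, width along m̂, thickness along n̂) the
  one with the smallest area is S0 — the structurally critical neck.
- **Lengths.** EL_k = |PS_k − proj(PS_k)| is the effective length
  (distance to the MBP, so EL₁ = 0 and EL₅ = D exactly), and
  SL_k = |IP − proj(PS_k)| the sagittal length.
- **Angles.** The skeleton IP→PS₁→…→PS₅ has turn angles α₁…α₄ (degrees,
  unsigned 3D angles; α₁ is the main bend of the extension at the plane).
- **Effective volume.** V_eff is the watertight volume of the extension
  clipped below the MBP (divergence theorem on the capped solid).

Before measuring, the scan is prepared the way the original digital
workflow does: coincident vertices are welded, the mesh is decimated to a
3000-face budget (quadric edge collapse with boundary preservation),
disconnected scan artefacts below 0.1% of the surface are dropped, and the
part is re-expressed in the landmark frame so results are bit-identical
under any rigid motion of the input.

Because no scanned appliances ship with the package, a synthetic-fixture
module generates watertight phantoms — an elliptical base plate joined to a
bent, optionally necked tubular extension, surfaced by marching cubes from a
signed-distance field — with closed-form ground truth for every reported
quantity, plus controllable scan noise and artefact blobs.

## Worked example

Generate a phantom appliance and measure it:

```sh
platemetry phantom --seed 0 --out-dir demo/
platemetry measure --mesh demo/phantom_seed0.stl \
    --landmarks demo/phantom_seed0_landmarks.json --out demo/record.csv
```

or in Python:

```python
import platemetry as pm

mesh, landmarks, truth = pm.make_phantom()   # default: drop 21 mm, bend 65°,
record = pm.measure_plate(mesh, landmarks)   # tube 6 × 4 mm, necked cleft arch
print(record["EL_5"], record["alpha_1"], record["V_eff"])
```

The default phantom prints (mm, mm², mm³, degrees):

```
EL_1..EL_5   0.00   5.26  10.52  15.78  21.04
SL_1..SL_5  49.65  52.10  54.13  55.44  55.99
A_1..A_4    20.40  20.42  19.31  18.82
W_1..W_4     5.95   5.90   5.87   5.92
T_1..T_4     4.38   4.38   4.15   4.05
S0 (cleft)  EL_0 5.72  SL_0 41.37  A_0 7.82  W_0 3.64  T_0 2.71
V_eff      404.45    alpha_1..4  65.03  3.86  7.12  8.52
```

Reading it: the effective lengths step by exactly D/4 (here D = 21.04 mm as
snapped to the scan); the recovered bend α₁ = 65.03° matches the generator's
65°; the widths ≈ 5.9 mm and thicknesses ≈ 4.1–4.4 mm recover the 6 × 4 mm
tube (thickness grows with obliquity as the extension steepens); S0 sits at
the cleft neck, the thinnest part of the appliance; and V_eff ≈ 404 mm³ is
the volume of the airway-opening segment.

`platemetry batch --manifest plates.csv --out cohort.csv` measures a whole
cohort into one table (columns `mesh,landmarks,stem`), one row per plate.

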