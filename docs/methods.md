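# Methods

## Scope and data model

`foramct` analyses one foraminifera specimen per greyscale stack. Stacks
are stored slice-major `(z, y, x)`; the user-supplied voxel spacing
`(dx, dy, dz)` in µm/voxel is the only calibration source (TIFF metadata
is deliberately ignored, since scanner exports are inconsistent). Voxel
`(0, 0, 0)` is centred on the physical origin, so the centroid of voxel
index `(k, j, i)` is `(i·dx, j·dy, k·dz)` µm. Centroids are reported in
Cartesian `(x, y, z)` order. Multi-specimen fields of view are out of
scope: split them into one stack per specimen first.

## Pipeline

1. **Infill removal (optional).** Granular sediment filling chambers
   post mortem overlaps neither background nor calcite in greyscale; an
   inclusive band `[lo, hi]` selects it and the selected voxels are set
   to 0, yielding the cleaned `Raw` volume. Removal precedes smoothing
   so the blur cannot smear infill intensity into the calcite band.
2. **Smoothing + calcite threshold.** A 3D Gaussian blur with sigma in
   µm (converted per axis to voxels, reflective borders, so total
   intensity is conserved) suppresses noise; an inclusive band threshold
   produces the calcite skeleton. Thresholds may be numeric or `auto`
   (Otsu's two-class split to the data maximum); resolved values are
   logged exactly as user-entered ones would be.
3. **Keep-largest-region.** Only the largest connected component
   survives (foreground connectivity 26 by default; ties broken toward
   the component whose first voxel comes earliest in raster order).
   Background-facing operations (hole filling, watershed neighbourhood)
   use 6-connectivity — the standard digital-topology pairing that
   avoids foreground/background paradoxes.
4. **Fill.** Dilation by a ball of `close_radius_vox`, 3D hole filling
   (background components not 6-connected to the border), erosion by
   the same ball. The result is explicitly unioned with the skeleton so
   `FilledMask ⊇ SkeletonBinary` holds even at the array border, where
   plain closing is not extensive. A headless check then replaces the
   interactive "is the test completely filled?" confirmation: the
   dilate/fill/erode sequence is repeated with a generous probe radius
   (default 4 voxels), and any void that only the probe seals — and
   whose internal radius exceeds the probe radius, distinguishing a
   chamber-scale cavity from a rolled-over surface crease — counts as an
   unfilled chamber. Plain morphological closing cannot perform this
   probe: its erosion reopens any aperture into a large cavity, which is
   precisely why the hole-filling step sits between dilation and
   erosion.
5. **Distance-based sealing (when needed).** If the check fails (or the
   user forces it), a two-stage procedure seals open apertures: stage 1
   unions the skeleton with all background within `t1` µm of it (a
   distance-threshold dilation closing any aperture narrower than
   `2·t1`) and hole-fills; stage 2 keeps voxels of that sealed solid at
   depth ≥ `t2` from its surface, unions the skeleton back, and
   hole-fills again. Depth is measured to the nearest background voxel
   *centre*, which places an original surface voxel at depth `t1` + one
   pitch; `t2` is therefore offset by one voxel pitch internally so that
   seal-then-trim is the identity on flat interfaces. With `t1 = t2`
   the outer surface is restored to within a voxel while enclosed
   chambers stay filled, and the result is asserted to contain the
   skeleton and to stay inside the hole-filled `t1` envelope (the
   envelope, not the bare dilation, because enclosed chamber interiors
   legitimately lie deeper than `t1` from calcite).
6. **Surface area.** Edge voxels are foreground voxels with at least
   one background 6-neighbour (the array border counts as background; a
   specimen touching the border triggers a truncation warning). Area =
   edge count × `(dx·dy + dy·dz + dx·dz)/3`. This voxel-face estimator
   is the workflow's native convention and systematically
   underestimates curved surfaces; `surface_area(..., method="mesh")`
   offers a marching-cubes alternative for users who want geometric
   accuracy.
7. **Wall split.** The foreground distance transform of the filled test
   measures each calcite voxel's depth from the outer surface (chambers
   are solid in the filled mask, so internal cavities do not count as
   surface). Voxels with depth > `split_t_um` form the inner septa,
   the rest the outer wall; ties at exactly `t` go to the outer wall,
   and the two masks partition the skeleton exactly. `auto` applies an
   Otsu split to the depth distribution over skeleton voxels (outer
   wall shallow, septa deep).
8. **Thickness.** Local thickness follows the model-independent
   definition (Hildebrand & Rüegsegger): the thickness at a voxel is
   the diameter of the largest sphere that fits inside the structure
   and contains it. Implementation: the foreground EDT gives each
   voxel's inscribed-ball radius; radii are quantised to bin edges
   (bin = ¼ of the smallest pitch, coarsened so at most 64 levels are
   processed) and swept from large to small, painting each level's
   coverage in one vectorised distance transform. Quantising radii
   *upward* makes the error one-sided: the map never undershoots
   literal sphere fitting and overshoots by at most half a voxel. The
   sphere model assumes near-isotropic voxels; a spacing ratio above
   1.5 triggers a warning. "Average thickness" for a whole test is the
   local-thickness mean over the full skeleton; inner/outer values come
   from their respective masks. Single-chamber tests have no septa; the
   inner-test summary is then all-zero rather than an error.
9. **Chambers.** `InnerChambers = FilledMask \ SkeletonBinary` (so
   calcite + chambers = test holds exactly, voxel by voxel). The
   chamber space is smoothed (binary → float, re-binarised at 0.5),
   distance-transformed, and seeds are cut at `EDT ≥ seed_t_um`
   (`auto`: half the maximum distance). Seeds are labelled by
   26-connected components in raster order and flood a marker-based
   watershed on the negated distance with a 6-connected neighbourhood,
   restricted to the chamber space. Chamber-space pockets unreachable
   from any seed are assigned to the nearest labelled voxel, so label
   coverage is total and the label count always equals the seed count.
   Provided `seed_t_um` exceeds the radius of any septal breach, each
   chamber core yields exactly one seed even when septa are partially
   dissolved. Per-chamber statistics (voxel count, volume, centroid,
   mean greyscale) are accumulated from the label map; the mean
   intensity is taken over the cleaned `Raw` volume by default (a
   label-as-signal variant exists for compatibility but carries no
   information). Chambers are numbered by ascending volume — the
   ontogenetic proxy, since foraminifera add successively larger
   chambers — with ties broken by label; how real specimens order
   chambers along the coil is not recoverable from volumes alone, so
   growth curves built on this proxy assume monotone growth.
10. **Porosity** = 100 × chamber volume / test volume (%). This is
    cavity porosity, not intra-wall micro-porosity; resolving pores
    within the wall itself is out of scope.

Every thresholding decision, with its resolved numeric values and
per-step timing, is appended to `<Sample>_ProcessingLog.txt`; the final
record carries the total processing time. Images are written as
multi-page TIFFs (binary masks 8-bit 0/255, label maps in the smallest
unsigned type that holds the maximum label, distance/thickness maps
32-bit float); CSVs use comma/LF/UTF-8 with 6-significant-digit floats.
Identical input + configuration reproduces every TIFF and CSV byte for
byte.

## Phantom generator

The generator emulates the variability that makes real scans hard:

- geometry: `n_chambers` spherical cavities with radii
  `r0 · growth_ratio^k` placed along a spiral (per-chamber z-translation
  and rotation); consecutive centres sit `r_k + r_{k+1} + wall` apart so
  cavities are separated by exactly one septum of thickness `wall`;
  calcite is the union of shells of thickness `wall` minus all cavities,
  and the shared-shell overlap between consecutive chambers is recorded
  as the septum mask;
- apertures: a ball of radius `aperture_um` carved through each septum
  centre (an effective opening narrower than the carving ball; 0 =
  sealed, the default);
- dissolution: a seeded random fraction `septum_breach_frac` of septum
  voxels deleted;
- infill: seeded random spheres of 1–4 voxel radius (the fine/coarse
  grain dichotomy of real sediment) until `infill_frac` of the cavity
  space is occupied;
- imaging: class mean intensities (background 2000, calcite 52000,
  infill 30000 on the 16-bit scale — strong but not saturating contrast
  typical of well-preserved specimens) plus Gaussian noise, quantised to
  uint16.

All randomness flows through one generator seeded by `rng_seed`, and the
ground truth (chamber labels, wall/septum/infill masks, per-chamber
volumes and centroids, porosity) is taken from the clean pre-noise
geometry. Defaults describe the reference specimen used throughout the
tests: five chambers, first radius 12 µm, growth ratio 1.2, 6 µm walls,
sealed, noiseless, unit spacing.

What the phantom does **not** emulate: scanner point-spread blur, beam
hardening, ring artefacts, partial-volume gradients at interfaces, and
intra-wall pores. Phantom interfaces are one voxel sharp, so passing
recovery tests demonstrates the correctness of the geometry pipeline,
not robustness to reconstruction artefacts; real scans still require
user-chosen thresholds.

`recovery_config` derives an analysis configuration from a phantom's
known class intensities (midpoint thresholds — the headless analogue of
reading a bimodal histogram), a smoothing sigma of half a pitch for
noiseless and one pitch for noisy volumes, close radius 1 for sealed
specimens, wall split at `wall + 1` voxel, and a seed threshold of half
the first-chamber radius (far above any breach pore).

## Numerical choices and edge cases

- EDTs are anisotropy-aware (`sampling = (dz, dy, dx)`) and measure to
  the nearest opposite-phase voxel centre; array borders are padded with
  one layer of the opposite phase, so an all-one-phase volume still
  yields finite distances. The sealing stage is the one exception: its
  background distance treats everything beyond the border as more
  background, because a virtual foreground border there would let the
  dilation band hug the array edge and hole filling would flood the
  whole box.
- Gaussian sigma 0 is the identity (modulo float cast); thresholds are
  inclusive on both ends; `keep_largest_region` on an empty mask, seeds
  that vanish at too high a cut-off, and empty masks in thickness or
  surface area raise informative errors rather than returning empty
  products.
- Filenames derive from the input basename minus its final extension
  only (`a.b.c.tiff` → `a.b.c`); characters that are invalid on common
  file systems are rejected.
- Default problem sizes in the test suite (phantoms of 3–5 chambers,
  ~0.3–2.3 M voxels; brute-force oracles on ≤ 14³ grids) keep the full
  suite under a minute while exercising every stage at realistic
  geometry ratios.

## Known limitations

- The edge-voxel surface-area estimator is biased low on curved
  surfaces; use the mesh estimator when absolute areas matter.
- The unfilled-chamber probe cannot detect apertures wider than twice
  its probe radius; such tests need the distance-based sealing enabled
  explicitly.
- Chamber numbering by volume is a proxy; it mis-orders pathological
  specimens whose later chambers are smaller than earlier ones.
- Thickness values on strongly anisotropic grids are biased by the
  sphere model (warned, not corrected).
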