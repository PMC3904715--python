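# Methods

## Geometry and conventions

All lengths are µm. Particles (chloroplasts) and cell bodies are
axis-aligned spheroids; "height" means the caliper along the optical
axis z, i.e. `2·rz`. Axis alignment makes every probe decision exact:
plane sections of a spheroid are axis-aligned ellipses, spheroid-vs-box
contact reduces (after scaling by the semi-axes) to a closest-point test,
and contact with a bounded planar surface reduces to 2D ellipse-vs-
rectangle. Rotated or lobed cells are out of scope; a lobed cell can be
approximated by overlapping spheroids, but number bias depends only on
z-calipers, not on lobing.

Contact uses the closed-set convention everywhere: touching counts as
intersecting. All counting tie-breaks therefore live in the probe rules
(touching an exclusion surface excludes; touching an inclusion face
includes), which keeps the tiling tests exact rather than
measure-theoretic.

Spheroid-in-spheroid containment and spheroid-spheroid overlap are solved
exactly as diagonal trust-region subproblems (a one-dimensional secular
equation per test, solved by bracketed root finding with a cheap
sufficient-condition fast path). These back the generators' containment
guarantees and the non-overlap placement mode.

## The counting rules

**Optical disector (unbiased brick).** A particle is counted by a brick
iff it intersects the closed box and touches none of the exclusion
surfaces: the look-up face, plus the 2D unbiased frame's forbidden line of
the brick footprint — left edge with its upward extension, bottom edge,
and the downward extension of the line through the bottom-right corner —
swept through every plane from the look-up level onward (through the brick
and beyond the reference plane). The sweep matters: with only the two side
faces and their vertical extensions excluded, a particle straddling the
x0/y0 corner of the footprint without entering the diagonal neighbour is
excluded from every brick of a tiling, and the mirrored configuration at
the opposite corner is counted twice. The swept-forbidden-line rule is the
3D analogue of the Gundersen frame and is how disector software applies
the rule in practice (2D frame on every optical section, look-up section
excluded). The package treats the tiling ("mosaic") property as normative
and asserts it exactly in the tests: for random spheroid populations and
brick tilings, every particle is counted by exactly one brick, in both
look-up orientations.

**Double disector.** The probe is applied in both z-directions on the same
slab; Q sums both directions and the reported probe height is twice the
slab height. A particle interior to the slab can be counted by both
directions by design — the doubled denominator keeps `E[Q]/(a·2h) = N_V`,
verified by simulation on periodic fields.

**Stack-based disector.** On labelled stacks the same rule is applied
discretely: a label is counted iff it appears inside the frame on a page
of the probe and appears neither in the look-up page (inside the
footprint) nor on the forbidden line — a half-pixel-wide closed band — on
any page from the look-up page upward. Pages are ordered top-down, so the
"above the reference" pages realise the exclusion sweep beyond the
reference plane. Exact agreement with the geometric rule cannot hold for
decisions whose geometric margin is below one voxel; the
stack-vs-geometry test therefore perturbs the geometric probe by 1.5
voxels in each direction and compares only particles whose decision is
stable under the perturbation (≥80–90% of particles at the test
resolution; every compared particle must agree exactly).

**2D unbiased frame and point grid.** The frame's forbidden line is the
left edge, the bottom edge, the upward extension of the left-edge line and
the downward extension of the vertical through the bottom-right corner;
the tiling property is asserted exactly, including degenerate (point and
segment) profiles. Point grids estimate reference areas as hits × area per
point; unbiasedness over uniform random offsets is verified by simulation.

## Estimators

Densities are ratios of pooled sums across probes — `ΣQ·p/(ΣP·a·h)` and
`ΣQ·p/(ΣP·a)` — not means of per-probe ratios, matching how disector
tallies are pooled in practice. `ΣP = 0` raises an explicit error rather
than returning infinity. Cavalieri volume is provided in both the textbook
`T·ΣA` form and the `mean(A)·L` variant used in needle protocols (default;
the two coincide when `L = n·T`). The theoretical bias factor is
`h̄_particle/h̄_cell`, the exact large-sample ratio of the 2D to the 3D
per-cell estimate.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the quantitative skeleton of needle mesophyll:
chloroplast mean caliper 4 µm (semi-axes 2.5, 2.5, 2.0 µm, 10% per-axis
CV), cell calipers in 40–60 µm (model cell default 49 µm, tissue default
40 µm), ~210 chloroplasts per cell, a 72% mesophyll volume-fraction target,
3 mm SUR section spacing along a needle, and optical-section spacings of
0.5 µm (chloroplast stacks) and 2 µm (cell stacks). Chloroplast placement
is uniform inside the cell by default — frozen-then-sectioned tissue does
not preserve the in-vivo peripheral arrangement — with a
`peripheral_shell` mode for arrangement studies. Chloroplast overlap is
allowed by default (counting is id-based); a bounded-rejection non-overlap
mode exists.

Cell placement offers dart-throwing (random-sequential-adsorption, the
spatially random option, practical below ~0.3 volume fraction) and a
jittered FCC-like staggered lattice whose affine scaling to the cell shape
reaches dense tissue-like fractions (bulk limit π/√18 ≈ 0.74); the default
`auto` mode selects by the implied density. Because cells are required to
lie wholly inside the domain, a boundary layer of roughly one cell size
cannot be filled; the realized whole-domain fraction is reported honestly
in the model metadata, and the 72% target is validated by point-counting
the bulk (domain core) in the tests.

Two artefacts of confined hard-core placement matter for experiment
design and are handled in the pipeline rather than hidden: (i) cell
centers pile up in a ~10 µm layer at the domain walls (+50% local
density), so all probe sampling bands keep a 15 µm buffer inside the
walls; (ii) a probe plane at a single fixed depth resamples the same thin
layer of cells across all lateral positions, so probe positions pair a
systematic series along x with an independently phased, shuffled
systematic series of depths. Neither adjustment touches the estimators —
they are sampling-design choices, exactly as SUR sampling is in a real
experiment.

What the generator does not emulate: fluorescence physics (PSF, noise,
bleed-through), segmentation errors, lobed or interdigitated cell shapes,
anisotropic tissue architecture (epidermis, vascular tissue), or shrinkage.
Passing tests therefore demonstrate correctness of the counting rules and
estimators on geometrically faithful populations — not robustness to
imaging artefacts, which would sit upstream of this package in a real
workflow.

## The two experiments

**Model-cell experiment.** A model cell (210 chloroplasts, 49 µm caliper)
is cut by 111 systematic sections spanning its z-extent (SUR phase; the
choice of systematic rather than exhaustive planes is an assumption
recorded in every report). Each section's profile count is the number of
particles whose z-extent contains the plane. The mean approaches
`n·h̄/H ≈ 17.1` profiles per section; the underestimation factor
`true_n / mean ≈ 12` exceeds ten-fold. With a single section the SE is
reported as `None` rather than fabricated.

**Tissue comparison.** A tissue block (default 480×200×240 µm, 250 cells
of 40 µm caliper, ~210 chloroplasts per cell) is probed at 16 SUR
positions. Each position applies a double disector for cells (slab 10 µm,
reported height 20 µm) and one for chloroplasts (slab 5.5 µm — twelve
0.5 µm optical sections — reported height 11 µm), a 3×3 point grid for the
reference space, and unbiased-frame profile counts for both populations on
the probe's middle section. Tallies are pooled as sums per arm, the
per-cell counts formed as density ratios, and their ratio estimates the
bias factor (expected 10). Positions with a zero cell tally are flagged
and excluded from the per-position paired list (pooled sums keep them). A
paired t-test across positions is reported for completeness but gates
nothing — ratios and ground-truth recovery carry the validation.

## Numerical choices

- Secular-equation root finding uses `brentq` at 1e-14 tolerances with a
  1e-12 relative slack on the final ≤1 comparisons (measure-zero
  boundary cases; the probe rules, not the geometry, own tie-breaking).
- SUR positions support two dialects: `grid6` (first position `(k+1)·T/6`,
  k a uniform integer 0–5 — the random-number-table protocol of needle
  sectioning) and `continuous` (first position uniform in `(0, T]`),
  selected per call.
- Label stacks are 16-bit; where profiles overlap, the highest id wins
  (documented, deterministic). Page 0 is the topmost plane, matching the
  browsing order of an optical disector.
- Placement rejection is bounded (an explicit `PlacementError` names the
  attempt limit); generators are deterministic given spec + seed, and
  model JSON round-trips exactly.
- Experiment sizes (20 replicate seeds; 250-cell blocks; 16 probes) were
  chosen so that Monte-Carlo standard errors on the headline ratios are a
  few percent, which the acceptance checks compare at 2 SE.

## Known limitations

- Coefficient-of-error formulas for stereological estimators
  (Gundersen–Jensen) and section-thickness corrections (Abercrombie) are
  deliberately absent; optical sections are treated as planes.
- The lattice placement mode realises dense packing with an ordered
  arrangement plus jitter, not an equilibrium hard-particle configuration;
  its boundary layer is unfillable by whole cells, so whole-domain volume
  fractions undershoot the bulk target on small domains.
- The ratio-of-sums per-cell estimator carries an O(1/ΣQ) small-sample
  bias (a few percent at the default probe counts), which the experiment
  defaults keep well inside the Monte-Carlo noise.
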