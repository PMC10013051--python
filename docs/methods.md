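# Methods

## The model

A 2D lung slice is represented as a honeycomb lattice of identical
linear springs (unit stiffness, degree-3 interior nodes).  Parenchymal
prestress — the baseline tension transpulmonary pressure puts on lung
tissue — is modeled by giving every spring a rest length shorter than
the lattice edge: `L0 = lattice_edge / prestress_ratio` with
`prestress_ratio > 1`, so the as-built lattice is everywhere under
tension.  Nodes in a one-lattice-edge band along the lung boundary are
fixed, as are all under-coordinated (degree < 3) nodes produced by
trimming the lattice to the lung silhouette: a free degree-2 node is
mechanically unbalanced under prestress and would drag entire lattice
columns sideways (we observed a 42 % spurious energy release from
exactly one such column before pinning them).

Low-attenuation areas (LAA; CT pixels strictly below −960 HU inside the
lung) are carved into the lattice: every spring whose midpoint falls in
a foreground pixel is removed.  Pixels live on integer centers, a pixel
covering `[c−0.5, c+0.5)` in each axis; all raster lookups use
`floor(x+0.5)` so half-integer coordinates resolve deterministically.
Springs under high-attenuation structures (pixels strictly above
−500 HU: vessels and the like) get a doubled rest length, which makes
them slack struts that never contract during relaxation.

Equilibrium minimizes the total elastic energy `Σ ½ k (L − L0)²` over
free-node positions.  Two solvers share this objective:

- **deterministic** (default and reference): L-BFGS quasi-Newton with
  an analytic gradient, run until the residual net force on every free
  node is below `1e−4 · k · lattice_edge`;
- **anneal**: Metropolis simulated annealing over Gaussian single-node
  displacement proposals (σ = 0.1 lattice edges), geometric cooling
  (0.995 per sweep, T0 = 0.1 · E/springs, 500 sweeps), followed by the
  deterministic polish.  With a fixed seed the trajectory is
  bit-reproducible.

Springs are linear and bidirectional.  The lattice is globally tense,
so compression appears only around carved voids, where the push-back of
compressed springs is what moderates hole expansion in crowded slices;
a `tension_only` flag switches to slack-under-compression springs
(buckling septa) for sensitivity work.

### Prestress magnitude

`prestress_ratio` defaults to 1.25 (20 % prestrain).  Hole expansion in
this model turns out to be only weakly sensitive to the exact value —
the carve halo (half a lattice edge around the mask) and the reduced
spring density at a relaxed void rim contribute as much apparent area
as the elastic displacement — so the default stays at a physiologic
distension scale.

## Apparent CT and LAA recovery

A network state renders to an image by exact segment accumulation:
every alive spring deposits `stiffness × in-pixel length` into each
pixel it crosses, and intensity is the deposit per unit pixel area.
Because the lattice pitch equals the pixel pitch, the raw per-pixel
line density is a honeycomb moiré (coefficient of variation ≈ 47 % on a
perfectly uniform lattice); the pipeline therefore blurs the render
with a Gaussian of `render_smooth_sigma` = 1.2 px, the smallest width
that brings the intact-lattice interior CV below 5 %.  Raw accumulation
(σ = 0) remains available and keeps the exact semantics (a unit spring
inside one pixel deposits exactly 1).

The LAA map of a rendered network is the set of lung pixels whose
intensity falls below half the interior mean intensity of the intact
template network — a self-normalizing threshold under which an
uncarved network reads ≈ 0 %LAA by construction.

## CSAM: curvature and size adjusted mapping

Carving an LAA mask directly (the naive method, NM) ignores that the
network is prestressed: removing springs lets the surrounding tension
expand and round the hole, so the reconstructed LAA is larger and
smoother than the original.  CSAM preprocesses each cluster before
carving:

1. extract the outer boundary (marching squares at the 0.5 level,
   counterclockwise, holes filled) and resample it uniformly in arc
   length with `max(64, round(perimeter))` samples;
2. shrink about the arc-length centroid, `r_s = α r + (1−α) c`
   (enclosed area scales by α²);
3. compute signed curvature per sample as the turn between the
   backward and forward difference tangents divided by the local arc
   step.  This angular form agrees with `|T′|/|r′|` to second order on
   smooth curves but sums to the exact polygon turning, which the
   plain second-difference form overestimates at rasterization corners
   (~5 % on a square);
4. subtract the constant β elementwise (no clipping; β is in 1/px, so
   a given β bends a long boundary much more than a short one — see
   "Parameter units" below);
5. reconstruct: the tangent angle is the running sum of `κ·ds` using
   the reference curve's own segment lengths (an unmodified profile
   then reproduces the polygon exactly up to rigid motion); positions
   integrate the tangent direction; the closure gap that a nonzero β
   necessarily opens is distributed linearly along the samples; the
   perimeter is rescaled to the reference's; the free global rotation
   θ0 (and a mirror variant) is recovered by brute force on a 360-point
   grid, scanned hierarchically (every 6th angle, then full resolution
   in a ±12° window) with a rasterized intersection-over-union
   objective against the original;
6. rasterize back to pixels (even-odd rule at pixel centers).

With α = 1 and β = 0 the chain is an identity up to rasterization
(IoU = 1.0 on all calibration fixtures).  Clusters below
`csam_size_floor_px` = 50 px bypass the chain: at lattice resolution
the adjusted and naive mappings are indistinguishable below that scale,
and the calibration experiment does not cover smaller targets.

### Parameter units

The printed reconstruction equations are only mutually consistent if
curvature is measured per unit of the normalized parameter t (i.e.
κ·L); this package instead keeps curvature in 1/pixel throughout —
the natural unit for raster boundaries — and subtracts β on that
scale.  A consequence worth knowing: β = 0.3 applied to a large
cluster (perimeter ≫ 21 px) removes more than the full 2π of turning
and destroys the shape, so calibrated optima put β near the bottom of
its 0–0.3 grid and the useful shape adjustment is carried almost
entirely by α.

## Calibration

For a single synthetic cluster, the mapping pipeline (preprocess →
carve → relax → render → threshold) is scored against the original
with the average symmetric surface distance (ASSD: nearest-neighbor
distances between the two boundary pixel sets, pooled over both
directions) for every (α, β) on a grid — α from 0.5 to 1.0 and β from
0.0 to 0.3, both in steps of 0.02.  The (1.0, 0.0) corner of each
error map is exactly the naive method.  The optimum is the centroid of
the region within 5 % of the map minimum (a single-cell argmin is
noise-sensitive on this pipeline).

Targets come from 4 seeded shape families (blob, elongated, lobed,
star: Fourier-perturbed discs whose realization depends only on
(family, seed), so one shape can be rescaled across the whole ladder)
at 7 sizes: 50, 100, 200, 500, 1000, 2000, 5000 px.  Each target is
embedded in its own network whose area is 5× the cluster area (side
floor 48 px): the fixed network boundary then stands in for the
tension catchment a cluster has inside a diseased slice — the region
whose prestress feeds the hole's expansion before neighboring voids
cut it off.  This sizing is what makes the calibrated law transfer to
whole-slice mappings; a fixed absolute domain left the optimum flat
across the ladder, and a generously scaled one over-shrinks clusters
in crowded slices.

The per-size optima are summarized as a power law α*(s) = a·s^b
(least squares on log α* vs log s, prediction clipped to (0, 1]) plus
a constant β* (its optima show no systematic size trend).  The package
ships a default model fitted by running this experiment over all four
families and the full ladder; `laaspring calibrate` reproduces it.

## Synthetic slices

The generator emulates exactly the features the pipeline consumes: a
two-lobed elliptical lung (~55 % of the grid), LAA clusters with
power-law sizes `P(S ≥ s) ∝ s^−D` (s_min = 4 px, capped at
min(1000, area/3)) placed by rejection sampling with a 2-px separation
halo (clusters that fail to place are split and retried), vessel-like
high-attenuation chords, and HU values sampled strictly on the correct
sides of the −960/−500 thresholds (parenchyma N(−870, 30) truncated,
LAA N(−980, 8) truncated below −960).  Everything is deterministic per
seed.

A severity suite spans 5–40 %LAA with the size exponent coupled to
severity (D ≈ 2.2 at 5 % falling linearly to ≈ 1.1 at 40 %),
reflecting that advancing emphysema coalesces clusters and flattens
the size distribution.  This coupling matters: at a fixed D = 1.5 most
LAA area sits in raster-scale clusters at every severity, the naive
method's error saturates by 10 %LAA, and the characteristic growth of
reconstruction error with severity disappears.

What the generator does not emulate: anatomically realistic texture,
airway trees, gravity gradients, lobar fissures, scanner noise.
Passing tests therefore demonstrate the mechanics and the mapping
logic, not clinical performance on real CT.

## Progression

Disease progression is simulated by iterative mechanical failure: at
each step every alive spring carrying at least `force_fraction`
(default 0.8) of the current maximum tension ruptures — the comparison
includes the maximum itself so at least one spring fails per step —
the network re-equilibrates (warm-started from the previous
configuration), and the structural metrics are re-measured from the
re-thresholded apparent CT.  Traces record %LAA, the largest cluster
A_L, the size exponent D, energy and removal counts per iteration.
Because springs are only ever removed, the void structure — and with it
%LAA and A_L — can only grow; the measured values, which come from
re-thresholding the rendered image after each re-equilibration, flicker
by a few pixels at cluster rims (≲0.06 %LAA points, ≲2 % of A_L per
iteration) on top of that monotone growth.

Coalescence is flagged when A_L grows by more than half the previous
second-largest cluster in one iteration — growth that boundary erosion
alone cannot produce.  Paired NM/CSAM traces of the same slice are
compared with D_local: the masks are partitioned into 10×10-px
squares, squares with no LAA in either mask are excluded, and D_local
is the mean absolute per-square %LAA difference.

## Structural metrics

- %LAA: LAA pixels as a percentage of the lung area.
- E_LAA: %LAA(reconstruction) − %LAA(ground truth), signed.
- A_L: pixel count of the largest 4-connected cluster.
- Exponent D: negative slope of log10 N(S ≥ s) against log10 s,
  unweighted least squares over the distinct cluster sizes inside the
  50–1000 px window; undefined (flagged) with fewer than 3 distinct
  sizes in the window.
- ASSD: as above; exactly matches an all-pairs brute-force oracle.

## Problem sizes and numerical choices

The test suite and the reproduction script run at deliberately modest
sizes chosen as the package's standard desk-scale conditions: 128×128
severity slices (lung ≈ 11 k px, networks ≈ 12 k nodes), a 20-slice
suite, reduced calibration grids (6 α × 4 β over 2 families × 3 sizes
a decade apart), 96×96 progression slices with 10 iterations and 5
seeds.  The full calibration grid (26 × 16 × 4 families × 7 sizes) is
available through `laaspring calibrate`.

Tie-breaks and degenerate inputs: the θ0 search prefers the smallest
angle and the unmirrored orientation on exact ties; single-pixel
clusters and clusters below the size floor map naively; an empty carve
mask is a no-op; a mask covering everything kills all springs; ASSD is
undefined (raised) for empty masks; the exponent fit is flagged
invalid rather than extrapolated when the window is underpopulated;
annealing falls back to the initial configuration if it would ever end
above the starting energy (it cannot after the deterministic polish).

## Known limitations

- 2D only; the coalescence statistics of real emphysema are 3D.
- Lattice pitch ≈ pixel pitch bounds the fidelity of both carving and
  rendering at the few-pixel scale; clusters under ~50 px are mapped
  naively for exactly that reason.
- The β adjustment in 1/px units is nearly inert for large clusters
  (see "Parameter units").
- The calibration transfers through a single per-size law; it cannot
  adapt to local crowding within a slice, which biases CSAM slightly
  negative at the highest severities.
- Linear springs; collagen recruitment nonlinearity is out of scope.
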