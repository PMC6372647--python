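# Methods

This note documents the models and numerical choices behind keelquant: what
the synthetic tissue generator does and does not emulate, how each measurement
is defined, and where defaults come from.

## Coordinate and unit conventions

Axes are `(t, z, y, x)` with `x` mediolateral (0 at the left edge, midline at
the field centre), `y` anteroposterior (anterior at low `y`), and `z`
dorsoventral (`z = 0` most dorsal). Voxel indices are 0-based; physical
positions sit at voxel centres (`pos = index · voxel_size`). Lengths are µm,
times minutes, angles degrees. The default calibration when a file carries no
metadata is 0.69 × 0.69 µm in-plane, 1.05 µm axially, 2.5 min per frame — the
acquisition settings of the imaging the analysis was designed for.

## The synthetic tissue model

The generator is a *kinematic prescription*, not a mechanical simulation: cell
trajectories, shapes and areas are specified directly, and the three renders
draw them in the corresponding imaging geometry. This is deliberate — the goal
is a movie whose ground truth is exact, so that each pipeline stage can be
scored by parameter recovery.

### Prescribed kinematics

* **Convergence.** Cells drift toward the midline with a sinusoidal time
  envelope (accelerating, then slowing) peaking at 0.25 µm/min for wild type,
  tapering linearly to zero inside the internalisation zone so cells
  accumulate near the midline without crossing it. An anterior drift
  (0.2 µm/min) acts before internalisation onset only, emulating the loss of
  the anterior motion component at onset. A small per-step positional jitter
  (σ = 0.12 µm) provides realistic track noise.
* **Deepening.** The midline tissue depth follows a monotone smoothstep from
  the initial to the final depth between onset and movie end (wild type
  42 → 138 µm over 10–13 hpf mapped to a 180-min movie with onset at 60 min;
  cdh2-like 44 → 85 µm; myosin-inhibited constant). Laterally the depth tapers
  to the plate value with a cosine ramp: full deepening within 15 µm of the
  midline, none beyond 40 µm — a keel confined to the medial zone. Each cell
  keeps a fixed fractional depth within the local tissue column, so medial
  cells are carried ventrally as the keel deepens (the "inward" component)
  while lateral cells are not.
* **Dorsal surface constriction.** Cells inside the 20-µm internalisation
  zone after onset lose dorsal profile area with a per-hour survival factor of
  `1 − constriction_rate` (wild-type rate 0.5/h, i.e. areas halve per hour,
  with a per-cell spread of σ = 0.06 on the rate; the cohort mean is unbiased
  because the survival factor is linear in the rate). A cell whose area falls
  below 10 % of its initial value is flagged internalised and leaves the
  imaging plane. The cdh2-like preset instead draws *ectopic* events as a
  Poisson process (0.15 events/h/cell, any position), with fast constriction
  (95 % loss/h) so events complete within a movie; what is known of the mutant
  is only that its events are spatially random across the plate width, so the
  rate and speed are package choices, fixed once.
* **Transverse shape schedule.** Long-axis angles to the parasagittal plane
  start at ~50° (leaning toward the midline) and, after onset, relax linearly
  in time toward a position-dependent target: 30° inside the medial zone, 80°
  outside it, with a narrow (±3 µm) ramp at the boundary. Making the target
  positional rather than a per-cell cohort property means converging cells
  reorient as they approach the midline, which keeps the late-stage zone means
  clean and matches the described behaviour. Cell lengths grow from ~14 µm
  toward ~34 µm (medial) / ~20 µm (lateral), capped at 90 % of the local
  tissue depth.

### Renders

* **Dorsal tangential view.** Cell footprints are a rasterised
  additively-weighted Voronoi tessellation of the cell centres (pixel →
  `argmin_i d_i − w_i`) with a radius cap (`d_i − w_i ≤ 0`), so the
  tessellation need not fill the frame: when cells constrict, the freed space
  becomes membrane-bright interstitium instead of inflating the neighbours —
  this is what lets medial areas halve while lateral areas stay constant.
  Weights are adjusted iteratively (30 iterations at the first frame, 12 with
  warm-started weights thereafter, 5 % median-error tolerance) so realised
  polygon areas match the prescribed areas; frame-0 prescribed areas are
  lognormal (σ = 0.22) and scaled to fill 80 % of the field. Membrane
  intensity is painted on region boundaries at the configured thickness
  (default 1.4 µm); an EVL-like layer of large-scale bright texture occupies
  the top 4 µm of the stack, and the tessellation plane sits 6 µm below the
  EVL bottom, inside the 5–7 µm selection window.
* **Transverse view.** The membrane channel carries a dim tissue fill (so the
  depth mask is contiguous) plus bright cell-outline ellipses with the
  prescribed axes and angles. Myosin and actin intensities decay exponentially
  below the dorsal surface (length scales 5 µm and 40 µm); the myosin
  mediolateral factor is `0.3 + 0.7·exp(−x̃²/2·20²)` for wild type and 1 for
  the cdh2-like preset.
* **Nuclei view.** Isotropic Gaussian blobs (σ = 2 µm) at cell centroids.
* **Noise.** Additive Gaussian (σ = 4) on a constant background (10), clipped
  at zero, quantised to uint16. No photobleaching, no PSF anisotropy beyond
  the voxel grid, no optical attenuation with depth.

Every render is a pure function of the config (including its seed): equal
configs give bit-identical stacks.

**What a green test does and does not establish.** The renders exercise the
geometry each stage depends on (EVL slice structure, membrane-bounded
footprints with realistic area statistics, blob-like nuclei at realistic
densities, exponential reporter gradients) but are optically much cleaner than
confocal data: no depth-dependent attenuation, no segmentation-relevant
texture inside cells, no nuclei shape variation, no drift. Recovery scores on
these movies are upper bounds on real-data performance; they validate the
measurement definitions and the code, not robustness to microscopy artefacts.

## Measurement definitions and defaults

* **Moments / axes.** Region moments are means over pixel centres with a
  `pixel²/12` extent correction on the diagonal terms; a single-pixel row
  then has a finite minor axis and solid rectangles recover the exact w/h
  axis ratio. Axis lengths follow the equivalent-ellipse convention `4·√λ`.
  Regions with λ₁ ≈ λ₂ (relative gap ≤ 1e−9) are flagged degenerate: the
  eccentricity index is 1 and the angle is missing.
* **Angles.** Orientations are reported in (−90°, 90°] from the +x image
  axis; alignment angles are folded into [0°, 90°]. In transverse frames the
  parasagittal reference is vertical, so the reported angle is
  `90° − fold(orientation)`. In dorsal frames the anteroposterior axis maps to
  image y (ap_axis = 90°); for real data the AP direction must be supplied
  (e.g. from a bright-field image), as the package cannot infer it.
* **Zones.** Medial is the half-open band [0, 20) µm from the midline,
  lateral [20, 60] µm, outside beyond. Cohort statistics freeze a cell's zone
  at its first appearance.
* **Midline.** Configured exactly for synthetic runs; estimated for real data
  by maximising left–right reflection correlation over the central half of
  the frame, falling back to the frame centre (with a warning) when the best
  score is below 0.2. Note the estimate needs a left–right symmetric
  structure (a deepened keel); a flat early plate does not constrain it.
* **Midline depth.** Within a ±5 µm band around the midline, the tissue mask
  is pixels above 20 % of the band's 99th-percentile intensity after Gaussian
  smoothing with σ = 0.5 µm; depth is the z-extent of the mask. The σ was
  chosen so that threshold crossing at a sharp edge moves less than half a
  voxel (σ = 1 µm dilates a step edge by ~0.84 σ per side, a 2-voxel bias on
  a 42-µm slab); the fractional threshold makes the measure invariant to
  global intensity scaling.
* **Tangential plane.** The EVL bottom is the slice above the first z whose
  mean intensity falls below half the superficial value; the analysis frame
  is a maximum-intensity projection of slices 5–7 µm below it. A manual
  `evl_z` override exists for stacks where the break is not detectable.
* **Segmentation.** Gaussian smoothing (σ = 1 µm), h-minima seeds with
  h = 10 % of the robust dynamic range, watershed restricted to pixels below
  50 % of the range (cell interiors), labels expanded by 1.4 µm (half a
  membrane width plus the smoothing-induced widening — calibrated so median
  per-cell area error on rendered movies is within a few percent), then
  min-area (4 µm²) and border-margin (2 px) filters with contiguous
  relabelling. Restricting the watershed to dark interiors is what keeps
  membrane-bright interstitium from spawning spurious labels. Deterministic;
  4-connectivity; ties resolved by scan order.
* **Nucleus detection.** Scale-normalised LoG over σ ∈ [1.5, 3] µm (three
  scales, per-axis voxel scaling), peak detection above an absolute response
  threshold (default 25 % of the frame's maximum response), sub-voxel
  refinement by an intensity-weighted centroid over a 3³ neighbourhood.
* **Linking.** Per-frame-pair optimal assignment on squared displacement with
  a gate of `max_disp` per bridged frame; unmatched detections seed new
  tracks; ends may bridge `memory_frames` (default 1) missed frames, with
  linearly interpolated gap rows flagged `imputed` and excluded from speed
  statistics. Deterministic and input-order invariant.
* **Events.** A tracked cell is an internalisation event when its area drops
  below 20 % of its initial area and the label is then absent for ≥ 2
  consecutive frames before the movie ends; losses at the end are censored.
  The recorded position is the last centroid's distance to the midline.
  Detection is resolution-limited: cells become unresolvable at roughly the
  10–14 µm² scale, so recall of fast (cdh2-like) events is partial (~50 %);
  missingness is spatially unbiased, which is what the spread statistics need.
* **Profiles.** Mediolateral profiles average background-subtracted surface
  intensity in 5-µm |x − midline| bins to 60 µm, with enrichment ratio
  mean(0–20)/mean(40–60); depth profiles bin by depth below the located
  surface to 40 µm, with steepness mean(0–5)/mean(20–40). Profiles are also
  emitted normalised to their own maximum, since reporter units are
  arbitrary. The band limits reuse the standard zone (20/60 µm) and depth
  (5/40 µm) windows.
* **Statistics.** Mann–Whitney U uses midranks; the two-sided p is exact by
  full enumeration when n₁+n₂ ≤ 12 with no ties (both tails counted, capped
  at 1), else a normal approximation with tie and continuity corrections.
  SEM uses the n−1 sample standard deviation.

## Workflow time-lines

Transverse movies map 10–13 hpf onto 180 min with internalisation onset at
60 min (so "early" frames precede onset and the final frames are keel stage);
the reduced-scale acceptance runs sample them at 5-min intervals. Dorsal
surface-profile movies cover the constriction window itself, so
`dorsal_run_config` starts the clock at onset (60-min movies for area series;
240-min at 5-min intervals for event detection, long enough for events to
complete and be confirmed).

## Known limitations

* The generator's three renders are modality-specific 2D/3D idealisations,
  not one consistent optical volume; cross-modality registration is exact by
  construction and therefore untested.
* Wild-type internalisation events cluster in time (cells sharing the onset
  and similar rates internalise within a narrow window); the per-cell rate
  spread staggers them only partially.
* The dorsal render has no cell rearrangement or neighbour exchange; the
  Voronoi topology changes only through constriction and drift.
* `estimate_midline` requires reflection symmetry and fails gracefully (frame
  centre + warning) on asymmetric or flat-plate frames.
* Exact Mann–Whitney enumeration is limited to n₁+n₂ ≤ 12; with ties the
  normal approximation is used at any size.
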