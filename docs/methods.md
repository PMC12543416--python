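# Methods

`cagetrack` reconstructs what a dual-camera home-cage tracking rig measures:
where a single mouse is in its cage at every video frame, how long it spends
in each cage region, how far it travels, and how those quantities distribute
over the circadian day. This note documents the model, the defaults, and the
choices made where the design was genuinely open.

## Measurement model

Two infrared cameras view the cage orthogonally. The *front* view images the
cage-width (x) and height axes, the *side* view the cage-depth (y) and height
axes. An object detector reduces each frame of each view to midpoint-based
bounding boxes `(x, y, w, h)` for up to three objects: `mouse`, `house`
(shelter) and `wheel` (running wheel). Image coordinates are origin top-left
with y increasing downward; the fused height axis z inherits that convention,
so larger z means lower in the cage.

**Containment.** The mouse occupies a region when its *midpoint* lies strictly
inside the region's box in the front view *and* in the side view:

    q = q_front ∧ q_side,
    q_view = (B_x − w/2 < R_x < B_x + w/2) ∧ (B_y − h/2 < R_y < B_y + h/2).

Strict inequalities put boundary points outside. Only the midpoint is used —
box overlap is deliberately not — because occupancy is a statement about where
the animal's centre is, and midpoints are far more stable than box extents
under detector noise.

**Fusion.** Front and side midpoints combine into a 3D position

    P = (F_x, S_x, (F_y + S_y)/2)ᵀ,

i.e. each horizontal axis comes from the view that resolves it and the height
is the mean of the two views' vertical coordinates. This assumes the two
cameras resolve height at the same pixel scale (they are the same camera model
at comparable distances from a small cage); the per-axis calibration below
absorbs the remaining difference on average.

**Distances.** The per-frame step is the Euclidean norm of the position
difference; a trajectory's length is the sum over consecutive frames.
A `squared` mode returns the plain sum of squared per-axis differences
(no square root) — the form some rig loggers record;
it is not the default because travelled distance is reported in metres.

**Calibration.** Pixel-to-millimetre scales are per-axis linear, computed from
the known interior cage dimensions (268 × 215 × 141 mm, Eurostandard Type 2)
and the pixel extent the cage spans in each view. The identity calibration
(pixels) is the default; with a calibration, outside activity is reported in
metres.

## Stream processing

1. **Best-box selection.** When a detector emits several boxes for one label
   in one frame, the highest-confidence box wins; ties break to the larger
   area, then the lower x. (Real detectors occasionally emit duplicates; the
   tie-break only needs to be deterministic.)
2. **Static-object reuse.** House and wheel do not move. Frames where their
   boxes are missing reuse the most recent detected box for that label, with
   no cap; the stream errors only if a static object is never detected.
3. **Frame pairing.** Front and side frames are matched greedily by nearest
   timestamp, each frame used at most once, under a tolerance of 0.3 s — the
   inter-camera latency the recording setup tolerates. Unmatched frames are
   dropped and counted. Timestamps missing from a stream are derived as
   `frame_index / fps`.
4. **Gap filling.** Missed mouse detections are filled per view. The default
   policy repeats the last known position (`hold_last`); `linear`
   interpolation between the flanking detections is available. Gaps longer
   than `max_gap` (default 2 s of frames, i.e. 30 at 15 FPS) are left absent
   *in full* and booked as `unknown`: a hard cap prevents a long-lost animal
   from fabricating occupancy. The cap applies to leading gaps (back-filled
   from the first detection) and trailing gaps (held from the last) as well;
   booking a partially filled long gap half-known seemed worse than either
   extreme.

## Metrics

Each paired, gap-filled frame is classified `wheel`, `house`, `outside` or
`unknown`. Wheel takes precedence over house when both containments hold
(the wheel is mounted above the cage floor, so the 2D projections can
overlap); precedence is configurable. Region time is frame count over frame
rate, so for every phase and the session

    t_house + t_wheel + t_outside + t_unknown = n_frames / FPS

holds exactly at the level of integer frame counts — the reports carry the
counts alongside the derived seconds so the identity survives float
arithmetic. Unknown frames are excluded from the three region times and
reported separately; the source data gives no basis for booking them
anywhere else.

**Outside activity** sums step distances over consecutive frame pairs that
are both classified outside; a run interrupted by any other region
contributes no distance across the interruption. Phase aggregation breaks
runs at phase boundaries, so per-phase activities sum to at most the session
activity.

**Running speed** combines wheel time with the hourly revolution counts R of
a wheel-mounted magnetic counter: `v = R / t_wheel` in revolutions/second,
the formula-literal value; with the wheel diameter (default 11.5 cm) the
tangential speed `v·π·d` in m/s is reported alongside. Zero wheel time with
zero revolutions is a well-defined zero; revolutions without wheel time are
flagged undefined rather than silently dropped. Hourly counts are assigned
to the circadian window containing the hour's *start* clock time.

**Circadian windows.** Two presets, both anchored to a 12/12 h light/dark
cycle with lights on at 6 A.M. and feeding at 1 P.M.:

| preset    | windows |
|-----------|---------|
| `periods` | FAA 9 A.M.–1 P.M., PA 2–6 P.M., NA 6 P.M.–6 A.M., PRA 6–9 A.M.; feeding hour 1–2 P.M. excluded |
| `phases`  | Light 1 3–6 P.M., Dark 6 P.M.–6 A.M., Light 2 6 A.M.–1 P.M. |

Windows are half-open `[start, end)` on the local clock and may span
midnight. The feeding hour is excluded only under `periods`; under `phases`
the uncovered 1–3 P.M. span books as `unassigned`. Frames in excluded or
unassigned windows still appear in the session totals, so conservation holds
for the whole recording.

## The simulator

The generator emulates the recording rig, not mouse biology: a 268 × 215 ×
141 mm cage, 1,640 × 1,232 px cameras at 15 FPS, an 11.5 cm wheel, sessions
starting 3 P.M. Its purpose is to give every pipeline stage a ground-truth
oracle.

* **Occupancy** follows a continuous-time Markov chain over {house, wheel,
  outside} with exponential sojourns. Default mean dwells 240/120/60 s;
  an hour-of-day multiplier (2.0 in the dark phase, 0.8 in the light, 1.5
  during the 9 A.M.–1 P.M. pre-feeding window) divides the house (rest)
  dwell and multiplies the active dwells, producing dark-phase and
  food-anticipatory activity structure.
* **Trajectory.** Within a sojourn the mouse performs a reflected Gaussian
  random walk (per-axis step SD 1/2/6 mm per frame in house/wheel/outside)
  confined to a margin-shrunk core of the region volume. The 8 mm region
  margin keeps detection jitter from flipping containment at region walls;
  a 36 mm image-edge margin keeps the rendered body fully inside the frame.
  The *outside* volume is a floor corridor disjoint from both region boxes
  along the depth axis, so simulated labels are exactly recoverable by the
  classifier — by construction there are no geometrically ambiguous frames.
  Sojourn entry points are drawn uniformly (the animal may "teleport" at
  transitions; only frame-level occupancy, not continuity across
  transitions, is measured against truth).
* **Wheel counter.** Hourly revolutions are `1.1 rev/s × wheel seconds`
  plus Gaussian noise (SD 20 rev/h), floored at zero and rounded. The rate
  matches the magnitude a food-restricted mouse shows in this assay
  (thousands of revolutions over a few thousand seconds of wheel time).
* **Corruption.** Mouse records are dropped i.i.d. with `miss_prob`,
  surviving midpoints get isotropic Gaussian pixel jitter, spurious
  low-confidence boxes appear at `false_box_rate` per frame, and side
  timestamps carry a constant latency offset. All randomness flows from one
  seed through named substreams, so changing the corruption never perturbs
  the trajectory.
* **Rendering.** Frames are grayscale: dark floor (8), dim house and wheel
  rectangles (60, 105), bright mouse ellipse (255) with axes matching the
  70 × 30 × 30 mm body. Rendering is deterministic. The shelter is
  transparent — the real rig's occlusions are exactly what the gap-filling
  stage exists for, and those are modelled by `miss_prob` instead.

**What passing tests do and do not show.** The simulator's corruption is
i.i.d. and its regions are geometrically unambiguous, so recovery within a
few percent here demonstrates the *pipeline arithmetic* is right — not that
a real detector achieves that accuracy on infrared video, where misses are
bursty (shadowing, odd postures) and region projections genuinely overlap.
The correlation analogue likewise validates the bookkeeping linking wheel
time to revolutions, not any biological effect size.

## Blob detector

A stand-in for the learned detector a real rig runs: fixed or Otsu
threshold, 4-connected components, area filter, largest surviving
component's bounding box; confidence is the component's mean intensity over
255. On rendered frames a fixed threshold of 180 (above both region-marker
intensities) is the reproducible choice; Otsu can settle between the floor
and the markers instead of isolating the body. Static regions are located
in a mouse-free reference frame by their intensity bands.

## Numerical choices and degenerate inputs

* Boundary points are outside (strict inequalities); classification is
  invariant to the mouse box extent by construction.
* Conservation is asserted on integer frame counts; float equality of the
  derived seconds holds to 1e-6 s.
* Projection→fusion inversion is exact to double precision (≤ 1e-9 mm);
  the mm→px→mm round trip cannot be bit-exact for arbitrary scales.
* `pair_frames` uses a vectorised nearest-match fast path when the
  assignment is one-to-one (regular frame grids) and falls back to an
  explicit greedy scan otherwise; both produce the same matching.
* Degenerate cases: empty trajectory, all-absent track, zero-variance
  correlation inputs and zero tolerance are errors; zero wheel time with
  zero revolutions is zero speed; a phase containing no frames reports
  zeros with an `empty` flag.
* Stream assembly and evaluation are column-wise numpy end to end (no
  pandas block consolidation, no whole-frame row copies), keeping a 22 h
  session around 1 GB resident and minutes-scale on one CPU.

## Problem sizes used in validation

Acceptance-style checks run at desk scale, chosen once: geometric oracles on
10³–10⁴ random inputs; conservation on one 22 h session at 15 FPS (~1.2 M
frames); recovery on twenty 2 h sessions at 5% miss, 2 px jitter, 0.2 s
latency; the correlation analogue on 100 simulated hours at 5 FPS; the
render→detect→evaluate loop on a 10 min session at 328 × 246 px. The
reduced frame rate and frame size in the last two keep long-horizon runs
tractable without touching the behavioral or corruption parameters.

## Known limitations

* Single animal only; no identity maintenance.
* No lens-distortion correction or true stereo triangulation; fusion
  assumes orthogonal views and a shared height scale.
* The dwell model is not a biological claim; dwell distributions, bursty
  detector failure and occlusion structure of real recordings are out of
  scope of the generator.
* Running speed is inherently unit-ambiguous in this assay: `R / t_wheel`
  is revolutions per second, while labs conventionally quote metres per
  second. Both are reported (m/s via the wheel circumference) rather than
  picking one.
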