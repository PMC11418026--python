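# Methods

This note documents the models, conventions and numerical choices behind
`salticid_vision`, in the order the data flow through the package.

## Coordinate system and arena geometry

All stimulus positions are 1-D spider-centric azimuths: 0 deg directly
ahead, positive to the animal's right (clockwise seen from above),
normalised into (−180, 180]. Elevation is ignored throughout — stimuli are
presented at the animal's eye level, and none of the modelled computations
depend on it.

The arena is two flat monitors of width *w* joined along a vertical edge at
an inter-panel angle *θ*, with the spider on the symmetry axis at distance
*d* from the junction. A point at arclength *s* along the right panel sits
at room coordinates (*s* sin(θ/2), *d* − *s* cos(θ/2)), so its azimuth is
atan2 of those components and the total coverage is twice the outer-edge
azimuth (azimuth is monotonic along a straight panel). For *w* = 537 mm,
*d* = 200 mm this gives 196.8 deg at θ = 120 and 262.5 deg at θ = 65,
matching the rounded spans quoted for the physical arena (~200, ~265), and
leaves a 97.5-deg wedge behind a forward-facing animal. A backward-facing
animal sees the same panels rotated by 180 deg; the junction is then at
±180 and the room-left monitor appears on the animal's right.

Eye fields are sets of closed azimuth intervals per eye pair. The
*behavioural* defaults follow the mapping experiment: ALE = [−50, +50],
PLE = ±[60, 180], with the 50–60 deg annulus covered by neither pair, and
empty AME/PME fields (principal eyes occluded; posterior median eyes
vestigial). The published span of the rear field is stated as ~260 deg,
which matches 360 minus the ALE span rather than the literal ±60→±180
interval (240 deg); the package reports the former and treats the
edge values as configurable rather than reconciling the discrepancy.

## Stimuli

**Biological walker.** The package needs a dot stimulus with the one
property that defines biological motion here: visually trackable points at
mutually fixed distances. The canonical walker is six dots in three rigid
pairs; each pair keeps an exactly constant within-pair separation (seeded
from 2–4 deg) while its centre oscillates pendularly (amplitude 3 deg)
about a centroid translating at 9 deg/s. Oscillation phases are evenly
spaced and mean-corrected every frame, so the cloud centroid equals the nominal
trajectory exactly. The stride rate defaults to 2.5 Hz — a realistic
walking rhythm, and fast enough that a scrambled copy diffuses visibly
within one presentation: the variance ratio between a scrambled display's
pairwise-distance diffusion and the walker's own articulation scales as
(2πf)²·T/(6·frame_rate), which is ≈3 at 2.5 Hz but <1 at 1 Hz (where a
"random" display would paradoxically look *more* rigid than the walker).

**Random (scrambled) display.** Per frame, the residual displacements
(each dot's step minus the common centroid step) are permuted across dots
with a seeded RNG. This preserves the centroid path *exactly*, preserves
the per-frame displacement-magnitude multiset *exactly* (so total motion
is identical), and destroys all local structure — pairwise distances
perform a random walk. Globally the two displays are indistinguishable by
construction; locally only the walker is coherent.

**Shapes.** The silhouette and ellipse stimuli of the second condition are
represented as rigid six-dot contours. To a purely azimuthal motion model
the two are identical by construction; this encodes the working hypothesis
that shape (as opposed to motion-structure) differences are a
principal-eye matter, outside this model's scope.

**Protocols.** Experiment 1: after 210 s of habituation, a 4-deg dot
sweeps one monitor at 9 deg/s (junction↔outer edge, side and direction
seeded-random), 30 presentations, 15-s gaps. Experiment 2: mirrored
left/right display pairs travel between ±90 and ±10 deg with a 1-s pause
at ±50 deg, 20 repetitions, 25-s gaps, biological side and direction
randomised per repetition. Paths are sampled at 120 Hz with the exact
endpoint appended when frame quantisation would fall short; the dwell
covers exactly 120 frames. The translation speed of the display pairs is
not independently specified and defaults to the experiment-1 value.

## The three-layer integration model

**Layer 1** is per-eye dot occupancy over azimuth bins — photoreceptor
input, zero for dots outside the eye's field.

**Layer 2** contains one detector sheet per eye stream, both evaluated
over a sliding window (default 1/3 s) on the stimulus dot group:

* **PL1** (PLE stream, global motion): fires at the bin under the group
  centroid when the centroid has displaced at least `motion_threshold`
  (default 1 deg) over the window. Because the walker and its scrambled
  twin share a centroid path, PL1 cannot distinguish them — by design.
* **AL1** (ALE stream, local coherency): as PL1, but additionally requires
  the group to be locally coherent: at least half the dots must have a
  partner whose pairwise distance varies by less than
  `coherency_threshold` (default 0.1 deg std) across the window. Rigid
  pairs pass with std ~0; scrambled displays never pass. A lone dot is
  vacuously coherent — single-dot stimuli must remain detectable through
  the ALE stream, as the mapping experiment shows they are.

The receptive-field localisation uses the group centroid (one active bin
per stimulus per stream) rather than raw per-dot occupancy: limb
oscillation makes the cloud's edge bins flicker several times per second,
which would riddle the comparator layer with artefactual events that the
real system's coarse receptive fields would never see. Eye assignment
follows the centroid bin, so at the field boundary the stimulus hands over
from one sheet to the other on exactly one frame.

**Layer 3** is a sheet of comparator (XOR-style) gates, one per bin, each
receiving direct input from its own layer-2 bin and delayed (by τ) input
from the neighbouring bins — a Hassenstein–Reichardt delay-and-compare
motif one stage above the retina. A gate fires when exactly one input
side is active, evaluated with one-bin neighbourhood tolerance:
*appearance* (direct active, no delayed activity at the bin or its
neighbours) or *disappearance* (delayed active, no direct activity in the
neighbourhood). A stimulus tracked smoothly across neighbouring bins —
one bin per τ — keeps every gate silent; onsets, offsets, stops, starts
and detector mismatches fire them. The neighbourhood tolerance on both
sides is necessary: a bare XOR against the OR of delayed neighbours fires
continuously at the gate trailing two bins behind any moving stimulus.

**Decision.** Gate activity is split into contiguous bursts; each burst
yields a pivot toward the bin with the highest summed activity, exact
ties broken uniformly at random (seeded). Two mirrored stimuli seen only
by the PLEs produce exactly tied bursts — bin edges are nudged toward
zero so mirroring is exact at edge values — hence 50/50 pivot directions.
Targets within the frontal dead zone (default ±5 deg, roughly the
principal eyes' own field) trigger no pivot: orienting toward a target
already faced is vacuous. The first decision per presentation is the
analysed orienting response; all decisions enter preference scoring, with
pivot amplitude equal to target eccentricity (the animal turns to face).

**Numerical choices.** Bins are 6 deg wide so that τ = bin_width/(9 deg/s)
is an integer number of frames (80) at 120 Hz; with 5-deg bins τ = 66.7
frames and the smooth-tracking cancellation breaks at every bin crossing.
The model's eye fields are contiguous at ±54 deg (a bin edge between the
behavioural estimates of 50 and 60): the multi-eye handoff mechanism —
walker crosses PLE→ALE silently, scrambled display "disappears" — requires
the two sheets to tile the azimuth without a seam. Both are configurable.

With these pieces the model reproduces the qualitative pattern: ALE-only
runs pivot to the walker essentially always (the scramble is invisible);
PLE-only runs are at chance; full-field runs with the narrow stimulus
geometry (±60→±5, no pause) show a net pivot tendency toward the
*scrambled* display via the handoff burst, and the wide ±90→±10 geometry
weakens/reverses that tendency — the long PLE-only approach and the pause
at ±50 give the walker extra salient events of its own.

## Treadmill scoring

The sphere-frame z-velocity series (deg/s, positive = clockwise sphere
seen from above) is the per-frame z increment times the frame rate.
FicTrac-style input is either per-frame z increments or per-frame 3×3
rotation matrices (decomposed with scipy's rotation machinery;
non-orthonormal matrices are renormalised by SVD with a warning). The
spider's intended rotation is the sphere's negated — applied in exactly
one place (the scoring operations), never in the series itself.

Peak detection: 5-frame moving-average smoothing, candidate extrema above
10 deg/s in both polarities, each extended to its bounding zero crossings;
the signed area is the trapezoidal integral of the smoothed velocity over
that lobe. Whether the 20-deg area criterion is evaluated before or after
smoothing is not fixed by the published text; the package evaluates it
after, and all parameters are explicit arguments.

Experiment-1 scoring: per presentation, the first peak with ≥20 deg of
area whose spider-intended direction matches the stimulus side; the
detection angle is the stimulus azimuth at peak onset. Peaks are
associated to presentations on [onset, next onset), so responses to a
stimulus vanishing at the end of its sweep still count — they are what
puts the backward-orientation mode at 180 deg. Detection histograms use
5-deg bins centred on multiples of 5; ±180 share a bin.

Experiment-2 scoring: every peak is signed positive if the intended
rotation is toward the biological/silhouette side, and the preference
statistic is the mean signed peak velocity. Inference is by seeded
sign-flip permutation (exact enumeration of all 2ⁿ patterns for n ≤ 15,
sampled otherwise) and a percentile bootstrap CI that resamples spiders
when group labels are supplied — a deliberate replacement for the original
mixed-model analysis, whose printed coefficients depend on the animal
recordings and are not reproduced here.

## Virtual spiders

The descriptive virtual spider responds to *detectable events* of a
presentation — the stimulus centroid appearing, disappearing, or crossing
an active eye-field edge, excluding events within ±5 deg of straight
ahead. With probability `response_probability` (defaults: 0.204 with ALEs
available, 0.111 PLE-only — the study's observed per-presentation
response rates) it picks one event uniformly, waits a lognormal latency
(median 0.10 s, σ = 0.35), and pivots toward the event azimuth. Pivots
are raised-cosine velocity pulses of 0.5 s whose discrete integral equals
the drawn amplitude exactly (normal, mean 40, sd 5, truncated to 25–60 deg
so every response clears the 20-deg criterion); the sphere-frame pulse
sign is opposite to the intended rotation. Baseline activity is white
Gaussian velocity noise (sd 2 deg/s), far below the 10 deg/s peak
threshold after smoothing. Latency and amplitude distributions are
explicit stand-ins — the study does not print them.

In model-driven mode the integration model's decisions are injected
instead, with amplitude equal to target eccentricity.

What the generator emulates: event-locked responding, response
probability, the sphere/spider sign inversion, detection at field edges,
and the file dialects of the deposited data. What it does not: optical
tracking artefacts, translation (x/y) components, drift, forward walking,
per-animal idiosyncrasies beyond Bernoulli responding, or the real
latency/amplitude distributions. Passing end-to-end tests therefore shows
the pipeline is self-consistent and recovers known ground truth — not
that real spiders behave like the generator.

## Scales used in the shipped analyses

The virtual mapping experiment runs 50 spiders per condition (30
presentations × two arena angles each) in the acceptance script and 16–30
in the tests/analysis drivers; the model experiments pool 60–120 runs.
These sizes put ~300–600 detections in each histogram, enough that the
modal bin is stable across seeds while a full run stays in the tens of
seconds on one core.

## Known limitations

* The model is 1-D and binary; no spiking dynamics, adaptation, or
  learning, and no AME scanning behaviour.
* The walker is a stand-in articulated pattern, not a reconstruction of
  the original display's joint kinematics (defined in earlier work and
  not printed here).
* The full-field (ALE+PLE) prediction with the wide ±90→±10 geometry is
  a net *biological* tendency, where the animals showed none; the model
  deliberately contains no response-probability, habituation or attention
  terms that would dilute it.
* Mixed-model coefficients from the original analysis are not
  reproducible from synthetic data and are treated as out of scope; the
  deposited per-spider tables can be fed through `preference_statistic`
  if available.
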