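# Methods

## Track data model and dialect

A track is a time-ordered series of K-point midlines (head→tail, mm) with
per-frame validity flags; frames where the tracker lost the animal are
kept and flagged rather than dropped, because the population statistics
need to know who was tracked when. The on-disk dialect is a flat TSV
(one row per larva and frame, blank spine cells for untracked frames,
optional semicolon-joined contour column) chosen to be diff-able and
close to Multi-Worm-Tracker/Choreography exports. Defaults: K = 11 spine
points, 10 Hz frame rate, millimetres and seconds throughout — all
configurable, since tracker output conventions vary. The centre of mass
G is the arithmetic mean of spine points; that is the construction the
downstream features (‖HG‖/‖TG‖, bend angle, motion speed) need, and it
avoids any dependence on contour quality. Head/tail orientation is
trusted from the input; automatic head–tail disambiguation is out of
scope.

## Per-frame features

All speeds are normalized by the instantaneous midline length, making
every feature scale-free; the test suite checks scale and rotation
invariance explicitly.

Choices where the construction was genuinely open:

- **Velocity estimator**: central difference over one frame (stencil
  configurable). One frame keeps fast actions (a Hunch lasts ~0.5 s)
  sharp at 10 Hz.
- **Body axis for S**: the unit vector from tail point to head point.
  Since S uses cos²θ, the sign of the axis is irrelevant.
- **Movement covariance for λ**: covariance of per-frame centre-of-mass
  displacement vectors over a centred 5-frame sliding window. Shorter
  windows make λ noisy; longer ones smear action boundaries.
- **Static-Bend speed threshold**: the threshold on the length-normalized
  motion speed is 0.02 s⁻¹. (Normalized speeds have units of s⁻¹; a
  printed unit of s⁻² for this quantity is read as a typographical slip.)
  The garbled "50 % of the n time step" phrasing is operationalized as:
  the normalized motion speed must be below threshold on at least 50 %
  of the action's frames.
- **Velocity-onto-spine projection**: the end-point velocity vector is
  anchored at the head (tail); the spine segment closest to the vector's
  endpoint is selected and the signed component of the velocity along
  that segment's head→tail direction, normalized by length, is returned
  (positive toward the tail). The orthogonal residual is available via
  `mode="residual"`; the signed component is the default because it
  separates retraction from lateral sweeping, which is what the
  refinement needs.
- **Terminal-segment cosines** are oriented outward (first segment
  toward the head, last toward the tail), so forward crawling yields
  cos_head ≈ +1.

Per-action aggregation: mean/max/min of each feature over the action's
frames, plus mean context over 5 frames before and after (truncated at
track edges and flagged), plus the duration — a 71-dimensional vector.
NaNs (untracked context, degenerate geometry) become zeros at vector
assembly; the forests treat that as just another split value.

## Base layer and refinement

The coarse layer is pluggable. Pass-through mode accepts externally
computed coarse intervals (the normal route when an upstream pipeline
already produced Crawl/Bend/Hunch/Back/Stop/Roll labels); rules mode is
a documented stand-in that tiles tracks from thresholds on a minimal
feature set (speeds, bend angle, length-change rate, signed forward
speed), merging runs shorter than 0.3 s into their left neighbour. The
stand-in is deliberately simple; the package's contribution is the
refinement on top of whatever coarse layer is used.

Refinement is two random-forest layers (default 300 trees, unlimited
depth, √p features per split, fixed random state): layer 1 maps coarse
Bends/Hunches to {newHunch, StaticBend, HeadCast}; layer 2 maps the new
Hunches to {Hunch, HeadAndTail, CShape}. A `layer1_classes=4` option
adds CShape as a direct layer-1 output, for the alternative reading in
which a Bend can map straight to a C-shape; the three-class layout is
the default because it matches the procedure description. Ties in
ensemble voting resolve by alphabetical class order (scikit-learn's
class ordering for string labels). All other coarse labels map 1:1
(Crawl→Crawl, Back→BackUp, Stop→Stop, Roll→Roll); output intervals tile
the input intervals exactly. Head Cast slow/fast subtypes are assigned
post hoc from the mean normalized tail speed (default threshold
0.10 s⁻¹), not by the trained layers.

Training labels: Head Casts are sampled at random from pre-stimulus
Bends; Static Bends from the during-stimulus low-motion rule above; the
Hunch/Head-and-Tail/C-shape tags come from the synthetic generator's
ground truth, standing in for manual annotation. Tagged classes take
precedence over the auto-tag rules (a C-shape is as slow as a Static
Bend, so the speed rule alone would double-label it). A class with fewer
than `min_per_class` (default 20) examples is an error naming the class.

## Synthetic data generator

The generator defines the study conditions for every test: it is
first-class, tested code, not a fixture. Each action is realized as a
midline motif whose defining inequality holds on every zero-noise frame:

| motif | construction | key constants |
|---|---|---|
| Crawl | straight body, forward CoM at 0.06 body-lengths/s, sinusoidal length modulation ±8 % at 0.4 Hz | FastCrawl = 1.5× speed |
| HeadCast | anterior half sweeps ±60° at 0.75 Hz about a fixed mid-body pivot | head speed ≈3.7× CoM speed; "fast" subtype adds a ∓35° posterior counter-sweep |
| StaticBend | held 100° mid-body kink (chord-based bend angle ≈ 57°), zero motion | normalized motion speed 0 < 0.02 s⁻¹ |
| Hunch | anterior segment lengths contract to 0.6× within 0.4 s, tail anchored, body straight | head–centroid distance drops ≈29 % |
| HeadAndTail | both halves contract to 0.6× | total length drop 40 %, larger than a Hunch's |
| CShape | static uniform arc, 240° total turning | chord-based bend angle ≈ 102° |
| Roll | bend side alternates ±110° at 2 Hz with lateral CoM translation | planar proxy for a 3-D action |
| BackUp / Stop | rearward CoM at 0.04 BL/s / no motion | — |

The peristaltic frequency (0.4 Hz) is set so the crawl's length-change
rate stays well below a Hunch's contraction rate — the two quantities a
length-based coarse rule must separate. Amplitudes are synthetic
conventions chosen for separability and plausibility, not measurements;
real inter-larva variability in speeds and motif durations is
unpublished, so population defaults (motif duration ranges, kernel
probabilities) are placeholders at realistic orders of magnitude.

Populations draw motif sequences from epoch-dependent categorical
kernels (baseline vs stimulation, switched exactly at the epoch
boundaries on the frame grid), with a configurable fraction of larvae
untracked at stimulus onset (picked up 0.5–3 s after onset), emulating
tracker dropouts. The default protocol is a 4 m/s air puff from 60 s to
90 s of a 100 s recording. Noise: i.i.d. Gaussian jitter per spine point
and an optional random-walk heading drift.

What the generator does **not** emulate: contour deformation (no contour
model beyond the midline), biomechanics, gradual action onsets/offsets
(motif boundaries are instantaneous), head–tail ambiguity, segmentation
errors, or arena-boundary effects. Passing recovery tests therefore
demonstrates the pipeline's correctness and internal consistency — that
well-separated actions are recovered and every rule behaves as specified
— not classifier performance on real tracker output.

The synthetic connectome builds a hemilateral target pair whose input
synapses are distributed over presynaptic classes with configured
fractions (exactly in constructed mode, multinomially when drawn), plus
"unreconstructed" partners below the node threshold and a small
downstream motor pathway for the distance analyses. The fluorescence
generator emulates the 5 s baseline / 5 s stimulation / 5 s recovery
assay, with a 1 s linear rise to a plateau whose true ΔF/F0 equals the
configured amplitude, and optional injected pre-stimulus transients.

## Statistics

- Cumulative probability conditions on larvae tracked at the window
  start (nearest valid frame within half a frame period); a larva
  performing the action twice counts once.
- Transitions are pairs of consecutive distinct intervals, timestamped
  at the destination interval's start; a flag restricts to each larva's
  first in-window transition (the default counts all, since the
  convention is ambiguous in figure captions). Self-transitions cannot
  occur (consecutive same labels are one interval). Cells below the 3 %
  display threshold are masked for display, never removed from the data.
- Chi-square: plain Pearson, two-sided, no Yates correction (a flag
  restores it); Benjamini–Hochberg step-up for multiple testing, with a
  planned-comparison mode that reports raw p-values.
- KS: D is the exact ECDF supremum; the p-value is asymptotic by default
  with an exact small-sample option.
- KDE: Gaussian kernels, Scott's rule bandwidth; zero-variance samples
  fall back to a small fixed bandwidth with a warning.
- Window presets: 1 s, 3 s, 5 s after onset and 10–30 s within the
  stimulus.

## Connectomics

Hemilateral pairing is metadata (a loader fills it from `_l`/`_r` id
suffixes for CATMAID-style exports), never inferred during analysis.
The strong-partner rule aggregates synapse counts per (seed member →
partner member) connection and admits a partner pair when the maximum
single connection carries ≥3 synapses. The fragment threshold
(node_count < 1,500, strict) exempts sensory neurons; fragments leave
named-partner listings but stay in every input-fraction denominator.
Connection types (axo-dendritic, axo-axonic, …) are carried through so
type-resolved fractions can be reported; defaults pool all types, and
hop distances treat all edge types as ordinary directed edges.

## Calcium

F0 is the mean fluorescence over the baseline window (default: the full
pre-stimulus segment). "Activity before stimulation" is operationalized
as baseline |ΔF/F0| exceeding a configurable threshold (default 0.3) at
any baseline timestep; exclusions are logged with the offending peak.
When repetition counts differ across larvae, a seeded subsample reduces
every larva to the minimum count before averaging. Dispersion is the
s.e.m. across larvae by default, across retained repetitions on request.

## Problem sizes and determinism

The recovery experiments train on 60 synthetic larvae and score 200
(about 4,300 refined intervals); oracle suites use 1,000 random postures
and 100–200 random statistical fixtures. One global seed fans out to
per-stage child seeds via `numpy.random.SeedSequence`, so full pipeline
runs are deterministic and their CSV outputs byte-identical across
repeats.

## Known limitations

- The rules-mode coarse layer is a stand-in; on real data the upstream
  pipeline's coarse labels should be supplied in pass-through mode.
- Roll is accepted from the coarse layer as given; the planar Roll proxy
  cannot capture true rolling kinematics.
- A GtACR1-style second classifier (different genotype baselines) is a
  retraining recipe — same machinery, different training data — not a
  separate implementation.
- Synthetic separability means recovery metrics are upper bounds;
  expect lower recall on real, noisy, boundary-ambiguous tracks.
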