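# Methods

This note documents the models, parameters, and design choices behind
`seegviz`, and what the synthetic phantom does and does not emulate.

## Working space and conventions

All volumes are reoriented to RAS+ immediately after load (axes
permuted/flipped without moving any voxel in world space) so that
left/right is consistent between image space and the exported scene; any
single fixed convention satisfies the left/right alignment requirement,
and RAS+ is the one most neuroimaging tools default to. Voxel indices
are 0-based; world coordinates are millimetres through the NIfTI affine;
all distances are reported in mm. The working space for contact
segmentation is 1 mm isotropic. Registration between CT and MRI is
consumed, not estimated: `apply_rigid_transform` applies a user-supplied
FLIRT-style matrix and tolerates ‖RᵀR−I‖ < 1e-3 (text-file rounding),
rejecting anything worse.

## Contact segmentation

Parameters (defaults chosen for CT with heavy, un-corrected metal
artifact):

| parameter | default | meaning |
|---|---|---|
| `metal_percentile` | 99.5 | threshold over in-mask CT intensities |
| `median_kernel_radius_mm` | 0.5 | spherical median filter radius |
| `rethreshold_percentile` | 40 | re-binarization after linear resampling |
| `mask_erosions` | 3 | brain-mask erosions (6-connected) before masking |
| `template_edge` | 3 | representative contact cube edge (voxels ≙ mm) |

The percentile populations are deliberate choices: the 99.5th percentile
is computed over voxels inside the 3×-eroded brain mask only, and the
40th percentile over strictly positive values of the resampled map —
both make the thresholds independent of the background-zero fraction.
The median-filter kernel contains every voxel whose centre lies within
the radius; at 0.5 mm native CT spacing this is a 7-point cross, at 1 mm
it degenerates to the identity (the kernel radius is read as a radius,
not a diameter).

The grouping/erosion loop alternates: group 6-connected components
(diagonal adjacency never joins components, which keeps nearly-touching
contacts apart); replace every component smaller than half the
representative (< 14 voxels) — or fitting inside it (all extents ≤ 3) —
by the 3×3×3 template centred on its rounded centroid; apply exactly
**one** 1-D erosion to each remaining component, choosing the first rule
that applies in the order: z-extent > 3 → erode along x, x-extent > 3 →
erode along y, y-extent > 3 → erode along x. One erosion per pass is
essential: a component that splits (e.g. two contacts bridged by a
streak) is re-grouped and its pieces replaced before any further erosion
can destroy the 3-voxel-wide contact cores. Note the rule set never
erodes along z; a z-running bridge is still split because the z-rule
erodes across it. A fallback erosion along the widest oversized axis
guarantees progress on shapes no rule reduces (unreachable in practice —
any fired 1-D erosion removes boundary voxels). Total unreplaced voxel
count strictly decreases per pass, so termination is structural.
Components at the lattice edge are processed normally; their template
cubes are clipped at the bounds with the midpoint preserved. Midpoint
centroids use round-half-even at exact .5 ties (NumPy rounding).

Known limitation: when a merged component's *first-firing* rule erodes
along the electrode shaft (an x- or y-running electrode whose
perpendicular extent exceeds 3 voxels through tilt or artifact), the
contact cores can erode away before the bridge splits, leaving a
displaced or missing midpoint. This affects a ~10–15% tail of contacts
under heavily streaked synthetic conditions and is the dominant error
source in the localization summary.

## Electrode building

The builder is greedy: seed with the contact farthest from the
brain-mask centroid ("outermost", ties broken lexicographically), pair
it with its nearest neighbour (within the search distance, else it
stays a logged singleton), then repeatedly add the contact within
`search_distance` (15 mm) of the **most recent** contact whose turn
angle relative to the previous inter-contact direction is at most
`max_deviation` (20°, which absorbs shaft bending without ever merging
parallel electrodes ~10 mm apart). Preference among eligible candidates
is smallest distance, then smallest angle. A finished electrode's
contacts are removed and the procedure restarts on the remainder, so
the result is a partition; internal lexicographic ordering makes it
independent of input order. Numbering follows the deep-equals-one
clinical convention: contact 1 is the chain end nearer the brain
centroid (exact ties go to the lexicographically lower endpoint).
Naming is anchor-based (nearest electrode tail within the search
distance; ambiguity is an error listing candidates; unmapped electrodes
are auto-named `E<k>`); no atlas-based naming is attempted.

## Signal processing

The clip is ±2 s around the chosen annotation (clamped at record edges
with a warning; duplicate labels require an explicit occurrence index).
Filtering is zero-phase throughout (forward–backward application) so
burst timing never shifts relative to the seizure marker. The notch
(IIR, Q = 30) defaults to 60 Hz mains and, deliberately, the fundamental
only: the 120/180/240 Hz harmonics lie inside the 80–250 Hz analysis
band and notching them would carve holes out of the very activity the
power trace is meant to display (`notch_harmonics` raises the count for
recordings with strong harmonic contamination). The bandpass is a
Hamming-window FIR, transition width 10 Hz (~53 dB stopband), order
⌈3.3·fs/10⌉ rounded odd.

Windowed power is the mean of squares over consecutive, non-overlapping
N = 24-sample windows (the final partial window averages over its actual
length, giving ⌈samples/N⌉ windows — 167 for a 4 s clip at 1 kHz).
Normalization is one global affine min–max map across all contacts and
windows; per-channel scaling would destroy the between-contact power
comparison the animation encodes. Because of this global scaling, any
positive constant factor in the power definition cancels exactly (a
property the tests assert directly). An all-equal trace normalizes to
zeros with a warning. Channel-to-contact matching is case-insensitive
exact match on `<name><number>`; unmatched channels are excluded and
logged.

## Scene generation

Surfaces come from marching cubes (Lewiner) at iso-level 0.5 on the
zero-padded binary mask, with vertices mapped to world mm and winding
oriented outward. Contacts are rendered as 3 mm cubes (the
representative's extent) at their midpoint; normalized power maps
linearly to uniform scale with power 0 at base size (contacts never
vanish) and power 1 at a 60 mm extent — read as the rendered extent of
the largest-power contact, so the scale factor is 20. Keyframes sit
1 s apart, one per data window, with linear interpolation. The timeline
is generated programmatically: one marker per whole second of data
(0…⌊clip⌋, i.e. five markers for a 4 s clip) along a bar 10 mm below
the brain bounding box, plus a red marker at the annotated event.
Materials are cosmetic (semi-transparent tissues, gold contacts).
Export is glTF 2.0 JSON with an embedded base64 buffer; FBX is not
produced (closed format). A light-weight reader (`import_gltf`) supports
round-trip verification, and scenes load in external glTF tooling.

## The phantom: what it emulates, and what it does not

The CT phantom models: an ellipsoidal brain (semi-axes 48×58×42 mm) of
soft-tissue intensity 40 inside a hyperintense skull shell (1200);
electrodes as straight or slightly bent trajectories of 0.8 mm-diameter,
1.5 mm-long contacts at 3.5 mm pitch (2 mm inter-contact gap); each
contact rendered as a Gaussian blob of width √((d/2.355)² + σ_PSF²)
with σ_PSF = 0.5 mm, whose **peak is the metal intensity (3000) scaled
by the partial-volume ratio** of the contact cylinder to the PSF kernel
volume (~870 at defaults) — a 0.8 mm contact in a 1 mm voxel never
reaches full metal intensity; bright 1-voxel streak bridges between
`streak_count` random neighbouring contact pairs (intensity 400), the
failure mode the directional erosion exists to split; 250 diffuse
artifact rays (amplitudes 100–400, fading exp(−s/8 mm)) radiating from
the electrodes, which fill the in-mask 99.5th-percentile quota so the
metal threshold sits in the artifact intensity range well above tissue —
the regime a non-artifact-corrected post-implant CT puts the pipeline
in. Rays keep 3.5 mm clear of contact centres: near-contact artifact is
already modelled by the blur and bridges, and physically merged blobs
are represented by the bridge streaks, not by welding the whole shaft
into one mass. Additive white Gaussian noise (sd 8) completes the
volume. Tissue masks (white core, gray shell, thin CSF rim) partition
the brain ellipsoid and stand in for an MRI segmentation.

The recording models 1 kHz pink-noise background (15 µV RMS) per contact
channel, a text annotation at the seizure time, and Gaussian-enveloped
120 Hz bursts (60 µV, σ = 80 ms): along one electrode the burst onset
advances 100 ms per contact number (deep to superficial), the
propagation pattern the animation is designed to reveal; other
electrodes receive a single weaker burst at a fixed latency. EDF+C
files are written by a small built-in writer and read back through MNE.

Not emulated: beam-hardening physics, anatomical tissue geometry, MRI
contrast, inter-electrode cross-talk, realistic seizure morphology
(spike-wave evolution), or sub-mm native CT resolution. Consequences:
the 0.5 mm median filter is an identity at the phantom's 1 mm native
spacing, so streak speckle that a clinical sub-mm CT pipeline would
remove survives here as unmatched "contact" fragments — passing tests
therefore demonstrate localization accuracy and artifact-splitting on
merged contacts, not false-positive suppression at clinical resolution.
Fragments are discarded in practice at the naming/channel-matching
step, mirroring the clinical workflow where only planned electrodes
receive names. For the artifact-free grouping-oracle condition the tests
use wide-pitch (5 mm) electrodes and noise sd 15: with no artifact
filling the percentile quota the threshold drops into the noise tail,
and these settings keep neighbouring blur tails from bridging at that
threshold (a clean, low-artifact CT).

## Validation statistics

Automated midpoints are matched to reference points by repeatedly taking
the globally closest pair under a 5 mm gate (greedy mutual-nearest);
at typical inter-contact spacing this equals the optimal one-to-one
assignment, which the tests verify against brute-force enumeration on
small instances. References may be snapped to the nearest voxel first
(mirroring raters who mark between voxels). Unmatched references count
as *missed*; matched distances are summarized as mean ± sd (mm) and
binned in voxel units (≤1, (1,2], (2,3], >3). Empty inputs yield an
empty report with NaN statistics rather than an error.

## Problem sizes

Default problem sizes — a 128³ phantom at 1 mm, 10-phantom acceptance
batches, 4 s clips at 1 kHz — were chosen so the full pipeline runs in
seconds per phantom on a single CPU while keeping every geometric and
spectral feature the algorithms depend on at clinical scale (real brain
extents, contact pitch, sampling rate, and band edges are all
life-size; only the number of electrodes per study is at the low end of
clinical practice).
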