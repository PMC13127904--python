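# Methods

`camoevolve` simulates the artificial evolution of camouflage: genetically
encoded prey patterns are rendered into synthetic ground scenes under
direct or diffuse illumination, hunted by a synthetic observer whose
detection time is the fitness signal, and evolved by a genetic algorithm.
This note documents the models, the defaults and why they were chosen,
and what the synthetic components do and do not capture.

## The genome and the genetic algorithm

Each individual is a haploid chromosome of 36 decimal genes in [0, 1]
(34 pattern loci plus 2 gloss loci).  The full locus table is in the
`pattern_gen` module docstring; briefly: reaction-diffusion rates and
nucleation, three CIELAB colours, marking threshold and geometry
(scale, orientation, anisotropy), countershading slope/offset,
edge-enhancement strength/width, plus coarse+fine paired loci so the GA
has a two-resolution encoding.  The exact meaning of each locus is a
design of this package: the locus semantics of the original pattern
toolbox are published elsewhere and no enumeration was available, so any
documented bijection that spans the same trait families preserves the
behaviour class of the search.

Populations of 24 start from a per-locus stratified uniform sample (each
locus's 24 values occupy the 24 bins of width 1/24, shuffled per locus),
which prevents initial genotype clustering.  Each generation, the 12
lowest-ranked individuals die — except that the previous generation's top
4 carry a lifeline — and 12 offspring are produced by random pairing of
survivors, per-locus uniform crossover, and mutation (per-gene
probability 0.10, Gaussian step SD 0.05, reflected at the [0, 1]
boundaries).  Lifeline status is recomputed each generation from the
previous generation's ranks only, so protection does not chain by right.
Mutation parameters are config keys; the defaults give visible phenotype
drift within 20 generations without erasing selected structure.

## Pattern formation

Markings come from the Gray-Scott reaction-diffusion system,

    du/dt = Du lap(u) - u v^2 + F (1 - u)
    dv/dt = Dv lap(v) + u v^2 - (F + k) v

integrated by explicit Euler (dt = 1) on a periodic lattice with a
9-point Laplacian.  The genetic parameter box is F in [0.01, 0.09],
k in [0.045, 0.070], Du = 0.16, Dv = Du / ratio with ratio in [1.8, 2.2]
— a regime containing spots, stripes and labyrinths.  u starts at 1 and
v at 0 with seeded circular nucleation spots (genome-controlled count
30–180 and radius at the 128-cell reference grid).  Dense small-spot
nucleation matters at these diffusivities: isolated large seeds freeze
into a few immobile solitons covering ~2% of the domain, whereas ~100
small seeds colonize 5–15% and give usable marking texture.  Any
non-finite value raises a stability error naming the offending
parameters; u and v remain in [0, 1+1e-6] throughout the box.

The v field is min-max normalized, resampled onto the skin raster with
genetic zoom / rotation / anisotropic stretch (periodic wrap, so tiling
is seamless), and thresholded at a genetic quantile — coverage is thus a
direct gene, independent of the RD regime.  Marking interiors shade from
a secondary to the primary marking colour.  Two image filters follow:

* countershading — a linear vertical L* ramp, slope in ΔL* per
  normalized height (positive lightens the top), applied before the
  spherical wrap so the gradient is the heritable trait;
* edge enhancement — a signed difference-of-Gaussians rim along the
  marking boundary (sigma_in 1.5 px, sigma_out 3–6 px at the 256 px
  reference), lighter just inside and darker just outside, mimicking the
  shadow rims that direct light forms at object edges.

Each skin is rendered with variants (edge enhancement off;
countershading neutral) from the same RD field so the "with vs without"
difference measures isolate one filter.  Gloss is a rendering-time
property: the two gloss genes are alpha values applied at compositing.

## Synthetic scenes and lighting

A habitat is an albedo texture (multi-octave coloured noise around a
base CIELAB colour plus discrete substrate elements — pebbles, blades,
leaves) and a height map in millimetres; element heights scale with the
habitat's 3-D amplitude.  A shipped 28-row parameter table spans five
substrate classes (bare, gravel, grass, leaf litter, mixed vegetation)
with 3-D amplitudes from 0 to 12 mm; habitat identity is (parameters,
seed), and each habitat's 24-scene set re-seeds the same parameters,
emulating repeat photographs of nearby patches.

DIRECT illumination is a collimated sun (azimuth uniform per scene,
elevation 30–60 degrees): Lambertian shading from height-map normals,
plus cast shadows found by a 1-px height-field ray march.  Shadowed
pixels keep 35% of their illumination and lose 8 units of b* (shadow
light comes from the blue sky; the magnitude is a config key since no
measured value was available).  DIFFUSE illumination has no directional
term: a soft ambient-occlusion shading (pixels below their smoothed
neighbourhood darken) at 75% of the direct level.  This reproduces the
premise that direct light raises background luminance and blue-yellow
variation, which the acceptance suite checks pairwise over habitat
seeds rather than assuming.

Every scene carries the appearance model of the grey 8%-reflectance
calibration button: a hemisphere lit by the same sun (directional term
attenuated as local 3-D variation grows, since cluttered surroundings
obstruct the beam) or by the sky (a shallow gradient).  A separate
glossy-target layer holds the specular highlight: compact and bright
under direct light, broad and dim under diffuse.

## Rendering

Compositing runs in linear-light RGB with sRGB encode/decode only at the
boundaries.  The skin is wrapped onto the button by the radial fisheye
map r_src = (2/pi) asin(r_dst), rotated so that under direct light the
skin's "up" faces the lit side (so the countershading gene acts against
the self-shading gradient); under diffuse light orientation is a seeded
uniform rotation.  The lit target is `illumination x reflectance +
alpha x gloss`, where illumination is the button appearance divided by
its known 0.08 reflectance and alpha is chosen per pixel from the
marking/ground gloss genes; values clip at the display maximum with no
tone mapping.  By construction an 8%-grey zero-gloss skin reproduces the
calibration button bit-for-bit after 16-bit quantization — the
renderer's calibration identity, checked across the whole library.
Placement is uniform over the feasible region at least two target
diameters from the image border and centre.

## Measurements

All measures work in CIELAB (sRGB/D65).  "Contrast" is the SD of the
signed even-symmetric Gabor response at six scales (1/64, 1/32, 1/16,
1/4, 1/2, 1 of the target diameter) and four orientations (0 = vertical
stripes, 45, 90, 135).  Filters are evaluated in the frequency domain —
a Gabor is a Gaussian bump at its carrier — with symmetric-reflection
padding, DC removal, and unit spatial L2 norm, so white noise scores
identically at every orientation and scale-1 wavelengths stay measurable
on rasters the filter's nominal spatial support would not fit.  The
finest printed scale is sub-Nyquist at an 80 px target (1.25 px); it is
computed as the defined discrete filter rather than skipped.  A scale is
skipped (NaN, logged) only when one wavelength does not fit the raster.
Directionality is max-over-orientations divided by the orientation mean
(1 when all contrasts are zero); verticalness is contrast(0) minus
contrast(90).

Camouflage difference measures compare the target disc with its local
surround (annulus to 2.5 target radii; global statistics use 15 radii,
clipped at the image border): |mean ΔL*|, Euclidean Δ(a*, b*), and the
pattern difference — the summed absolute contrast difference across
scales in L*, orientations averaged first.  GabRat (sigma 3 px, 180
outline points) splits Gabor energy at the outline into components
parallel ("coherent") and orthogonal ("false") to the local tangent and
reports false / (false + coherent); the tangent-angle energy is
interpolated from eight filter orientations, because four orientations
leave an interpolation error visibly above the dense-angle value (worst
0.07 vs 0.016 against a brute-force oracle; the acceptance bound is
0.05).  Countershading gradients are weighted least-squares slopes of
row means on normalized height (positive = lighter top).  Gloss measures
are luminance differences between renders with gloss on, off, and at
maximum (the relative value normalizes by the target's own maximum,
since dark targets are inherently glossier).  Edge enhancement is the
contrast shift summed over the four finest scales between the
with/without variants.

In the per-trial hot path the Gabor transforms run in float32; the
measurement-grade default is float64 (the oracle tests exercise the
float64 path; the observer consumes the float32 one).

## The synthetic observer

Human players are replaced by an explicit surrogate: saliency is the
equally weighted sum of z-scored metrics (luminance, colour and pattern
difference, and 1 − GabRat, so edge disruption lowers saliency), with
the z-reference fixed by a calibration batch of 100 random genomes
rendered across the scene library.  Detection time is log-normal with
median t0 exp(−beta x saliency), t0 = 800 ms, beta = 0.5, noise SD 0.4
log-units, capped at the 15 s timeout; fitness equals the detection
time (timeouts score 15 000 ms).  The defaults put generation-0 medians
near the sub-second starting values of human play and leave improvement
detectable within 20 generations; all are config keys.  The
response-vs-capture hybrid of interactive play (with its 600 ms rule) is
deliberately collapsed into this single time.  No human effect size is
claimed or reachable: the observer guarantees only the qualitative
structure — detection accelerates with each difference metric and slows
with edge disruption — and every downstream conclusion is therefore
tested at sign level, never as an effect size.

## Experiment design and scale

The full design is 28 habitats x 3 lighting treatments (DIRECT, DIFFUSE,
and MIXED with an exact randomized 12/12 split per generation) = 84
populations, each playing generations 0–20 with 24 targets per play:
1,764 plays and 42,336 presentations.  Populations advance in lock step
and all randomness descends from one master seed through per-population
streams, so records are byte-identical across reruns.

The property runs use a desk-scale configuration — 3 habitats (one per
substrate extreme), 288 x 352 px scenes, 40 px targets, 64 px skins, a
64-cell RD grid with at most 800 steps — with the evolutionary design
itself unchanged.  These sizes are the package's default trade-off
between statistical resolution and the cost of ~23,000 render+measure
cycles per five-seed run.

## Countershading reporting frame

Targets are aligned with the illumination axis under direct light, and
final-generation skins are evaluated by rendering them onto their
habitat's azimuth-aligned, scene-averaged direct raw target.  Gradients
of that render are reported with the illumination axis pointing down the
measured image: the bare grey target then scores negative (its lit side
is at the bottom of the frame), and a positive shift means the skin
lightens the shadow side, i.e. countershades.  In reduced runs
direct-evolved skins cancel roughly half of the ~40 L* self-shading
gradient while diffuse-evolved skins barely move, reproducing the
direct > mixed > diffuse ordering of countershading strength.

## What passing tests do and do not show

The scene generator emulates the statistics that drive the hypotheses —
luminance/chromatic variation, cast-shadow structure, 3-D relief, the
lighting-dependent button appearance — not any real habitat: there is no
global illumination, no perspective, no within-scene lighting mixture,
and targets always sit in direct light under the DIRECT treatment.  The
observer is a weighted-metric process, not a human.  Passing the
property suite therefore shows that the pipeline's machinery (pattern
genetics, calibrated rendering, measurements, selection) produces the
paper-predicted sign structure under its own stated premises; it says
nothing quantitative about human search or real habitats.

## Numerical choices and degenerate inputs

Marking threshold quantiles 0 and 1 give all-marking and all-ground
skins exactly.  Zero-variance metrics are disabled (weight 0) at
observer calibration.  Constant feature columns are dropped before
standardization; PCA truncates rank-deficient input and fixes signs so
each component's largest-|loading| feature is positive.  Selection ties
break by the population's seeded RNG.  Gloss relative values guard the
zero-maximum case.  Trend groups need at least 3 points and a
non-constant predictor, otherwise they are skipped and logged.
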