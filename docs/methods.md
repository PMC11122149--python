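# Methods

## The circle estimator

Local conduction velocity and voltage amplitude are defined per spherical
filter ("circle") of radius 5 mm placed on the mapped chamber surface:

- **CV** = theoretical diameter (10 mm) divided by the first-to-last local
  activation interval among the circle's measurement points, in mm/ms ≡ m/s.
  The *theoretical* diameter is used even where the covered surface patch is
  slightly smaller than a flat disc, so the estimator is a fixed, simple
  functional of the LAT field.
- **VA** = arithmetic mean of the unipolar amplitudes of the circle's
  points, in mV.

Properties worth keeping in mind when interpreting outputs:

- For a planar wavefront at speed *v* crossing a flat, fully sampled circle
  the estimate equals *v* exactly.
- For a focal (radial) wavefront the activation interval across a circle is
  at most diameter/*v*, so the estimator is upward-biased; the bias is
  largest for circles containing the source (up to a factor ~2 right at a
  focus) and negligible far from it. Because every map in a study is
  estimated with the same geometry of bias, ratios between conditions and
  rate coefficients are essentially unaffected.
- Finite sampling can only shorten the observed interval (the extreme points
  of a circle are rarely sampled exactly), adding a small positive bias that
  shrinks with point density; at 1.3 points/mm² it is a few percent.

Circle membership uses the 3-D Euclidean ball, matching a spherical filter
applied to the embedded surface, not geodesic distance. On strongly folded
surfaces a ball can capture points of an opposing wall; this is a known
limitation of the approach and of this implementation.

Velocities strictly above 6 m/s are physiologically implausible for working
myocardium and are flagged as outliers; exactly 6.0 m/s is kept. Circles
whose points activate simultaneously (zero interval) are excluded as
`zero_dt` rather than assigned an infinite velocity, and circles with fewer
than 10 points are dropped outright — a first-to-last interval over a
handful of points is not a velocity measurement. Excluded rows stay in the
metrics table with their reason for audit.

## Surface covering

Circle centers come from greedy farthest-point sampling over the non-cutout
vertices: starting from a seeded random vertex, the vertex farthest from all
accepted centers is accepted next. Sampling runs past the nominal 7-mm
spacing until every vertex lies within 0.9 × radius (4.5 mm) of a center.
The continuation is what guarantees full coverage — stopping at the 7-mm
spacing alone would leave every vertex between 5 and 7 mm of its nearest
center outside all circles (about a fifth of a flat surface in practice).
The 0.9 factor sets the overlap of the covering; at the default it yields
roughly 130 circles of ~74 mm² per synthetic chamber, about a hundred
points per circle, and a points-per-area resolution of ~1.3/mm², the regime
of published ultra-high-density porcine chamber maps. Covered area is the
summed area of triangles whose centroid falls inside the ball (triangles
touching a cutout vertex excluded); this converges to the true patch area
with mesh density and is reporting-only — CV always uses the theoretical
diameter. Membership is boundary-inclusive (distance ≤ r). A circle's wall
label is the majority label of its members, ties broken in a fixed
anatomical label order.

## Mixed-effects models

Per-circle values from all maps of a study enter

    log CV ~ heart_rate + group,  random intercept per animal
    VA     ~ heart_rate + group,  random intercept per animal

fitted by REML (statsmodels MixedLM), where `group` is chamber × rhythm /
pacing-site (or chamber-wall × rhythm at the wall level) in cell-means
coding, and heart rate carries no interaction with group — the model assumes
one common rate effect across chambers. CV is modelled on the natural-log
scale; the base of the logarithm only rescales the coefficient, and the
back-transformed per-bpm multiplier exp(β_HR) is base-free.

Reported quantities:

- **Rate effects**: exp(β_HR) as a per-bpm CV multiplier (delta-method SE),
  β_HR directly as the VA slope in mV/bpm.
- **Estimated marginal means**: per-group predictions at a stated reference
  heart rate (90 or 145 bpm), at the population level (random intercept at
  its mean, zero); CV means and intervals are formed on the log scale and
  back-transformed. Requests more than 20% outside the observed heart-rate
  range warn about extrapolation.
- **Contrasts vs sinus rhythm**: within each chamber (or wall) family, each
  paced group minus the NSR group; on the CV side back-transformed to a
  ratio. p-values use t statistics on residual degrees of freedom — with
  thousands of circles per fit, small-sample df corrections are
  indistinguishable — adjusted by Sidak for the targeted paced-vs-NSR family
  or by Tukey's HSD (studentized range with the family's group count) when
  an all-pairwise family is requested.

With only four animals the random-intercept variance can estimate on the
boundary at zero. statsmodels' fixed-effect solution is numerically
unreliable exactly there (singular random-effects covariance), so the model
detects the boundary and refits the fixed effects by ordinary least squares
— which is what the mixed model *is* when the variance component is zero —
and warns. Groups with fewer than two observations, single-animal tables and
missing NSR references are rejected with explicit errors.

## Paired map differences

Circles of a paced map are matched to the same-animal, same-chamber
intrinsic map by mutual nearest centers within 2.5 mm (half the circle
radius). On synthetic studies centers coincide exactly because the covering
is seeded per (animal, chamber); the tolerance exists for real, separately
reconstructed maps. Pairs in which either member is excluded are dropped.
Four statistics summarise each map pair:

1. mean of |pace − intrinsic|;
2. that mean divided by the mean intrinsic value (absolute difference
   ratio) — an algebraic identity with (1), kept as a separate output
   because it is the scale-free quantity;
3. per-circle relative change, (pace − intrinsic) / mean(intrinsic) × 100%,
   for distribution plots;
4. the IQR over circles of (pace − intrinsic) / intrinsic — note each
   difference here is normalised by *its own* intrinsic value, unlike (3).

IQRs use linear-interpolation quantiles (numpy's default, type 7); with
>100 pairs the convention moves the IQR by well under 2% and it is
overridable.

## Synthetic study generator

The generator emulates a four-animal, 44-map high-density mapping protocol:
every chamber mapped under sinus rhythm and under pacing from a subset of
chambers, at mean heart rates between 86 and 171 bpm, with epi/endo pacing
access recorded as metadata. Animals are assigned round-robin within each
(chamber, pacing) cell — this keeps pacing conditions balanced over animals
and guarantees each paced map has a same-animal intrinsic partner for the
paired analysis. The per-bpm rate effects, pacing multipliers/offsets and
noise scales default to the fitted values of the in-vivo porcine study this
protocol mirrors; chamber-level CV intercepts (0.75–1.05 m/s at 145 bpm)
and VA intercepts (3–14 mV) are set to values consistent with healthy
porcine myocardium and that study's reported local-difference statistics.

**Geometry.** Chambers are ellipsoids (semi-axes 16–22 mm, per-animal size
factor 0.93–1.07) sampled uniformly by area at 1.3 points/mm² — about 5.5k
points per map, the scale of real ultra-high-density maps — and
triangulated by convex hull. Wall labels are azimuthal quadrants (anterior /
lateral / posterior / septal) plus a superior cap on the atria; cutouts are
contiguous patches grown from random seeds to 8% of vertices by default.
The same (animal, chamber) reuses one mesh across all its maps, as the same
anatomical chamber would.

**Activation.** The wavefront is simulated as graph shortest paths from a
focal source (chamber-specific "sinus" site for NSR, pacing-site entry
point otherwise) with edge traversal time = length / mean endpoint speed.
The graph uses 1-ring plus 2-ring mesh neighbours: shortest paths restricted
to triangle edges overestimate surface distance by up to 2/√3 − 1 ≈ 15% in
the worst direction, while the 2-ring graph keeps the metric dilation below
~4% (verified against great-circle distances on sphere meshes). A planar
source mode (activation = projection / speed) provides analytically exact
fixtures.

**Fields.** The per-vertex speed field is
chamber intercept × 1.004^(HR − 145) × pacing multiplier ×
exp(animal effect) × exp(noise); amplitude is
chamber intercept − 0.012 (HR − 145) + pacing offset + animal effect +
noise + jitter, truncated at 0 mV. The rate law is parameterised around the
145-bpm reference so intercepts are interpretable at the study's
normalisation heart rate; the per-bpm base is unchanged by the shift.
Animal effects (sd 0.1 on log-CV, 0.5 mV on VA) are drawn once per animal
and shared across its maps. Spatial noise is a smooth Gaussian-bump random
field with 3.5-mm correlation length — sub-circle scale, so per-circle
values decorrelate quickly — normalised to exactly zero mean and the stated
sd (0.3 log-CV, 1.5 mV VA) over the *non-cutout* vertices of each map.
Pinning the per-map mean to zero is deliberate: it confines the noise to
within-map spatial variation, so between-map variation carries only the
modelled effects and the mixed model's independence assumptions hold at the
map level. VA additionally gets 0.3 mV iid per-point jitter.

**What the generator does not emulate**, and what passing tests therefore do
not show about real data: fibre-orientation anisotropy (conduction is
locally isotropic), realistic chamber anatomy (no trabeculae, appendages,
valve planes or strongly folded walls, so the Euclidean-ball limitation is
never stressed), colliding wavefronts and lines of block, far-field and
annotation noise in LATs (activation times are exact up to the graph
metric), beat-to-beat variability, and any epi-vs-endo pacing difference
(access is metadata only). Parameter-recovery results show the analysis is
consistent with its own assumptions at realistic sizes — not that those
assumptions hold in vivo.

## Determinism and problem sizes

All stochastic stages derive their generators from one master seed through
named SeedSequence keys (per animal, per map, per covering); identical
configuration and seed reproduce byte-identical map files and table hashes,
which the run manifest records. The default study used by the test suite
and the acceptance script is the full 44-map protocol (~5.5k points/map,
~130 circles/map, >4500 modelling circles) and runs in well under a minute;
unit tests use a reduced 16-map study on smaller chambers and flat patches.
Flat-patch fixtures are tested on interior circles at elevated density
(10–30 points/mm², small positional jitter): rectangular patches have
borders that truncate circles and aligned grids quantise the activation
interval, two artifacts closed chamber surfaces do not exhibit.
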