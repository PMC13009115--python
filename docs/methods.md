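# Methods

This note documents the models, estimators and design choices behind
`ewimap`, and what the synthetic phantom does and does not emulate.

## Activation model

The electrical wavefront is modelled as isotropic geodesic propagation on
the 8-connected pixel graph of the myocardial mask. The edge between
neighbouring pixels a, b costs `|ab| · (1/v_a + 1/v_b) / 2` milliseconds,
where v is the local conduction velocity (default 0.5 mm/ms, a typical
working-myocardium value); scar polygons multiply v by a factor in (0, 1].
Activation time is origin time plus the shortest-path distance (Dijkstra via
`scipy.sparse.csgraph`); pixels in components unreachable from the source
are flagged and carry NaN. This is the simplest model honouring
earliest-activation semantics; it has no fibre anisotropy, no restitution,
and no transmural conduction heterogeneity. 8-connected geodesics
overestimate Euclidean path lengths by up to ~8%, which is irrelevant here
because every comparison uses the same graph metric.

The focal source is a single pixel chosen inside the requested segment at
the target transmural depth of its layer (1/6, 1/2, 5/6 for endo/mid/epi).
Transmural layers are wall-depth terciles ([0,⅓), [⅓,⅔), [⅔,1]) throughout
the package; no quantitative layer boundary is standard, and terciles make
the three layers equally wide.

## Strain synthesis and the zero-crossing rule

Noiseless traces follow a smooth template
`ε(t) = A·tanh((t_m − t)/w) + A·(1 + tanh((t − t_m − T_sys)/w_rec))` with
amplitude A = 5·10⁻⁴ (a realistic incremental interframe strain at
2000 fps), transition width w = 4 ms, systolic duration T_sys = 150 ms and
recovery width 30 ms. The first factor crosses zero exactly at the
mechanical activation time `t_m = AT + EMD`, so a detector sampling at the
frame rate is accurate to half a frame period (0.25 ms at 2000 fps) by
construction. Additive white Gaussian noise (default SD 5·10⁻⁵, i.e. 10% of
amplitude) and an optional linear baseline drift are applied afterwards.

Clinical ZC annotation is semi-automated with manual review; a testable
artifact needs a deterministic rule. The detector smooths with a
moving average (default 5 ms), scans the analysis window (default
[reference, reference + 350 ms]) for downward sign changes, and accepts the
first crossing after which the smoothed trace stays strictly negative for at
least `min_negative` (default 20 ms). Times interpolate linearly between
the bracketing frames. Traces without a qualifying crossing return quality
`no_crossing` (never a silent zero); more than one qualifying crossing is
`ambiguous` (the first is still reported). A manual-override table (pixel →
forced time) stands in for reviewer edits. The detector is verified against
an independent brute-force scan implementing the rule literally.

## RF path

Post-beamformed RF lines are random scatterer trains convolved with a
Gaussian-modulated 2.5 MHz pulse, sampled at 20 MHz with c = 1540 m/s
(axial sample spacing c/2fₛ = 0.0385 mm). Frame-to-frame motion integrates
a prescribed incremental strain schedule over depth, so the estimators can
be validated against ground truth. Displacement estimation is 1-D windowed
normalized cross-correlation (defaults: 64-sample window ≈ 2 wavelengths,
80% overlap, ±8 sample search) with parabolic sub-sample refinement;
perfect-correlation peaks are kept at their integer lag, flat windows are
flagged invalid. Incremental strain is the least-squares slope of
displacement vs depth over a sliding 5 mm kernel. Only incremental
(frame-to-frame) strain is computed, because the ZC definition operates on
incremental strain. Phase-based estimators were not used: the
cross-correlation approach is the standard RF-domain choice and its
sub-sample bias (< 0.05 samples on noiseless band-limited lines) is
verified by test. The lateral-resolution figures quoted for such systems
are treated as metadata only; no lateral tracking is implemented.

## Isochrones and site-of-origin localization

Scattered activation times (150–300 reviewed points at paper scale) are
interpolated with Clough–Tocher cubic interpolation on their Delaunay
triangulation — exact at the samples and exact for linear fields — and
evaluated at every mask pixel; pixels outside the convex hull take the
nearest sample's value and are flagged extrapolated. Views are
co-registered by expressing all times relative to a common surface-ECG
reference (pacing spike when present, else QRS onset).

The earliest region is all pixels within 5 ms of the global minimum across
views. The SoO segment contains the region's earliness-weighted centroid
(weights `threshold − AT`), which is more robust to single-pixel noise than
the raw argmin; the layer is the wall-depth tercile at that location. The
call is *diffuse* when the region spans > 2 segments or > 25% of a view's
mask and the region boundary does not rise at least half the 5 ms margin
above the minimum (a focal source has a boundary ~5 ms late; a flat plateau
reaches its boundary near the minimum). Diffuse calls report layer
`diffuse` and score as transmurally incorrect. These thresholds are
package-defined operationalizations of a qualitative clinical judgement.

## ECGI side

UEGMs are synthesized at 1000 Hz as a tanh intrinsic deflection centred on
the node's electrical activation time plus a slow repolarization wave; rS
morphology adds a small r wave (default 20% of the downstroke) 15 ms before
the deflection, with slopes kept well below the downstroke slew so LAT is
unaffected. Signals are low-pass filtered (zero-phase 4th-order Butterworth
at 100 Hz) and then rescaled so the measured slew rate equals the configured
value exactly (slew scales linearly with amplitude; the default 0.32 mV/ms
echoes typical endocardial values). LAT is the earliest sample of the
minimum central-difference dV/dt; the discretization of the derivative is a
package choice, as is measuring slew on the averaged beat. Morphology is rS
when the pre-deflection positive excursion exceeds 10% of the dominant
negative amplitude (baseline = leading 10 ms), QS when there is a dominant
negative deflection without such an r wave, `other` otherwise. Beat
averaging aligns windows to a template at the maximum-correlation lag and
accepts beats with Pearson r ≥ 0.93. Nodes are sampled on the epicardial
band (wall depth ≥ ⅔) of non-septal segments only; requesting septal nodes
is an error, mirroring ECGI's absent septal representation. No inverse
problem is solved: ECGI maps are simulated at the electrogram level, so the
phantom cannot exhibit inverse-solution artifacts (spatial smoothing,
breakthrough mislocalization).

## Electromechanical delay model and cohorts

Per subject, the EMD is one Gaussian draw (subgroup-specific mean/SD) plus
deterministic transmural-layer and basal/mid/apical offsets, applied per
pixel. Subgroup defaults are 50 ± 29 ms (scar-positive), 39 ± 25 ms
(impaired LV function without scar) and 33 ± 21 ms (structurally normal),
45 ± 28 ms pooled; the default cohort is 33 subjects split 20/4/9. Both
offset sets default to zero: the reported level-wise delay patterns are not
consistent with a single deterministic offset vector across subgroups, so
offsets are exposed parameters rather than fitted defaults. Because the
within-subject delay is a single draw, the pooled segment-level SD is
dominated by the between-subject SD; this matches the reporting granularity
of global mean ± SD over pooled segments (segment-level deltas are pooled
across subjects before averaging — the alternative, per-subject means first,
is a documented choice point).

Cohort subjects are realized on an idealized full-ring biventricular
annulus (endo/epi radii 25/35 mm, 1 mm grid) whose 24 angular sectors are
the 24 segments, so a single plane carries the whole model with consistent
ground truth. The EWI chain synthesizes strain traces at ~10 sampled
epicardial points per segment (not dense movies) and runs real ZC detection;
the ECGI chain synthesizes ~3 UEGMs per covered segment and runs real LAT
detection. This keeps a 33-subject cohort near 3 s while every measurement
operator actually executes; dense per-pixel movies remain available for
single-subject studies. Generation is bit-for-bit reproducible from the
cohort seed via spawned child seeds.

What the phantom does not emulate: 3-D geometry and interplanar gaps,
reverberation/clutter and speckle decorrelation, respiratory and cardiac
motion other than the prescribed schedule, inverse-reconstruction artifacts,
multifocal rhythms, and rate-dependent EMD. Passing tests therefore
demonstrate correctness of the measurement chain under the stated model, not
clinical performance.

## Statistics

Slew rates are compared across truth layers with one-way ANOVA (layers with
< 2 records excluded with a warning) and morphology with a chi-square
contingency test. Segment-level delays are summarized per anatomical row
(global, basal/mid/apical, RV/LV) × subgroup; subgroup differences use
one-way ANOVA with pairwise t-tests Bonferroni-corrected over the three
subgroup pairs (the correction method is a package choice). Normality is
not tested; ANOVA is applied unconditionally, consistent with standard
practice at these group sizes. Localization accuracy uses exact
(Clopper–Pearson) binomial 95% CIs; per-modality accuracies are over maps
with a call from that modality, while both-correct / both-failed
proportions are over all maps.

## Numerical choices and problem sizes

Times are ms relative to the ECG reference (negative values allowed for
pre-QRS activity), lengths mm, strain dimensionless. Grids are 0-based and
row-major. LAT ties break to the earliest sample within a 10⁻¹² relative
tolerance; a perfect correlation peak suppresses parabolic refinement;
interpolation exactness is asserted to 10⁻⁸ and linear reproduction to
10⁻⁶ of the field range (Clough–Tocher gradient estimation is iterative, so
permutation invariance holds only to numerical tolerance). Test problem
sizes (1–2 k-pixel masks, 33-subject cohorts, 3 replicate cohorts in the
test suite and 20 in the acceptance script, 10⁴ traces for the detector
equivalence check) were chosen so the full suite runs in well under a minute
per heavy check while keeping Monte-Carlo standard errors a small fraction
of the tolerances they are tested against.
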