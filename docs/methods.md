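# Methods

## The worm-like-chain model and its discretization

A membrane ruffle's top-view backbone is treated as a 2D worm-like
(Kratky–Porod) chain.  In the convention used here the tangent correlation
decays as ⟨t(0)·t(s)⟩ = exp(−s/(2 lₚ)), which integrates to the mean squared
end-to-end distance

    <Ree^2>(L) = 8 lp^2 [ L/(2 lp) - 1 + exp(-L/(2 lp)) ]
               = 4 lp L - 8 lp^2 (1 - exp(-L/(2 lp))).

Its limits are the rigid rod (⟨R²ₑₑ⟩ → L² for L ≪ lₚ) and the random coil
(⟨R²ₑₑ⟩ → 4 lₚ L − 8 l²ₚ for L ≫ lₚ); both are asserted in the test suite.

The sampler discretizes the chain into segments of fixed length Δs
(default 0.05 µm) joined by Gaussian turning angles of variance Δs/lₚ.
Summing independent increments gives ⟨cos θ(s)⟩ = exp(−s/(2 lₚ)) exactly,
so the discrete ensemble reproduces the closed form above without further
calibration; the ensemble-versus-theory agreement is tested at Monte-Carlo
precision.  Δs must satisfy Δs ≤ lₚ/5 (enforced), keeping the wrapped-
Gaussian/Gaussian distinction negligible; 0.05 µm is ≥16× below the softest
persistence length of interest (0.8 µm).

### Intrinsic curvature as quenched disorder

Strongly curved ruffles can look floppy without being soft: a preferred,
non-straight shape also decorrelates the tangent.  This is modelled as
*quenched* per-step preferred angles, drawn once per chain from a Gaussian
of variance Δs/lₚ,int and added to the thermal turning angles.  Because the
variances add, the observed persistence length obeys the reciprocal sum

    1/lp_obs = 1/lp + 1/lp_int,

and `decompose_intrinsic` inverts it exactly.  A constant-arc (fixed
curvature) picture would *not* produce a worm-like ⟨R²ₑₑ⟩(L) with additive
reciprocals, which is why the disorder model was chosen; with 0.8 µm
observed and 5 µm bending stiffness it yields lₚ,int = 1/(1/0.8 − 1/5)
= 0.95 µm.  The disorder is redrawn for every chain (fresh realization of a
heterogeneous population), and the identity is verified end to end:
simulate with known (lₚ, lₚ,int), fit, decompose, recover lₚ,int.

### Fitting

`fit_persistence_length` minimizes Σᵢ (R²ₑₑ,ᵢ − ⟨R²ₑₑ⟩(Lᵢ; lₚ))² over pooled
per-ruffle points — unweighted least squares, the simplest reading of a
scatter-plus-curve analysis.  The objective is nearly flat in lₚ for stiff
data, so the optimizer (Levenberg–Marquardt in log lₚ) is restarted from
{0.1, 0.5, 1, 2, 5, 10, 50} µm and the best residual kept.  Rows violating
Rₑₑ ≤ L (possible under measurement noise) are rejected and counted, not
clipped.  Uncertainty is a percentile bootstrap resampled over ruffles
(default 1000 resamples, 95% level); resampled refits start from the
full-data estimate.  Simulation studies in the test suite show ≤5% median
bias at n = 300 chains and ≥90% empirical coverage of the nominal 95%
interval at n = 150 chains, L ∈ [2, 20] µm.  Note that the unweighted
objective is heteroscedastic (Var R²ₑₑ grows with L), which is the main
driver of the ~6% sampling SD of the estimate at n = 300.

## Synthetic volumes

`volume_synth` renders each ruffle as a slab of constant lateral thickness
centred on its backbone, extruded vertically from a flat dorsal surface at
`base_z` to a per-ruffle height; voxel values are approximate occupied
fractions (linear partial-volume weighting per face, flat end caps), making
the rendered mass L × thickness × height exact to a few percent.  Defaults
follow the measured phenotype: 0.83 µm thickness, heights ~N(2.0, 0.5) µm,
0.1 µm isotropic voxels, non-overlapping placement by rejection sampling.
A uniform cytosol slab fills the volume below the dorsal surface so a
cytosol control ROI always exists; in the second channel the ruffle density
is multiplied by an enrichment factor (default 3) while cytosol stays at
unit density.

Degradation models the *residual* point-spread of deconvolved light-sheet
data as an anisotropic Gaussian (σ = 0.1 µm lateral, 0.25 µm axial by
default) followed by Poisson counts at `photon_scale` × density (default
500) plus a constant camera offset (100).  Time series repeat the static
geometry with independent noise per frame at 8 s intervals.

What the generator deliberately does **not** emulate: curvature of the real
dorsal surface, ruffle growth/merging/closure dynamics, photobleaching,
read noise, deconvolution artifacts, and 3D (out-of-plane) backbone paths.
Passing recovery tests therefore validate the measurement chain's geometry
and statistics, not its robustness to those real-data complications.

## Morphometry

Segmentation is Gaussian smoothing (σ = 1 px) + Otsu threshold + 8-connected
labelling with a minimum area (0.25 µm²); parameter-light and deterministic.
For synthetic scenes the projection is taken over the sub-volume above the
dorsal surface, since the cytosol slab below it would otherwise dominate
the projection.

Skeleton metrics build an 8-connected pixel graph of the topological
skeleton, prune terminal spurs shorter than 0.3 µm (rasterization whiskers),
and take the contour to be the longest endpoint-to-endpoint path (Dijkstra
with the conventional 1/√2 step weights); branch count is the arc count of
the condensed graph with adjacent junction pixels merged.  Two digitization
corrections are applied to the *reported* length: (i) the pixel path is
low-passed by endpoint-preserving Chaikin corner-cutting before summing
segment lengths, removing the up-to-8% overestimate of the raw 1/√2 metric
on oblique or curved paths; (ii) each end is extended along its local
tangent to the mask boundary minus half a pixel, undoing end erosion by
thinning (about half the local width).  With both corrections a 10 µm
straight bar measures 9.93 µm, a quarter-circle arc is within 3.3% of its
analytic length, and 0° vs 37° orientations of the same bar agree within
0.5%.  If a skeleton closes into a loop (thinning occasionally does this on
wiggly bands), the most distant pixel pair found by a double Dijkstra sweep
substitutes for the endpoint pair.

Thickness is the full width at half maximum of a cross-section profile
sampled at quarter-pixel spacing with bilinear interpolation; the baseline
is the median of the outer 15% of samples, crossings are located by linear
interpolation, and the result is corrected in quadrature,
t = √(FWHM² − (2.355 σ_PSF)²), clipped at zero.  For a 0.83 µm slab blurred
at σ = 0.1 µm the quadrature rule overcorrects slightly (the exact
box⊗Gaussian FWHM is narrower than the quadrature sum), giving a known ~5%
downward bias — well inside the 10% acceptance band and verified against a
brute-force numerical convolution oracle.

Heights are read per vertical column along the skeleton: the topmost
threshold crossing is located to sub-voxel precision by linear interpolation
between bracketing voxel centres ((i + 0.5)·voxel convention), minus
`base_z`.  The threshold defaults to Otsu of the volume, which lands near
half-amplitude where the blurred-edge crossing coincides with the true edge.
At photon scale 500 and 0.1 µm voxels the height SD along a constant-height
sheet is ~5–10 nm, far below the 110 nm scale of interest; columns that
never reach threshold record height 0 with a flag.  The dorsal base height
is an explicit parameter (known exactly for synthetic scenes); automatic
base detection is out of scope.

## Enrichment and correlation

The enrichment ratio is (mean ruffle ROI − offset)/(mean cytosol ROI −
offset) with equal pixel counts and disjoint ROIs.  In the automated
pipeline the ruffle ROI is the segmented footprint eroded by 2 px: the
un-eroded footprint includes partial-volume fringe pixels that dilute the
ratio by ~15%, whereas the eroded core matches how a manual ROI is drawn on
signal.  The cytosol control is an equal-count random pixel set outside the
dilated ruffle union, on the full-depth channel-2 projection.

Cross-correlation is the Pearson coefficient of mean-subtracted overlapping
segments at each integer frame lag in [−max_lag, +max_lag], averaged across
ruffles (each ruffle normalized before averaging); lags are reported in
seconds via the frame interval (8 s default).  The peak lag breaks ties
toward zero.  Constant traces are excluded with a warning.  The synthetic
trace generator produces logistic rise-to-plateau curves with randomized
onset and time constant, channel 2 delayed by an integer frame count plus
Gaussian noise — sufficient to verify lag localization and the null
(white-noise) behaviour, but not bleaching or non-stationary baselines.

## Benchmark sizes and determinism

The bundled benchmark and acceptance computations use 300-chain ensembles,
single scenes of ≤160² × 50 voxels with ≤5 ruffles, and 35 traces of 30
frames — sizes at which every stage's recovery statistics are already
stable (the fit's sampling SD is ~6%, thickness/height estimates average
over ≥50 stations) while the whole pipeline runs in seconds.  All
randomness flows from explicit integer seeds: chains use master + index
per-chain seeds (note: master seeds closer than the ensemble size share
chains — replicate studies use well-separated masters), scenes draw child
seeds from a seeded generator, and identical configuration + seed yields
byte-identical reports.

## Known limitations

* Contour measurement is 2D (top-view projection); truly overhanging or
  folded ruffles would be foreshortened.
* Overlapping ruffles are not separated; synthetic scenes enforce
  non-overlap and real coalescing ruffles would need manual curation.
* The quadrature PSF correction assumes a Gaussian PSF and a slab-like
  cross-section; other profiles bias the corrected thickness.
* The enrichment ratio compares projected intensities and ignores
  differences in axial extent between ruffle and cytosol columns beyond
  what the equal-ROI convention absorbs (maximum projection adds a small
  extreme-value bias, ≈2% at the default photon scale).
* The intrinsic-curvature decomposition requires lₚ,obs < lₚ; near-equal
  values make lₚ,int numerically unstable (it diverges in the limit).
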