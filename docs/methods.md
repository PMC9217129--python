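# Methods

`cotrack` quantifies the oligomeric state of membrane proteins diffusing in
live cells from dual-channel single-molecule movies. This note documents
the models implemented, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was open.

## The measurement principle

A protein tagged with a self-labeling enzyme is exposed simultaneously to
two spectrally distinct dye ligands, so each protomer of an oligomer
independently ends up carrying a "reference" dye (probability `p1`), a
"partner" dye (`p2`), or nothing detectable (`pu = 1 − p1 − p2`; this
catch-all covers unlabeled, pre-bleached, and undetected protomers).
Protomers bound in one complex diffuse together; their trajectories in the
two color channels are therefore near-identical, while unbound molecules
wander independently. Counting the fraction of reference-channel
trajectories that have a co-diffusing partner-channel trajectory reads out
the average oligomer size without any intensity calibration.

## Sliding-window trajectory correlation

For every spatially adjacent pair of reference/partner tracks, a window of
`N` consecutive frames slides along their common time span in steps of one
frame. Within each window in which *both* tracks have a position in every
frame, Pearson correlation coefficients are computed separately for the x-
and y-coordinate sequences. A reference track is classified a
**co-localizer** when at least one window of at least one adjacent partner
track has PCC > `T` on both axes. Each reference track counts at most
once. The per-cell statistic is

    % correlated trajectories = 100 · n_ref_corr / n_ref_total

with `n_ref_total` the number of reference-channel tracks spanning at
least `N` frames.

Windowing makes the comparison robust to unequal track durations and to
trajectories that cross: only stretches where both particles were
continuously followed are compared. Adjacency (at least one point of one
track inside the other track's bounding rectangle, symmetrized, inclusive,
optional padding) both prunes the pair search and removes false positives
from similar-shaped tracks in distant parts of the cell; we treat the
"partial spatial overlap" requirement and adjacency as a single test.

Parameter roles and defaults:

* `N` (window length, frames; default 12, 14 supported): shorter windows
  raise sensitivity to brief encounters but also the chance correlation of
  independent random walks (two independent 12-point random walks exceed
  PCC 0.8 on one axis ~5% of the time; requiring both axes squares that).
* `T` (PCC threshold; default 0.8): the operating point of the classifier.
  It is an empirical instrument-dependent setting; `calibrate_threshold`
  reproduces the tuning procedure by maximizing dimer-minus-monomer
  separation on simulated (or measured) control cells and returns the
  smallest `T` on the plateau of maximal separation, which minimizes
  attenuation of true co-localizers. Different window lengths pair
  naturally with different `T` (e.g. N=14 with T=0.85 gives a several-fold
  lower false-positive floor than N=12/T=0.8 at equal dimer capture in our
  simulations).
* Windows with zero variance on an axis (immobile spot) have undefined PCC
  and never classify a pair: a stationary spot carries no co-diffusion
  evidence.
* Strict inequality (PCC > T) is used.

The false-positive floor is density dependent: each reference track is
tested against every adjacent partner track, so the per-cell floor grows
roughly linearly with the number of adjacent candidates. At ~0.04
eligible tracks/µm² per channel the floor is ~1.5–2.5% (N=12, T=0.8); at
~0.01/µm² it falls below 0.2%. Reported control percentages should always
be compared at matched density, which is how the package's own control
simulations are configured.

## From co-localizer fractions to mean stoichiometry

For a cluster of `n` protomers, inclusion–exclusion gives the probability
of carrying at least one dye of each color,

    P_both(n) = 1 − (1−p1)^n − (1−p2)^n + (1−p1−p2)^n ,

and, because clusters with no dye are invisible, the observable is the
fraction of visible clusters carrying both colors,

    F_obs(n) = P_both(n) / (1 − (1−p1−p2)^n).

In the symmetric case `p1 = p2 = P_L`, a constitutive homodimer control
(`n = 2`) gives `F_obs = P_L / (2(1−P_L))`, inverted as
`P_L = 2·F_obs/(2·F_obs + 1)` to calibrate the labeling probability
(typically ≈ 0.14 per color under saturating labeling). A measured
`F_obs` then maps to an effective mean cluster size by solving
`F_obs(n̂) = F_obs` with Brent's method on n ∈ [1, 64] (tolerance 1e-6).
`n` is continuous: the observable averages over a mixture, so fractional
values (e.g. n̂ ≈ 1.8) are mean-field effective sizes, not physical
subunit counts. The closed forms are evaluated in extended precision
because the alternating sum cancels catastrophically for small
probabilities; this keeps the calibration round-trip exact to 1e-12 over
the whole valid range.

**Denominator caveat.** The plotted percentage uses reference-channel
tracks as denominator, while `F_obs` is defined over *all visible*
clusters. The two differ: for ideal dimers at `P_L = 0.14` the
reference-denominator percentage is `100·2p/(2−p) ≈ 15.1%` whereas
`F_obs ≈ 8.1%`. `CellColocResult` therefore exposes both: the plotted
`percent_correlated` and an `f_obs` estimator
`n_corr / (n_ref + n_partner − n_corr)` over the union of visible tracks,
which is the quantity the stoichiometry inversion consumes. The assay's
sensitivity `dF_obs/dn` is highest in the monomer-to-tetramer range and
decays beyond ~10 protomers (`sensitivity_curve`).

## Spot detection and linking

Detection: a scale-normalized Laplacian-of-Gaussian filter at scale
σ = spot_radius/(√2·pixel_size); local maxima of the sign-flipped response
above `quality_threshold` are kept and refined to sub-pixel precision by a
1-D quadratic fit per axis (offsets clamped to ±0.5 px). Quality is the
raw LoG response, so thresholds are not numerically transferable from
software that normalizes quality differently.

Linking: frame-to-frame correspondence is a rectangular linear assignment
problem with squared-displacement costs, birth/death alternatives priced
at `max_link_distance²`, solved exactly (`scipy` Jonker–Volgenant); a
second assignment joins segment ends to later segment starts within
`max_gap_frames` missing frames and `max_gap_distance` (gap closing).
Splitting/merging events are out of scope. Spots are canonically sorted
before linking, making the result invariant to input row order; ties are
measure-zero for continuous positions.

Defaults are physically motivated rather than fitted: spot radius 0.25 µm
(diffraction limit), link radius 0.6 µm ≈ 4σ of the per-frame Brownian
step at D = 0.18 µm²/s and 60 ms frames. We use 4σ rather than 3σ
because at 3σ roughly 0.3% of genuine steps per frame are refused, which
fragments several percent of 50–100-frame tracks; at 4σ refusals are
negligible while spurious links remain rare at the operating densities
(≤ 0.05 spots/µm²). At that density bound the linker recovers ≥ 90% of
simulated particles as single tracks with < 1% identity switches.

## Diffusion by MSD

Each trajectory is cut into consecutive non-overlapping 5-frame segments
(within gapless stretches only; the non-overlapping choice avoids the
strong lag-to-lag correlations of time-averaged MSD). Squared
displacements from each segment's first point at lags 1–4 are averaged
across segments, and the curve is fitted to the 2-D Brownian law
⟨r²⟩ = 4Dt by least squares through the origin (D = Σtᵢmᵢ/(4Σtᵢ²),
negative fits clipped to 0). Tracks with fewer than 15 points are
excluded — too few segments for a stable average — and the exclusion is
signaled, not silent. The through-origin form follows the law as stated;
its known consequence is that static localization error (which adds
4σ_loc² to every MSD point) inflates D instead of being absorbed by an
intercept. The bias is monotone in σ_loc and is covered by a test; a
free-intercept fit is available (`through_origin=False`). On 1,000
simulated noiseless tracks the ensemble mean D is within 5% of truth for
D ∈ {0.05, 0.18, 0.5} µm²/s. Tracks export to a plain
(particle, frame, x, y) CSV for external Bayesian state-array tools.

## Large-cluster (puncta) criterion

A cell "exhibits clustering" when > 1% of its integrated fluorescence lies
in small high-contrast structures. Pipeline: Gaussian smoothing (σ = 1 px)
→ background correction → normalization of the mean in-cell intensity
to 1 → 3×3 (4-neighbor) Laplacian, sign-flipped so bright puncta respond
positively → threshold (default 5) → one 3×3 binary dilation → compare
intensity inside the mask with the cell total. Background correction is
unspecified upstream of us; we subtract the median intensity outside the
cell mask, or the 5th percentile when no mask is given — both scale-safe.
Mean normalization (over the mask when provided) makes the decision
invariant to illumination and gain, which a test asserts exactly. A
uniform image has no contrast and returns fraction 0; an all-zero image is
rejected as undefined. The response threshold sits downstream of our
background choice, so its effective value may need recalibration against
other normalization chains; it is exposed as a parameter.

## The synthetic-data generator

`simulate_trajectories` → `render_movie` emulate the acquisition end to
end: oligomers of configurable size distribution perform 2-D Brownian
motion (per-axis step SD √(2DΔt)) in a reflecting or periodic field,
optionally confined to a binary region mask (crudely emulating tubule
geometry; steps leaving the mask are rejected in place); protomers are
labeled by the three-state model; each fluorophore photobleaches
irreversibly with a per-frame probability (absorbing state — blinking is
not modeled, matching the model's single undetectable term); the partner
channel is sampled a half-frame (default 0.03 s) after the reference
channel, as sequential two-channel acquisition implies, while analysis
pairs channels by combined-frame index exactly as the real pipeline does.
Rendering integrates a Gaussian PSF over pixel boundaries (erf form),
adds constant background, Poisson shot noise, and Gaussian read noise,
and produces channel-interleaved uint16 stacks.

Defaults are the study conditions: D = 0.18 µm²/s, 60 ms combined frames,
100 frames/cell, P_L = 0.14 per color, bleach probability 0.01/frame
(movies short enough to avoid extensive bleaching), pixel size 0.065 µm
(100× objective, 6.5 µm sensor pixels), PSF σ = 1.3 px, 1,000 detected
photons per fluorophore per frame over a background of 50 counts
(SNR ≈ 8–10, typical of bright rhodamine dyes under oblique-angle
illumination), read noise 2 counts. `truth_to_tracks` bypasses rendering
and returns ground-truth trajectories with configurable localization
noise (default 20 nm) — the oracle used to test the classifier in
isolation.

Not emulated: the ER network's actual topology (the mask is a stand-in),
anomalous or state-switching diffusion, dye blinking, chromatic offset
between channels, and cell-to-cell variability in expression or labeling.
Passing tests on this generator therefore validate the *algorithms* under
the stated physical model, not robustness to every real-data pathology.

## Batch analysis and reproducibility

One movie (or one pair of per-channel track files) is one cell. A JSON
config fixes `N`, `T`, tracking parameters, the folder per condition, and
iteration counts; unknown keys are rejected. Per-cell 95% CIs are
percentile bootstraps over per-track co-localizer flags; per-condition
CIs bootstrap cells; both views are exposed because resampling level is
an analysis choice. Pairwise condition comparisons report a two-tailed
t-test and an approximate permutation test,
p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (n_perm + 1), whose smallest attainable
value is 1/(n_perm+1) and whose null distribution is uniform (verified by
a KS calibration test). Cells with zero eligible reference tracks are
reported but excluded from condition aggregates. All randomness
(simulation, bootstrap, permutation) derives from the single config seed
through per-task `numpy` seed sequences, so a rerun reproduces every
output byte for byte.

## Problem sizes used in the shipped checks

The package's own verification suite runs at deliberately chosen scales:
10⁶ particles for Monte-Carlo labeling checks; 1,000 tracks × 100 frames
for diffusion recovery; 2,500–7,500 dimers for classifier calibration;
and, for the full-pipeline control experiment, 10 cells per condition of
56 × 56 µm rendered movies at matched per-channel density (~0.02 eligible
tracks/µm², N = 14 / T = 0.85 — a low-floor instrument-style operating
point), which separates constitutive dimer from monomer controls with the
permutation test at its floor. These sizes give sampling errors well
below the effect sizes being asserted.

## Known limitations

* The percentage statistic is asymmetric (reference-channel denominator)
  and density-dependent through its false-positive floor; compare
  conditions only at matched density, and use the `f_obs` estimator for
  stoichiometry.
* The stoichiometry model lumps every loss mechanism into one
  undetectable state; `P_L` calibrated on a dimer control absorbs those
  losses only to the extent they are shared by the experimental samples.
* The MSD estimator is per-track noisy (few segments per track); it is
  intended for ensemble means and distribution shifts, not single-track
  classification.
* Gap-closed track segments may occasionally bridge distinct particles at
  high density; identity switches are < 1% at the recommended densities
  but grow quickly beyond them.
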