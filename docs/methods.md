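# Methods

## Mass targeting

A transamination converts an amino donor R-CH(NH₂)-R′ into the carbonyl
compound R-C(=O)-R′. On the elemental formula this is the net transform
**−NH₃, +O** (Δm = −1.031634 Da): the nitrogen leaves with the
transferred amino group, the α-carbon gains a carbonyl oxygen. `chem`
applies this bookkeeping to any donor with a transferable primary amine
(N ≥ 1, H ≥ 3 at the formula level) — α-amino acids yield keto acids,
primary amines yield aldehydes. Monoisotopic masses are summed from the
NIST atomic-mass table shipped with pyteomics (`pyteomics.mass.nist_mass`,
≥ 9 decimals).

The oxime probe's m/z bookkeeping is deliberately a single convention:
the O-alkyloxyamine fluorous tag is treated as a **net additive
contribution** of 793.2365, and the condensation releases one water, so

    conjugate m/z = 793.2365 + M(compound) − 18.010565.

Whether the instrument observed protonated or as-deposited species is
not resolved by this convention — it simply reproduces the three
browsable display channels (Leu → 905.3, Trp → 978.3, His → 929.3) to
one decimal, and both the tag contribution and the condensation loss are
configurable on `ProbeSpec`.

Targets closer than the m/z tolerance (default 0.05 Da, matching the
display window used with such data) are cross-flagged. Two collision
classes matter:

* **isomeric products** (Leu/Ile, AABA/GABA/BABA): identical conjugate
  m/z in *different* wells — harmless for scoring, reported as warnings;
* **degenerate pairs**: a well whose product is chemically identical to
  its own keto acceptor (Glu with α-ketoglutarate, Ala and β-Ala with
  pyruvate, Phe with phenylpyruvate). Product and residual acceptor then
  share one channel and the conversion ratio is unidentifiable; such
  wells are marked *not evaluable* and excluded from hit calling with an
  explicit reason, rather than guessed at.

Donors that cannot form a stable taggable carbonyl (S-adenosyl
methionine's sulfonium chemistry; flagged `no_stable_ketone` in the
panel) keep their wells in the design but are likewise reported
not-evaluable. Glutamine's product α-ketoglutaramate reversibly cyclizes
to a lactam, leaving only a small open-chain (taggable) fraction; its
targets carry a `cyclizes` warning but remain scoreable.

The bundled panel holds the 31 screen donors, the three screen acceptors
(α-ketoglutarate, pyruvate, phenylpyruvate) and ten further keto acids
used in acceptor-side validation. Formulas are neutral species.

## Synthetic plate generator

The generator emulates the acoustically printed NIMS experiment with the
assay's stated conditions as defaults:

| parameter | default | meaning |
| --- | --- | --- |
| donor / acceptor | 10 mM / 6 mM | reaction stoichiometry |
| replicates | 3 | biological replicates per cluster |
| pitch | 900 µm | spot center-to-center distance |
| raster step | 75 µm | pixel size (pitch = 12 px) |
| spot FWHM | 3 px | Gaussian footprint, ≈ 225 µm for a 10 nl deposition; ≥ 9 informative pixels per spot |
| spot_efficiency_cv | 0.10 | log-normal desorption/ionization factor shared by all ions in a spot |
| ion_noise_cv | 0.03 | independent per-ion Gaussian factor (floored at 0) |
| baseline_level | 2 counts | additive per-pixel level at every panel channel |
| mz_jitter_sd | 0.005 Da | per-spot peak-position jitter |
| center_jitter_px | 1 | uniform spot-center offset, exercises registration |

Planted truth is a map (enzyme, donor, acceptor) → converted fraction f
of the donor pool. Ion amounts follow 1:1 stoichiometry: product
∝ 10f, residual acceptor ∝ max(0, 6 − 10f) (in counts; 100 counts/mM),
so the *observed* ratio of an active well is 10f/6 until the acceptor is
exhausted. `TruthProfile.for_observed_ratio` inverts this so profiles
can be planted on the observed-ratio scale. Controls carry no donor and
the full acceptor pool.

Noise family choices (unconstrained by the assay description): the
shared spot factor is log-normal (strictly positive, mean 1) because it
models a multiplicative surface efficiency — exactly the variability the
ratio statistic is designed to cancel; per-ion factors are Gaussian with
a floor at zero. Intensities are arbitrary counts; no detector
saturation, no matrix clusters, no profile-mode peak shapes, no
cross-contamination between wells. Everything is reproducible from a
single integer seed, and the generator returns a ground-truth table
(true centers, efficiency factors, amounts, expected ratios).

What passing tests on this generator shows: the pipeline recovers
planted activity patterns under realistic multiplicative noise, the
ratio statistic cancels shared efficiency, registration tolerates
sub-pitch printing offsets. What it does not show: robustness to
chemical background peaks, mass-calibration drift, spot shape anomalies
or carryover — real-data concerns outside the generator's scope.

## Extraction

`ion_image` sums centroid intensities within a **closed** ±tol window
(default 0.05 Da) per pixel. Grid registration moves each expected
center to the integer position within the search radius (default 2 px)
maximizing the summed intensity over the spot disc (default radius
2 px); ties break by smallest displacement, then row-major order, so a
flat image leaves centers unchanged and the objective never decreases.
The pipeline registers on the image summed over *all* panel channels,
because control spots have no product signal of their own. The per-spot
reduction is the mean over the disc (a summed variant is available).
Coordinates are 0-based (row, col) pixels; physical position = pixel ×
pixel size.

## Scoring

Per spot, r = I_product/(I_product + I_acceptor); both-zero input is
undefined (NaN) and propagates as missing, never as 0. Controls are
matched per (enzyme, acceptor) — the acceptor channel defines the
control's denominator — and summarized by the sample mean and SD (n−1)
of their replicate ratios. Because a control well contains no donor, its
"product" intensity is defined as the mean over all product channels of
the panel that do not collide with an acceptor channel: pure background,
one ratio per control replicate.

The dual rule uses strict inequalities on the replicate mean: active ⇔
mean r > 0.1 AND mean r > control mean + 10 × control SD. Per-replicate
pass counts are reported for transparency; a combination needs ≥ 2
evaluable replicates to be called at all (fewer → reported missing, not
inactive). No multiple-testing correction is applied, matching the
assay's design where the 10-SD margin itself provides the stringency. A
re-call at a lowered ratio threshold (0.05) surfaces borderline
combinations for sensitivity analysis. Z-factors use a hit's replicate
ratios as positives and the matched control ratios as negatives.

The titration fit is unweighted least squares of r = Vmax·x/(Km+x)
(scipy `curve_fit`; Vmax₀ = max(y), Km₀ = x at half-max, Vmax bounded to
[0, 1.5], Km > 0), reporting r² = 1 − SSres/SStot and asymptotic
standard errors.

## Kinetics

Michaelis–Menten fits are unweighted nonlinear least squares on initial
rates; kcat = Vmax/[E]. Fits with Km outside the tested concentration
range, or with essentially flat rates (saturation-only designs), are
flagged rather than failed, since the estimate is then extrapolated.
The Salkowski turnover converts background-subtracted 530 nm absorbance
to product concentration through a linear standard curve and normalizes
per enzyme per time; readings below background floor at zero with a
warning. No printed kinetic constants exist to compare against, so this
module is validated by simulation recovery (median relative error < 10%
at 5% rate noise across a kcat × Km grid).

## Reference screen profiles

`profiles.py` plants two demonstration screens. The tyrosine-AT screen
(20 proteinogenic donors × α-ketoglutarate) marks Tyr, His, Leu, Met,
Phe and Trp active with observed ratios 0.35–0.85. The broad-specificity
screen (31 donors × 3 acceptors) marks 13 donors active with at least
one acceptor (Ala, Arg, Asn, Asp, Glu, His, Leu, Met, Phe, Trp, Tyr,
AABA, O-methyl-tyrosine) and all three acceptors used, with
phenylpyruvate the weakest; Asp is active only with α-ketoglutarate, and
four donors (Gln, Ile, Val, Ser) sit between 0.05 and 0.1 so that only a
lowered threshold reveals them. Degenerate wells (Glu×α-KG, Ala×pyruvate,
Phe×phenylpyruvate) are planted active where true but recovered through
the non-degenerate acceptors, so headline counts never depend on an
unidentifiable channel. The specific ratio values within these bands are
package choices, fixed once.

## Problem sizes and numerical choices

The full broad-specificity screen renders 96 clusters (288 spots) on a
241 × 481 px surface with 34 m/z channels — about 4 million centroids —
and runs end to end in a few seconds; the test suite completes in well
under a minute. Window comparisons are closed intervals; disc membership
is Euclidean (dr² + dc² ≤ r²); spot rendering uses a ±4 px window
(> 3σ of the footprint), so cluster neighbours at 12 px never overlap.
Degenerate inputs are handled explicitly throughout: empty formulas,
zero-variance Z-factor sides (undefined when means coincide), all-zero
titrations (flagged, Vmax → 0), spots outside the image (missing value
with warning).

## Known limitations

* Single-adduct model: no isotope patterns, no adduct series, no E/Z
  oxime isomerism (mass-identical anyway).
* The tag-contribution convention is calibrated to the display channels,
  not to a resolved ionization model.
* Absolute quantification via spiked internal standards is out of scope
  (interface-level only); the assay is semi-quantitative by design.
* The generator's intensity scale and noise levels are calibration
  choices, not fitted to any instrument's data.
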