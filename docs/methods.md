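# Methods

`calfish` quantifies, per cultured cell, the agreement between a functional
calcium response and single-molecule in situ hybridization (RNAscope)
signal. This note describes the analysis model, the synthetic-data
generator used to validate it, and the numerical choices behind both.

## Functional scoring

The functional recording is a 1 Hz sequence of paired frames excited at
340 nm and 385 nm. For each channel a scalar background — the intensity
mode of all pixels outside every ROI, estimated on the time-averaged frame
with a Freedman–Diaconis histogram — is subtracted before the pixelwise
F340/F385 ratio is formed; pixels whose 385 nm denominator is non-positive
carry no signal and are excluded from ROI means. A cell's trace is the
mean valid ratio over its ROI per frame.

Each agonist application is scored as the trapezoidal area under the
baseline-corrected trace over the 60 s following application onset
(ratio·s). The baseline is the mean of the five samples in the half-open
window [start − 8 s, start − 3 s); the half-open convention makes the
sample count exact at 1 Hz. Negative areas are retained — clipping them
would bias the non-responder distribution that the response threshold is
fitted to. Cells count as viable neurons only if the peak
baseline-corrected ratio within the 60 mM KCl window (plus a 10 s tail
for slow risers) reaches `min_delta` (default 0.1 ratio units; the gate
criterion itself is standard, the cut-off is a package choice). Only
gated cells enter classification.

## RNAscope quantification

Confocal Z-stacks are combined by average-intensity projection — the
average reflects total signal along the light path — and each cell's
index of mRNA content is the background-subtracted mean projected
intensity over its ROI (background again the off-ROI mode; an
area-integrated variant is available via `statistic="integrated"`).
Values are floored at zero: a cell cannot carry negative signal, only
noise can. The positivity threshold is mean + 2·SD (sample SD, n − 1) of
intra-day negative-control probe intensities.

For sparse signal in neurites a Laplacian-of-Gaussian blob detector over
σ ∈ [1, 3] px on a maximum-intensity projection returns puncta
candidates; its LoG threshold defaults to 0.15 of the image dynamic
range, which holds precision and recall above 95% for diffraction-limited
spots down to single-digit SNR in planted-spot benchmarks. Puncta counts
are not used in the headline correlation: perikaryal signal is dense
enough that discrete molecules merge, so the mean-intensity index is the
robust statistic there.

## Registration and ROI transfer

The confocal and wide-field frames differ by an in-plane similarity
transform (rotation, translation, isotropic scale — different optics on
the two microscopes). Coordinates are 0-based (x right, y down), pixel
centers at integers, and the stored transform maps confocal → wide-field.

Estimation is intensity-based on the transmitted-light image pair: a
coarse grid over rotation (±16° in 2° steps) and scale (0.88–1.13 in 0.04
steps) is scored by phase correlation (translation) plus normalized
cross-correlation over the valid overlap, and the best candidate is
polished by Powell optimization of the NCC over all four parameters. A
final NCC below 0.2 is flagged as low-confidence. A closed-form
least-squares landmark fit is available as the fallback for fields where
intensity registration is unreliable. Inside the pipeline the estimate
runs on 2× block-downsampled images (with exact conversion of the
transform back to full-resolution coordinates); at the pipeline's image
scale this is accurate to ~0.002° and ~0.01 px, orders of magnitude below
what ROI transfer needs. Benchmarks over random transforms within ±15°,
±20 px and scale 0.9–1.1 at SNR 5 recover parameters within 0.2°, 0.5 px
and 0.005 scale.

ROI label images are carried into the confocal frame by nearest-neighbor
lookup through the transform (labels are categorical; interpolation would
invent values). ROIs that land entirely outside the confocal field are
dropped and reported.

## Thresholding and classification

Both modalities use the same rule: positive means strictly greater than
mean + 2·SD of a Gaussian reference. For RNAscope the reference is the
negative-control probe. For the functional AUC the reference is the
population of non-responders — a circular definition, since
non-responders are whatever falls below the threshold being fitted. The
package resolves the circularity with a deterministic fixed-point
iteration: initialize the threshold at median + 2·(1.4826·MAD) (robust to
the responder mode even when responders are a third of the sample), then
repeatedly (i) keep values ≤ threshold, (ii) refit (μ, σ), (iii) set
threshold = μ + 2σ, until the kept set stops changing (cap 50 iterations,
non-convergence reported).

The refit is censoring-aware maximum likelihood — the kept sample is
modeled as a Gaussian truncated above at the current threshold. Plain
moment refits are inconsistent here: every trim shrinks the sample SD, and
on a pure Gaussian the trim-and-refit map has its fixed point near
μ + 1.72σ (the solution of −h(z) + 2·sqrt(1 − z·h − h²) = z with
h = φ(z)/Φ(z)), not μ + 2σ. With the truncation correction the procedure
recovers μ + 2σ on pure Gaussians to within 0.05σ at n = 10⁴ and induces
the nominal one-sided false-positive tail of ≈ 2.3%.

Gated cells fall into four categories — positive on both modalities,
RNAscope-only, functional-only, neither — and the Pearson product-moment
correlation (two-sided p from the t-distribution with n − 2 df; a seeded
permutation variant is available) is computed over the *union* of cells
positive on either modality, on raw intensity and raw AUC by default
(log–log as an option). Category counts always sum to the gated-cell
count, and raising either threshold can only shrink the union.

## The synthetic-data generator

No per-cell raw data accompany the study this pipeline reimplements, so
validation is end-to-end on simulated recordings with known truth.

**Population.** Of `n_cells` (default 500), a deterministic 85% are
neurons; only neurons depolarize to KCl, express probes, or respond to
agonists. Per probe channel, a neuron expresses with probability
`fraction_expressing` (default 0.35 — between typical functional and mRNA
positivity fractions for these channels in dissociated sensory cultures);
expression among expressors is lognormal (median 150 a.u., log-sd 0.8)
and responder AUC is lognormal (median 25 ratio·s, log-sd 0.7): both
quantities are positive, right-skewed, and continuous down to the
detection floor. Discordance knobs (`p_silent_expressor`,
`p_responder_nonexpressor`, default 0) create mRNA-positive
non-responders and responders without mRNA.

**Correlation calibration.** `true_correlation` is defined as the
expected raw-scale Pearson correlation of (measured intensity, measured
AUC) over the pipeline's union set — the statistic the pipeline actually
reports. The generator achieves it in closed form: the union is a mixture
of clusters (co-positive cells, the two discordant classes, and the
≈ 2.3% functional false positives of the blank class that the threshold
rule necessarily admits, sitting at the origin), whose means and
variances — including measurement-noise variances — are known; the
mixture-moment equation is solved for the within-class latent correlation
of the jointly-lognormal co-positive cells (for a bivariate lognormal the
raw covariance is m_x·m_y·(e^{ρ_l σ_x σ_y} − 1), inverted for ρ_l).
Targets that the configured discordance geometry cannot reach clip to
±1 with a warning — with study-scale discordance the union correlation
is dominated by the cluster geometry, not the within-class coupling.

**Discordance emulation.** `discordance_from_counts` inverts observed
category counts into latent rates, accounting for the fact that the
threshold rule converts ≈ 2.3% of function-negative cells into apparent
responders; expected *observed* counts then match the published
breakdown.

**Recovery benchmark.** Fisher-z confidence intervals presume a bivariate
normal sample. A thresholded union drawn from a bimodal population with
discordant clusters has super-Fisher sampling variance (origin-adjacent
false positives carry leverage on r, and lognormal tails inflate var(r)
at high ρ) — a real property of this analysis design worth knowing when
interpreting such correlations. Correlation-recovery validation therefore
uses `correlation_recovery_config`: every gated neuron expresses and
responds (the single-population analog of a co-transfected cell line),
with bivariate-normal marginals at moderate CV (intensity 150 ± 25,
AUC 25 ± 5), so the union is the whole coupled population and the
recovered R is Fisher-consistent. Measured coverage at ρ = 0 / 0.43 / 0.9
over 400 replicates is 93.5 / 93.2 / 96.0% against a nominal 95%.

**Traces.** A response is a single-exponential rise (τ = 3 s) to a
plateau for the application duration, then exponential decay (τ = 20 s),
on a 0.8 baseline ratio; the amplitude is scaled so the trapezoidal area
of the noiseless kernel *on the acquisition grid* over the 60 s scoring
window equals the cell's true AUC, making noiseless recovery exact by
construction. KCl responses have fixed amplitude 0.8 for responsive
cells. The default schedule is AITC 100 µM at 20 s for 60 s, capsaicin
1 µM at 210 s for 30 s, KCl 60 mM at 290 s for 15 s; the ~2 min washout
gaps keep each decaying tail below the noise floor before the next
flat-baseline window, so per-window baseline correction stays unbiased.

**Images.** Cells are disks (radius 4 px) placed by random sequential
adsorption with an 11 px minimum separation inside a 30 px margin. The
340 nm cell intensity follows the cell's ratio trace against a constant
385 nm brightness, over per-channel constant backgrounds, so the
background-subtracted pixel ratio reproduces the trace. Confocal stacks
put the expression value uniformly over the soma across 21 planes (the
perikaryal signal is dense; discrete puncta are not modeled there), with
the soma drawn 0.8 px larger than the ROI disk — ROIs are adapted to lie
inside the cell boundary, so every transferred ROI pixel samples the
plateau rather than a partially-filled edge. The confocal frame is
displaced from the wide-field frame by a known similarity transform
(default 3°, (12, −7) px, scale 1.03), and matched transmitted-light
images are rendered analytically in both frames. Pixels receive Poisson
photon noise plus Gaussian read noise (SD 3); a mean/variance-matched
Gaussian approximation to the photon term (`photon_noise="gaussian"`,
indistinguishable at the ≥150-count levels simulated) is available and
used for the largest validation runs. Negative-control intensities are
drawn from N(0.5, 1.2) a.u., clipped at zero — wider than pure photon
noise, as real control wells include autofluorescence variability.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: optics (no PSF, no depth attenuation, no
pinhole model), cell morphology (disks, no neurites in the headline
images), motion and focus drift, photobleaching, Fura-2 saturation,
spectral bleed-through between Opal dyes, day-to-day staining batch
effects, and correlation between the two probes' expression (channels are
sampled independently). Trace kernels are stereotyped; real response
shapes vary by receptor kinetics.

## Determinism and problem sizes

Every stochastic step flows from one `numpy` Generator seeded from the
config; identical configuration and seed give bit-identical images and
byte-identical run reports. Reported validation sizes — chosen as
standard desk-scale experiment sizes — are: 500 cells on 512² frames for
per-seed recovery runs (20 seeds), 1200 cells on 640² frames for the
correlation summary (8 seeds), and 1047 cells (890 gated, the published
population size) on 640² frames for discordance emulation (16 seeds).
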