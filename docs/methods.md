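# Methods

## The dose-field model

A spatially fractionated (microbeam) field is modelled as a periodic
lattice of rectangular stripes: dose `D_peak = pvdr × D_valley` inside
a stripe of width *w* (default 50 µm), `D_valley` outside, with
centre-to-centre pitch *p* (default 400 µm). Prescriptions quote the
valley dose. The lattice is treated as infinitely periodic along the
lateral axis — `dose_at` is exactly pitch-periodic — while `n_beams`
(default 25) bounds the extent of rendered fields.

Penumbra is modelled as convolution of the ideal lattice with a
unit-area Gaussian of scale σ, evaluated in closed form through the
Gaussian CDF on each stripe. A Gaussian penumbra is the standard
dosimetric choice and gives closed forms for the dose, its mean
(conserved under convolution) and the FWHM; exponential-tail penumbrae
are not modelled. The analytic FWHM references half-maximum to the
*valley floor* (half = valley + (peak − valley)/2), matching profiles
normalised to percent of peak intensity over a non-zero valley;
an absolute-zero baseline is available (`baseline="zero"`). A FWHM of
a single peak stops being measurable when broadening washes out the
lattice; this is flagged when peak/valley contrast falls below 2% (or,
for the zero baseline, when the valley floor rises above
half-maximum). Note that for σ ≲ w/2 the FWHM stays essentially at the
collimated width — a rectangle convolved with a symmetric kernel still
crosses half-maximum at its edges — so visible broadening (e.g. a
67 µm width, 34% over nominal) implies a penumbra scale of roughly
σ ≈ 24 µm.

## The synthetic-image generator

The generator emulates a confluent monolayer fixed shortly after
irradiation and imaged in two channels at a 20×-like sampling. Study
conditions (defaults, chosen once):

| parameter | default | rationale |
|---|---|---|
| pixel size | 0.65 µm/px | typical 20× dry-objective scale |
| field | 2000×900 px (1300×585 µm) | > 3 lattice periods per image |
| nuclei per image | 675 | confluent-monolayer sampling, non-overlapping |
| nucleus radius | 8 ± 1 µm | large gliosarcoma-like nuclei |
| focus σ | 0.6 µm | near-diffraction-limited punctum |
| γH2AX yield | 4 foci/nucleus/Gy | keeps peak-nucleus foci countable at this sampling |
| background | 0.05 foci/nucleus | unirradiated control level |
| focus amplitude | lognormal, CV 0.25 | foci vary individually in brightness |
| noise | Gaussian σ 50 counts on a 150-count pedestal | detector read noise |

Beams run parallel to the image y-axis. Per nucleus the true focus
count is Poisson with mean `background + yield × dose(x_centre) ×
enhancement`, where the enhancement multiplier is `enhancement_peak`
for nuclei whose centre lies inside a stripe and `enhancement_valley`
elsewhere (transition-zone nuclei — centres within 2σ of a stripe edge
— carry the valley multiplier and a distinct ground-truth label). The
dose is evaluated at the nucleus centre: a cell's damage burden
follows the dose its nucleus received, and cells straddling a beam
edge inherit the centre dose, which mirrors the "half a cell in the
beam" ambiguity of real transition zones. Foci fall uniformly inside
their parent nucleus; an optional ceiling on the Poisson mean probes
the saturation regime (off by default — DSB yield is linear in dose).
All draws flow from one counter-based (Philox) generator, so the same
seed and configuration are bit-identical.

A true γH2AX yield is tens of foci per Gy; the default of 4 is a
deliberate down-scaling that keeps per-nucleus foci resolvable at
0.65 µm/px while preserving every ratio the pipeline measures (PVDR
contrast, DSBER linearity), which are yield-independent. The generator
does not emulate z-stacks, optical PSFs beyond Gaussian spots,
photobleaching, cell-cycle focus kinetics, or nucleus-to-nucleus
repair variability; passing tests therefore validate the estimators
under the stated generative model, not those confounders.

## Focus detection and the foci factor

Nuclei are segmented by Otsu thresholding of the smoothed counterstain
with a distance-transform watershed to split touching nuclei (minimum
area 20 µm²). Foci are detected by multiscale Laplacian-of-Gaussian
blob detection on a contrast-normalised image; the normalisation scale
`max(p99.9 − median, 10 × robust σ)` and a 5-robust-σ floor on each
blob's local maximum are both homogeneous in intensity, so detection
is invariant to global intensity rescaling. A blob's *area* is its
measured footprint (pixels above half its local maximum), so a merged
blob keeps an area proportional to its multiplicity; its *integrated
intensity* is aperture photometry over a 3σ disk with an annulus
background that removes neighbouring foci's tails.

The foci factor — equivalent foci per nucleus in a region — has two
strategies behind one interface:

- **area** (the `foci_factor` default): Σ focus areas / median focus
  area, divided by the effective nucleus count (regional nuclear area /
  mean nucleus area).
- **intensity**: total background-subtracted foci-channel flux inside
  nuclear masks, divided by the single-focus flux unit (median
  integrated intensity of size-typical, spatially isolated foci).
  Flux is exactly conserved when foci merge, so this stays unbiased in
  the overwhelmed high-dose-peak regime, where footprint-based counts
  lose 10–15%; ground-truth recovery drove this choice, and the BPVDR
  pipeline uses it.

Region membership is positional by default (nuclear area apportioned
pixel-by-pixel, so straddling nuclei contribute proportionally);
`assign="nucleus"` instead assigns whole nuclei by centroid — the
whole-cell convention of drawn ROIs, and the assignment consistent
with dose-at-centre biology. The pipeline uses nucleus assignment:
proportional splitting pushes the signal of peak-edge nuclei into
valley ROIs and biases the BPVDR several percent low.

DSBER is the plain ratio of two foci factors; the unirradiated
control's whole-image FF is the denominator for regional DSBERs.

## Beam profiles

`lateral_profile` column-averages the foci channel (median-subtracted
to remove the camera pedestal; auto-orientation by comparing row/column
trace variance, ambiguous below a 1.2 ratio). `detect_peaks` finds
prominent smoothed maxima, refines each to the centroid of its
above-half-maximum span, and — when the trace autocorrelation shows a
dominant period — discards candidates inconsistent with the lattice;
the pitch estimate divides out gaps from missed peaks.

`segment_average` pools up to 16 one-pitch windows across replicate
traces. Window centres are *not* the per-peak centroids: centroids
self-align on their own nucleus-scale noise and sharpen the average by
2–3 µm. Instead each trace's detected centres are projected onto a
regular lattice whose common offset is the fundamental Fourier phase
of the whole trace — a single-frequency statistic nearly orthogonal to
edge-shape noise, leaving the averaged width unbiased. The average is
normalised so the central 40% of the nominal width reads 100%.

FWHM is read between the valley floor (mean of the outer 25% of the
window per side, robust to near-peak shoulders) and the plateau, with
crossings located by an outward scan and linear interpolation; ties at
exactly half resolve to the outermost crossing. A light (3 µm default)
smoothing stabilises crossing detection against correlated
nucleus-scale noise; it is off for clean geometric profiles. On
heavily broadened profiles the edge slope is gentle and crossing-based
readings become nucleus-shot-noise limited (several µm of scatter), so
`fit_gaussian_broadening` additionally fits the closed-form broadened
lattice (floor, amplitude, σ, centring shift free; width and pitch
nominal) to the whole window — the penumbra-fitting convention of
dosimetry — from which an FWHM follows analytically.

The end-to-end pipeline pools the pitch across replicates (median of
per-image estimates, then refinement by maximising the stripe-template
correlation over candidate pitches) and re-derives each image's ROI
lattice by whole-trace template matching, which stays accurate down to
peak/valley contrasts near 2 where individual maxima fail.

## Biological PVDR

Peak ROIs are centred on the detected lattice with width equal to the
measured FWHM (adaptive mode, accounting for broadening) or fixed at
the nominal 50 µm; valleys are the complement. The pipeline excludes a
5 µm band at every peak-ROI edge from both regions: the FWHM carries a
couple of µm of uncertainty, and a single peak-edge nucleus
misassigned to the valley inflates the valley FF noticeably. (The
`partition` primitive itself defaults to no buffer, i.e. an exhaustive
peak+valley tiling.) BPVDR is the average of per-image
FF_peak/FF_valley ratios — the average of ratios, not the ratio of
averages — over at least 6 replicates, with uncertainty reported as
`sem_95 = 2 × sd / √n`, the 95%-confidence SEM convention used
throughout (including clonogenic error bars).

At the reference conditions (PVDR 8.9, no enhancement) the pipeline
recovers BPVDR ≈ 8.8 ± 0.4 across seed sets, FWHM 50 ± 2 µm and pitch
400 ± 1.5 µm; configured PVDRs of 2, 5 and 8.9 are recovered within
5%. The ~1–2% residual BPVDR deficit is the dose-independent
background plus detection-chain losses.

## Clonogenic analysis

Plating efficiency is colonies counted (colonies of ≥ 50 cells, an
upstream counting convention) over cells seeded. Plates with fewer
than 50 or more than 300 colonies are discounted; the boundaries are
literal (50 and 300 kept; 49 and 301 dropped). The surviving fraction
is the mean treated PE over the mean reference PE — the cell-only
control for unirradiated points, the same treatment's 0 Gy sample for
irradiated points — with the SEM over per-plate SFs. Linear-quadratic
curve fitting is out of scope.

## Numerical and design notes

- Degenerate inputs: an empty counterstain image segments to zero
  nuclei (not an error); saturated images set a flag and warn; a
  single detected peak flags the pitch as undefined; fewer available
  profile windows than requested are used as-is and recorded.
- `sem_95` is undefined (raises) below two values; BPVDR from a single
  image carries `sem=None`.
- Seeds: every generator draw derives from the config's single seed
  through Philox; the CLI derives per-image seeds as `seed + i`.
- Problem sizes in the test-suite: unit tests run a half-scale lattice
  (25 µm beams at 200 µm pitch) on ~700×300 px images; the
  acceptance-level checks run the reference lattice at full image
  size with 6 replicates (and 10 wide images for the broadened-FWHM
  check), sizes chosen to keep estimator noise a few times smaller
  than the tolerances they assert.
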