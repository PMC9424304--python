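# Methods

This note documents the models behind `uvplume`, the parameter choices
that matter, what the synthetic generator does and does not emulate,
and the numerical conventions used throughout.

## Spectral world and forward camera model

All spectral quantities live on a 300–700 nm grid with a 5 nm step
(81 points); band integrals use the midpoint rule, which is exact for
the piecewise-constant curves involved. The illuminant is flat
(idealised illumination). Receptor sensitivities model an average
ultraviolet-sensitive (UVS) avian visual system as Gaussians peaked
near 370 (u), 445 (s), 508 (m) and 565 nm (l), normalised to unit
integral; the world seed perturbs peaks by ±2 nm and widths by ±5% so
distinct but structurally identical worlds exist.

The camera has five channels: visR/visG/visB behind a UV/IR-cut filter
(zero below 400 nm) and uvR/uvB behind a UV-pass filter (zero above
400 nm). A UV-range green channel is deliberately absent: camera green
channels carry too little sensitivity in the UV to be useful, so the
model never creates one and the mapping basis never sees one. Camera
curves are scaled so a perfect white reflector under the reference
illuminant yields a response of exactly 1 per channel at gain 1; this
is a pure units convention and cancels in normalisation.

A pixel's channel response is
`gain × Σ_λ illuminant·reflectance·sensitivity·Δλ`, linear in both gain
and reflectance. Quantum catches use the same integral with receptor
sensitivities; *relative* catches divide by their sum, so a flat
spectrum under the flat illuminant sits at the achromatic centre
u = s = m = l = 0.25 exactly.

## Synthetic specimens

A specimen image is a body ellipse plus head disc rendered above a row
of five grey standards (2/40/60/80/99% nominal reflectance, left to
right), on a dark(0.5%) background — near-black but nonzero, so
thresholding baselines face a realistic task. An eye disc
(dark, non-plumage) and a bright label rectangle (flat 85%,
disconnected from the specimen) are optional. Per-pixel channels are
the forward model plus zero-mean Gaussian noise clipped at zero.
Defaults give the specimen a UV-yellow body (UV bump 0.25 + long-pass
0.55) and a UV-peaked, visibly dark head (bump 0.45) — the two
qualitative colour classes the UV metrics are designed to separate.
The generator does **not** emulate plumage texture, patchiness,
specular highlights, chromatic lighting gradients, or camera vignetting;
pipeline accuracy on these images is an upper bound on real-archive
accuracy, and the segmentation "sanity" bars (IOU > 0.8) are properties
of this fixture, not claims about museum photographs.

## Classic segmentation

Both baselines work on an unweighted mean of the three visible
channels, min–max rescaled to 0–255 integers (the greyscale conversion
is otherwise unspecified in the source workflows). Gaussian smoothing
(σ = 1 px, reflective borders) precedes both; a morphological close
then open with a 3×3 square element follows both. Thresholding
binarises at the modal histogram value plus 15 (ties in the mode broken
toward the darker value, matching the dark-background assumption) and
keeps the 8-connected component whose topmost pixel has the smallest
row index (ties by larger area) — the specimen always sits above the
standards. Region growing admits 4-neighbours whose grey value lies in
[seed−6, seed+30]; the window is anchored at the *original seed value*
(not a running region mean), which makes the grown region exactly the
seed's connected component of the eligibility mask and is how the
implementation computes it.

## Evaluation

Confusion counts are exact pixel tallies for the plumage class; IOU,
precision and recall follow the usual per-class ratios, and mean IOU
averages the plumage and non-plumage classes. A zero denominator
(empty prediction or empty truth) raises `UndefinedMetric`; batch
summaries propagate these as missing values excluded from means, with a
logged count, rather than coercing them to zero. Any mask resizing for
comparison should use nearest-neighbour so masks stay binary.

## Colour pipeline

**Normalisation.** For each channel, an ordinary least-squares line of
nominal reflectance (0.02…0.99) on the mean intensity of the five
standard patches is fitted and applied to all pixels. Linear OLS
through the standards (intercept included) is the simplest form that
(a) returns each standard's nominal reflectance up to fit residual and
(b) removes a global lighting gain exactly; forcing the fit through the
origin would also be gain-invariant and differs only at the dark end.
Non-monotone standard means raise `StandardOrderError`.

**Cone-catch mapping.** One least-squares fit per receptor on the
shared 31-term basis {1, each channel, each squared channel, each
pairwise product, each three-way product of distinct channels} over the
five channels, targeting the *raw* quantum catches; relative catches
come from clipping predictions at zero and renormalising each pixel to
sum 1 (pixels with no positive raw catch are re-cited to 0.25s and
counted). Fitting raw catches and normalising afterwards is what makes
R² > 0.99 achievable — relative catches are ratios and are badly
conditioned near dark pixels. Calibration spectra are random mixtures
of flat, UV-bump, long-pass-sigmoid and UV+long-pass families with the
smoothness of real pigmentary/structural reflectance (UV bump
σ 18–35 nm, i.e. FWHM ≈ 40–80 nm; sigmoid transition scale 20–45 nm; a
2–6% broadband pedestal on chromatic spectra). Narrower or steeper
families create genuine ambiguity — distinct spectra with identical
five-channel responses but different u catches — that no mapping can
resolve; the defaults reflect the band-limited nature of real plumage
reflectance, not a tuned test condition.

**Re-citing.** Pixels whose mean normalised reflectance across the five
channels is strictly below 1% are set to the achromatic centre; the
five-channel mean is the natural camera-space reading of "across all
channels".

**Aggregation and sampling.** Candidate block factors are enumerated
from 100 down to 1 over the mask's bounding box (blocks anchored at its
top-left corner, partial edge blocks allowed); the first factor with at
least 500 valid cells — i.e. the *largest* factor keeping 500 cells,
hence maximal denoising — wins, and 500 cells are sampled uniformly
without replacement under the caller's seed. Reading the search as
"smallest factor" literally would always select factor 1 and make the
enumeration pointless. Aggregation operates on normalised channel
values *before* cone-catch mapping; the mapping is nonlinear, so the
order matters, and averaging camera-space reflectance first mirrors
raster-style downsampling of the photograph itself.

## UV metrics

Mean *u* and peak *u* (mean of the top 50/25/10% of *u* values;
`ceil(fraction·n)` pixels) summarise "pure" UV reflectance. UV+
colouration flags pixels satisfying all of: u quantum catch > 0.05
relative to a 100% white standard; UV-band reflectance > 3%; UV-band
reflectance above the minimum visible reflectance (strict, with a 1e−9
guard against float-equal bands). In camera space the UV band is the
mean of the two normalised UV channels and the visible minimum is the
minimum over the three normalised visible channels — the closest
camera-space analogue of the band-based criteria; the white reference
is a flat 100% spectrum pushed through the same camera/mapping path, so
the catch ratio is internally consistent. A specimen view shows UV+
colouration when the flagged fraction strictly exceeds 5% (1% and 10%
as sensitivity thresholds). Species-level values average specimen
values within species × sex × view; presence flags are aggregated by
strict majority (> 0.5) — an artifact convention, since flag
combination across specimens is otherwise unspecified — and side views
are dropped because back and belly views already cover those plumage
regions.

## Phylogenetic mixed model

The animal model y = Xβ + a + e, a ~ N(0, σ²ₐA), e ~ N(0, σ²ₑI), with A
the shared-path correlation matrix of a unit-height tree (diagonal
jittered by 1e−8 for factorisation stability). Observation rows may
repeat species — the trait tables place each species' sex × view
combinations in separate rows sharing one phylogenetic effect, since
sex and view enter as fixed effects. β carries a flat improper prior;
each variance a scaled inverse-χ² prior with scale V and degree of
belief ν, i.e. inverse-gamma(ν/2, νV/2) — the univariate reading of the
usual (V, ν) parameterisation — defaulting to V = 1, ν = 0.002.

The Gibbs sampler exploits eigen-rotations fixed before the chain
starts: with Z̃ = Z·L (L a symmetric factor of A) and ZAZ' = ŨD̃Ũ',
the rotated response has diagonal marginal covariance σ²ₐD̃ + σ²ₑI once
the effects are integrated out, so β is drawn from its *marginal* full
conditional in O(np²), and the effects are then drawn from their
conditional using a second fixed eigenbasis in O(q²). Together these
constitute an exact joint conjugate (β, a) update — no per-iteration
(p+q)³ factorisation and no β–a random-walk confounding. Variances
update from their inverse-gamma full conditionals. Binary responses use
probit data augmentation (latent truncated-normal draws) with the
residual variance fixed at 1. The probit link is chosen over a
logit-based categorical family for exact conjugacy at desk scale;
effect *directions* are comparable across links but coefficient
magnitudes are not, so binary-model coefficients should not be compared
numerically to logit-scale results.

Chains default to 11,000 iterations, thinning 25, burn-in 1,000 — 400
draws per tree, one-tenth of the full-study settings of
110,000/25/10,000, which remain available through `ChainSettings`.
Posterior summaries use the median and an ECDF-based (inverted-CDF)
95% quantile interval, making summaries depend only on the multiset of
draws — pooling identical per-tree draw sets leaves them unchanged.
Pooling across a tree sample concatenates draws with tree provenance
retained. H² = σ²ₐ/(σ²ₐ+σ²ₑ) per draw from intercept-only fits;
marginal and conditional R² per draw as
var(Xβ)/(var(Xβ)+σ²ₐ+σ²ₑ) and (var(Xβ)+σ²ₐ)/(var(Xβ)+σ²ₐ+σ²ₑ),
with var(·) the population variance over the observed design.

**Identifiability note.** With a single observation per species and
A = I (a star phylogeny), σ²ₐ and σ²ₑ are exchangeable and only their
sum is identified; the replicated sex × view layout is what separates
them (between- vs within-species variance). Recovery checks therefore
use the replicated layout, and the identity-tree calibration check pins
σ²ₐ at zero through its prior instead.

## Comparative-data generator

Pure-birth (Yule) trees with the requested number of extant tips,
scaled to unit height. Three continuous climate predictors (UVB,
temperature, solar radiation) share a latent factor (pairwise r ≈ 0.5)
to mimic their real collinearity; forest dependency and visual system
are Bernoulli (0.5 and 0.3 — UVS rarer than VS); foraging strata is
Beta(2,2). All predictors are standardised. Effects β map onto the
documented predictor order with zero padding. Phylogenetic effects are
drawn once per species with covariance σ²ₐA; the gaussian response adds
iid noise per row, the binary response thresholds the latent value at
zero with residual variance fixed at 1. The generator does not emulate
measurement error in species means, unequal specimen counts, missing
predictors, or phylogenetic signal in the predictors themselves.

## Problem sizes and defaults used in tests

Specimen canvases are 220×300 px (≈17k plumage pixels), calibration
sets 250 spectra, comparative datasets 200 species × 4 rows, and
recovery suites 20 replicates per heritability level at the desk-scale
chain — sizes chosen so the whole suite exercises every stage end to
end in a few minutes on one core while leaving the estimators'
asymptotics visible.

## Known limitations

* The forward camera model is noise-free apart from additive Gaussian
  pixel noise; no photon (shot) noise, quantisation or RAW-decoding
  effects are modelled.
* The cone-catch mapping is only as good as the calibration family;
  spectra sharper than the camera's band structure are irreducibly
  ambiguous (see above).
* Binary-model coefficients are on the probit scale.
* The u cone-catch metric has no enforced upper bound; empirical
  maxima depend on the spectra in play, and no attempt is made to
  reproduce any particular maximal value.
* Chan-Vese and graph-cut baselines are not included.
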