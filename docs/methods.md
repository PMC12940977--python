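# Methods

`ftirxai` studies *why* a neural classifier says an FTIR spectrum belongs to
a molecule carrying a given functional group. It trains one small binary
CNN-KAN classifier per group, attributes each decision to individual input
wavenumbers with expected gradients, and aggregates those attributions into
the summary statistics a spectroscopist can check against band-assignment
tables: signed range sums, S+/S- averages, FA/FB/FC profiles, and extracted
fingerprint regions. Because curated FTIR libraries with per-molecule
functional-group labels are not freely redistributable, the pipeline is
validated end to end on synthetic spectra with planted characteristic bands,
where the ground truth of "which wavenumbers matter" is known by
construction.

## Input representation

All models consume absorbance spectra resampled onto one canonical uniform
grid: 3106 points spanning 650-3775 cm^-1 inclusive (spacing 3125/3105 ≈
1.0064 cm^-1). Raw CSV or JCAMP-DX input is sorted, duplicate wavenumbers
averaged, linearly interpolated onto the grid (constant extrapolation
outside the native range), and min-max normalized to [0, 1] per spectrum.
Min-max scaling was chosen over max-only scaling because it gives a bounded,
offset-free input regardless of baseline level; the original min/max are
kept in the metadata so the transform is invertible. A constant spectrum is
rejected rather than silently mapped to zeros: a zero vector would poison
training without any visible symptom. JCAMP files declared in transmittance
are converted by a = -log10(t) with t clipped to [1e-6, 1].

## Synthetic spectra

A virtual molecule is a set of functional groups plus a band list. Each
group plants one band per characteristic interval of a fourteen-group
literature band library (e.g. nitriles 2200-2280 cm^-1; nitro 1300-1390 and
1490-1570 cm^-1; phenols 3200-3700 cm^-1), with the band center uniform in
the interval. Bands are Gaussian A·exp(-(x-c)²/2w²) (75%) or Lorentzian
A·w²/((x-c)²+w²) (25%), amplitude U(0.3, 1.0), width U(8, 40) cm^-1 —
doubled for intervals wider than 200 cm^-1, which are broad O-H/N-H stretch
envelopes. Rendered spectra add 2-6 confounder bands (uniform centers), a
random quadratic baseline scaled to amplitude 0.15, i.i.d. Gaussian noise
(sd 0.01), and are then min-max normalized.

Datasets are class-balanced per target group (positive fraction 0.5,
exactly round(n/2) positives), mirroring the balanced 100-spectrum
evaluation sets the aggregation statistics assume; training sets default to
400 spectra. Negative molecules keep the target group's characteristic
intervals *clean*: no band center may come closer to a target interval than
4 widths (Gaussian) or 8 half-widths (Lorentzian), so tail leakage into the
target ranges is negligible and the classes are separable in principle —
the planted-band soundness property asserted in the tests. A
`hard_negatives` switch instead parks confounders 5-60 cm^-1 outside the
interval boundaries to study borderline misclassifications.

What this generator does *not* emulate: physically correct intensities,
band-shape systematics (Fermi resonances, rotational envelopes), correlated
instrument noise, ATR distortion, or realistic co-occurrence statistics of
functional groups. Passing tests therefore demonstrate that the
attribution and aggregation machinery recovers planted spectral evidence,
not that a NIST-trained classifier would behave identically.

## Classifier

Each classifier is independent and binary: a 1-D convolutional feature
extractor followed by Kolmogorov-Arnold (KAN) layers and a sigmoid. The
default stack is two conv blocks (8 then 16 channels, kernel 9, ReLU,
max-pool 8), flatten (48 positions × 16 channels), a KAN layer 768→16, and
a KAN layer 16→1. Every KAN edge carries a learnable univariate function
φ(u) = w_base·silu(u) + Σ_m c_m B_m(u), with cubic B-splines on a uniform
grid of 8 intervals over [-2, 2]; outputs are the sums of edge functions.
The B-spline basis uses the Cox-de Boor recursion; inside the network it is
evaluated by the local de Boor triangle (only order+1 functions are nonzero
at any point), which is what keeps CPU training and attribution fast. The
spline term sees inputs clamped to the domain (its gradient vanishes
outside); the base term is evaluated unclamped so gradient signal survives
saturation.

Total pooling is deliberately ×64 (≈65 cm^-1 per flattened position):
coarser stacks cannot localize a band near a characteristic-interval
boundary — absolute position survives pooling only through the flatten
index — and plateau below 90% held-out accuracy on the planted-band tasks.

Training: Adam (lr 1e-3), binary cross-entropy with logits, batch 32, 25
epochs, a stratified-by-shuffle 20% holdout for per-epoch accuracy, fully
seeded and reproducible. The decision is 1 iff probability ≥ threshold
(default 0.5); a tie at exactly the threshold counts positive — "rounding"
is ambiguous at 0.5 and the convention is documented rather than implicit.

The network is implemented in NumPy with explicit forward/backward passes,
so input gradients are exact (they match central finite differences to
≤1e-3 relative error in the tests) and the whole model has no framework
dependency.

## Attribution

Expected gradients estimates SHAP-style values

    φ_i = E_{b~background, α~U(0,1)} [(x_i - b_i) · ∂f/∂x_i(b + α(x - b))]

by Monte Carlo: each of n_samples draws picks a background spectrum and an
independent α. Defaults: n_samples 512, background = 100 training spectra
sampled with a fixed seed. The explained output f is the sigmoid
*probability* (a SHAP gradient explainer differentiates the model output it
is given; the logit is available as an option, and the two gradients differ
only by the factor p(1-p)). Per-spectrum seeds are derived as seed + the
spectrum's own index, so datasets can be partially recomputed and results
are invariant under input reordering.

The independent oracle is midpoint-rule integrated gradients with a single
baseline, φ_i = (x_i - b_i)·(1/m)Σ_k ∂f/∂x_i(b + α_k(x-b)), α_k=(k-½)/m.
For linear models both are exact; for the trained network the two
estimators agree within Monte-Carlo error, and the completeness identity
Σφ_i = f(x) - E_b f(b) is satisfied up to a gap that shrinks as 1/√n — both
are measured, not assumed.

## Aggregation

Range sums add signed attribution values (not absolute values — informative
absence must stay negative) over grid points inside characteristic
intervals, with half-open membership lo ≤ x < hi so adjacent literature
intervals such as the two ketone C=O ranges never double-count a point; an
interval reaching the grid end keeps the final point. S+ averages range
sums over positive-labeled spectra, S- over negatives. Pointwise, FA is the
positive-subset mean attribution, FB the *negated* negative-subset mean
(sign-flipped so that correctly-read absence of a band also appears as a
positive peak), FC = FA + FB exactly; per-point standard deviations are
computed within each subset (FB's on the flipped values, identical in
magnitude).

Fingerprint regions are extracted from FC by thresholding: maximal runs
with FC ≥ 0.25·max(FC), merged across gaps narrower than 15 cm^-1 and
discarded below that width, optionally restricted to a wavenumber window.
The threshold rule is this package's own — by eye, profiles like FC are
read off a plot; a reproducible artifact needs an explicit rule, and 25% of
the peak with a 15 cm^-1 minimum width tracks what visual inspection picks
out on the synthetic profiles.

## Verification protocol and problem sizes

The bundled study (scripts/acceptance.py) trains classifiers for alkane,
alkene and alkyne — three groups whose library ranges are mutually disjoint
and whose C-H/C=C-H/C#C-H stretch bands at 2850-2990, 3000-3100 and
3200-3310 cm^-1 are adjacent, the classic discrimination exercise — on 400
spectra each, explains balanced 100-spectrum test sets (n_samples 512,
background 100), and reports: held-out and test accuracy; S+/S- per group;
Jaccard overlap of extracted fingerprint intervals (2800-3400 cm^-1
window) with each group's own and the other groups' stretch bands;
closed-form recovery of w_i(x_i - mean b_i) on a linear surrogate (median
over 20 seeds at 4096 samples); the completeness-gap median across 20 seeds
as the sample count doubles 64→4096 plus its size at 4096 relative to
|f(x) - E f(b)| over 20 spectra; and the mean |EG - IG| against three
Monte-Carlo standard errors. These sizes run in roughly a quarter hour on
one CPU core and are the package's reference operating point; everything
scales up through the configs.

## Known limitations

- The synthetic generator's independence assumptions make the tasks easier
  than real group detection; accuracies here say nothing about NIST-scale
  accuracy.
- Attribution of the probability saturates for very confident predictions
  (gradients vanish); explaining the logit avoids this but changes the
  completeness reference values.
- Fingerprint extraction assumes FC has a meaningful positive maximum; for
  an untrained or failed classifier it returns an empty set with a warning.
- The KAN spline domain [-2, 2] clips extreme activations; inputs are
  min-max normalized so this is rare, but a model trained on unnormalized
  data would silently saturate.
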