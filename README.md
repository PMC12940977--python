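# ftirxai

Explainable functional-group classification of FTIR spectra.

Infrared spectroscopists decide whether a molecule carries a functional
group by looking for its characteristic absorption bands — a nitrile C≡N
stretch near 2200-2280 cm⁻¹, a phenolic O-H envelope at 3200-3700 cm⁻¹.
Neural classifiers can make the same call from the raw spectrum, but give
no reason. `ftirxai` closes that gap: it trains small **CNN-KAN binary
classifiers** (a 1-D convolutional front end followed by
Kolmogorov-Arnold layers with learnable B-spline edge functions) on
normalized absorbance spectra, and explains each decision with **expected
gradients**, the SHAP-style attribution

&nbsp;&nbsp;&nbsp;&nbsp;φᵢ = E₍b,α₎ [(xᵢ − bᵢ) · ∂f/∂xᵢ(b + α(x − b))],&nbsp;&nbsp; b ~ background, α ~ U(0,1),

which assigns one signed value per input wavenumber: positive values push
toward "group present", negative toward "absent", and Σφᵢ ≈ f(x) − E f(b)
(completeness). Attributions are aggregated into the quantities a
spectroscopist can check against band-assignment tables:

- **range sums** — signed attribution mass inside a group's literature
  characteristic interval(s), per spectrum;
- **S⁺ / S⁻** — range sums averaged over the positive / negative half of a
  balanced test set;
- **FA / FB / FC profiles** — pointwise mean attribution over spectra with
  the group (FA), the sign-flipped mean over spectra without it (FB), and
  FC = FA + FB, whose peaks mark the wavenumber regions the classifier
  actually relies on;
- **fingerprint regions** — intervals extracted from FC by thresholding,
  with Jaccard overlap against literature ranges;
- red/blue/gray **explanation plots** and structured error reports for
  misclassified spectra.

Everything is validated end to end on synthetic spectra with planted
characteristic bands (a 14-group band library, confounder bands, baseline,
noise), where ground truth about "which wavenumbers matter" is known by
construction. See `docs/methods.md` for the model, the generator and the
numerical choices.

## Worked example

```python
import numpy as np
from ftirxai import (SimulationConfig, ModelConfig, generate_dataset,
                     build_model, train_classifier, BackgroundSet,
                     explain_dataset, group_statistics, DEFAULT_LIBRARY)

train = generate_dataset(config=SimulationConfig(seed=1, n_spectra=400,
                                                 target_group="nitriles"))
test = generate_dataset(config=SimulationConfig(seed=2, n_spectra=100,
                                                target_group="nitriles"))

cfg = ModelConfig(seed=1)
model, log = train_classifier(build_model(cfg, "nitriles"), train, cfg)
print(f"holdout accuracy {log[-1]['holdout_accuracy']:.3f}")

background = BackgroundSet.sample_from(train, size=100, seed=1)
attrs = explain_dataset(model, [s for s, _ in test], background,
                        n_samples=512, seed=3)
labels = [lbl for _, lbl in test]
stats = group_statistics(attrs, labels, DEFAULT_LIBRARY["nitriles"])
print(f"S+ = {stats.S_plus:+.3f}   S- = {stats.S_minus:+.3f}")
```

prints (≈30 s training, ≈2 min attribution on one CPU):

```
holdout accuracy 0.963
S+ = +0.357   S- = -0.407
```

The classifier reached 96% held-out accuracy, and the attribution mass in
the nitrile characteristic range 2200-2280 cm⁻¹ is positive for spectra of
molecules that contain the group and negative for those that do not — the
model is reading the band a chemist would read.

The same study runs from the shell:

```
ftirxai pipeline --workdir out --seed 0
```

which simulates, trains, explains and analyzes the bundled three-group
configuration (nitriles / nitro / phenols) and writes per-group summaries,
FA/FB/FC profile tables, fingerprint intervals and explanation plots under
`out/`.

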