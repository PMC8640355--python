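# ramanembryo

Chemometrics pipeline for **non-invasive embryo viability screening** from
Raman spectra of spent day-3 embryo culture medium.

In IVF, an embryo's metabolism subtly alters the microdrop of culture
medium it grows in. Raman spectroscopy of the dried spent medium therefore
carries a metabolic fingerprint of the embryo — without touching the embryo
itself. This package implements the full analysis used to ask whether that
fingerprint predicts which day-3 cleavage-stage embryos will develop to the
blastocyst stage:

* **preprocessing** — asymmetric-least-squares fluorescence baseline
  removal, cubic B-spline resampling onto the integer 1 cm⁻¹ grid
  [200, 2000], vector normalization (‖x‖₂ = 1), subtraction of the
  medium-only background spectrum, and extraction of the biological
  fingerprint region 600–1800 cm⁻¹ (1201 features per spectrum);
* **exploration** — group mean ± SD spectra, characteristic-peak counting,
  and three-component PCA with a sample-level permutation test for group
  separation;
* **classification** — a multilayer perceptron (1201 → 64 → 64 → 2, ReLU,
  cross-entropy, Adam) trained on a sample-level split (30 + 30 samples,
  i.e. 300 spectra) with 10-fold sample-stratified cross-validation and
  early stopping, evaluated at the *sample* level by majority vote over
  each sample's five replicate spectra (sensitivity = non-blastula recall,
  specificity = blastula recall);
* **band screening** — two-class LDA with covariance shrinkage on all
  spectra; wavenumbers whose z-scored LD1 coefficient magnitude exceeds 3
  are merged into differential bands and annotated against an embedded
  literature lookup (ribose/RNA at 863.5 cm⁻¹, aromatic ring breathing at
  1008 cm⁻¹, amide I at 1632 cm⁻¹, …);
* **synthetic data** — a seeded generator producing studies with the same
  statistical structure (80 blastula + 48 non-blastula samples × 5
  coffee-ring replicates = 640 spectra, 29 shared peaks on a fluorescence
  baseline, small group effects at eight differential Raman shifts), so the
  whole pipeline is testable without any instrument data.

## Worked example

```python
from ramanembryo import *

config = SimConfig(seed=2021)                  # the default synthetic study
dataset = generate_dataset(config)             # 640 spectra + medium background
features = preprocess_dataset(dataset)         # 640 x 1201 fingerprint matrix

split = split_dataset(features, n_per_group=30, seed=1)
model = train_mlp(features, split, MLPConfig(seed=1))
cm, report, _ = evaluate_model(model, features, split)
print(cm.counts)         # [[16  2]
                         #  [ 0 50]]
print(report)            # MetricsReport(sensitivity=88.89, specificity=100.0,
                         #               accuracy=97.06)

bands = select_bands(fit_lda(features))
print([b.apex for b in bands])
# [864.0, 960.0, 1007.0, 1104.0, 1199.0, 1359.0, 1408.0, 1632.0]
for a in annotate_bands(bands)[:2]:
    print(a.raman_shift, a.chemical_bond, a.substrate)
# 863.5 Ribose vibration RNA
# 959.5 Symmetric stretching vibration of v_1-PO^3-_4 ... Phosphate of HA cholesterol
```

The confusion matrix counts test *samples* (18 non-blastula + 50 blastula
held out); sensitivity/specificity/accuracy are percentages at the sample
level. The screened band apexes fall within a few cm⁻¹ of the eight
differential centres embedded by the generator.

The same pipeline is available from the shell:

```sh
ramanembryo simulate  --out data/ --seed 2021
ramanembryo preprocess --in data/ --out features.csv
ramanembryo explore   --features features.csv --out explore/
ramanembryo train     --features features.csv --out model/ --seed 1
ramanembryo evaluate  --model model/ --features features.csv --out metrics.json
ramanembryo screen    --features features.csv --out bands.csv
ramanembryo report    --metrics metrics.json --bands bands.csv --out report.json
```

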