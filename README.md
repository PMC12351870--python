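# breedcomp

Genomic breed composition (GBC) prediction and purebred/hybrid calling from
SNP genotypes.

Breeding programs need to verify that an animal sold or registered as a
purebred really is one, and to flag first-generation crosses (F1 hybrids),
whose genomes are deliberately close to both parental purebreds. `breedcomp`
implements a breed-identification strategy built for exactly this hard case:
instead of classifying animals into discrete breed labels, it predicts each
animal's **ancestry-proportion vector** over a panel of reference purebreds
and thresholds that vector to make the call.

## The method

For K reference breeds, every animal gets a GBC vector
q = (q_1, …, q_K) with q_k ≥ 0 and Σ q_k = 1. Training targets are exact
compositions — a purebred Duroc is [0, 0, 1], an F1 Yorkshire × Landrace is
[0.50, 0.50, 0.0] — and the model is trained as a **multi-output regression
under mean-squared-error loss**, not as a classifier under cross-entropy.
The primary backend is a multi-layer perceptron with three hidden layers
(1024-512-256, ReLU) and a softmax output, so every prediction lies on the
probability simplex by construction. An animal is called purebred of its
top breed when max_k q_k strictly exceeds a determination threshold θ
(default 0.75, scan grid 0.60–0.90), and hybrid otherwise.

Also included, behind the same predict-GBC contract: random-forest and
support-vector-regression backends (clip-and-renormalise to the simplex),
classification-framework ablations of all three ("-CLA"), and a supervised
maximum-likelihood ancestry estimator (EM on the binomial admixture
likelihood, with breed allele frequencies taken from labelled purebreds).

Because no public genotypes exist for the motivating pig cohorts, the
package ships a Balding–Nichols multi-breed simulator (divergence F per
breed, HWE within breed, F1 and arbitrary crosses, per-SNP missingness)
that defines the synthetic study used by every test: three breeds at
F = 0.15 over 1,000 SNPs, 300 purebreds/breed + 150 F1s for training, and
an independent test population of 100/breed + 100 F1s from the same breed
frequencies. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from breedcomp import (
    MLPGBCRegressor, QCThresholds, apply_qc, call_breeds, evaluate,
)
from breedcomp.experiments import intersect_panels, prepare_dataset
from breedcomp.simulate import SimConfig, sample_population_pair

cfg = SimConfig(seed=1)                      # the default 3-breed study
(g1, t1), (g2, t2), _ = sample_population_pair(cfg)

train = prepare_dataset(g1, t1, cfg.breeds)  # QC -> impute -> one-hot
g1_qc, report = apply_qc(g1)
print(f"QC: {report.n_surviving}/{report.n_input_snps} SNPs survive")

g1_al, g2_al = intersect_panels(g1_qc, g2)
test = prepare_dataset(g2_al, t2, cfg.breeds, qc=QCThresholds(0, 0, 0))

model = MLPGBCRegressor(breeds=cfg.breeds, random_state=2)
model.fit(train.X, train.targets())
pred = model.predict(test.X)

calls = call_breeds(pred, list(cfg.breeds), test.truth["sample_id"].tolist())
res = evaluate(calls, test.truth, threshold=0.75)
print("per-category accuracy:", res.accuracy)

f1 = pred[(test.truth["category"] == "hybrid").to_numpy()]
print("mean F1 prediction:", np.round(f1.mean(axis=0), 3))
```

prints

```
QC: 794/1000 SNPs survive
per-category accuracy: {'Duroc': 1.0, 'Landrace': 1.0, 'Yorkshire': 1.0, 'hybrid': 1.0}
mean F1 prediction: [0.495 0.495 0.01 ]
```

The QC line shows the three per-SNP filters (call rate ≥ 0.90, MAF ≥ 0.05,
HWE exact P ≥ 10⁻⁶) at work — pooling diverged breeds deflates
heterozygosity, so the HWE filter bites. Every test animal, including all
100 F1 hybrids, is called correctly at θ = 0.75, and the average F1
prediction sits at the expected [0.5, 0.5, ~0] composition.

The same pipeline is scriptable end to end:

```
breedcomp simulate --config sim.yaml --out fx/
breedcomp qc --bfile fx/pop1
breedcomp train --bfile fx/pop1.qc --labels fx/pop1.truth.tsv --model-dir model/
breedcomp predict --model-dir model/ --bfile fx/pop2 --out preds.tsv
breedcomp call --gbc preds.tsv --threshold 0.75 --out calls.tsv
breedcomp scan --gbc preds.tsv --truth fx/pop2.truth.tsv --out scan.tsv
```

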