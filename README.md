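# ltcvol

Linear tensor coding for statistical texture modeling and classification of
medical volumes.

`ltcvol` is for researchers working with small ensembles of co-registered,
shape-normalized intensity volumes (e.g. tens of CT organ volumes, each a
dense 3rd-order tensor of voxel values) who need a compact statistical
texture model: reconstruction from few coefficients, synthesis of plausible
novel volumes, and two-class discrimination (e.g. normal vs abnormal
organs) with interpretable, per-basis features.

## The model

Each volume `A_i` in an ensemble of M samples is written as a linear
combination of shared unit-norm **rank-one basis tensors** around the mean
texture `ℳ`:

    A_i = ℳ + Σ_j c_{i,j} · B_j + residual_i,
    B_j = u_j^(1) ∘ u_j^(2) ∘ u_j^(3)   (outer product, unit factors).

Bases are extracted greedily: the best shared rank-one direction of the
current residuals — the rank-(1,1,1) case of GND-PCA (generalized
N-dimensional PCA, alternating per-mode eigen-subspace fitting) — is
materialized as a basis, each sample receives one coefficient
`c = ⟨residual, B⟩`, the residuals are deflated by `c · B`, and the loop
repeats until the summed residual norm falls below a threshold `r` or a
basis budget is reached. With one basis the coding *is* rank-(1,1,1)
GND-PCA; GND-PCA at general core ranks is included as the baseline.

On top of the coding:

- **Texture model** — coefficients are modeled as Gaussian per basis
  (mean `m_k`, std `λ_k`); sweeping one coefficient within `±2λ_k`
  synthesizes novel volumes that vary along a single basis.
- **Basis selection** — each basis is scored by the point-biserial
  (Pearson) correlation between its coefficient column and the ±1 labels,
  and ranked by |r|.
- **Classification** — leave-one-out cross-validation with a linear SVM or
  KNN on all, or only the selected, coefficients.
- **Synthetic ensembles** — a seeded generator planting orthogonal
  rank-one structure, a decaying coefficient spectrum, class-linked bases
  and voxel noise, with ground truth returned for recovery tests.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
import numpy as np
import ltcvol as lv

# synthetic two-group ensemble: 20 volumes of 16x16x8 voxels, five shared
# variation bases with a decaying spectrum, one class-linked basis, noise
ens = lv.generate(lv.SynthSpec(mean_level=0.0, mean_amplitude=5.0, seed=0))

# greedy coding: 8 unit-norm rank-one bases + per-sample coefficients
model = lv.fit_ltc(ens.samples, max_bases=8)
print("bases extracted:", model.n_bases)
print("summed residual norm:", [round(v, 1) for v in model.residual_trace])

# reconstruction fidelity vs number of bases
curve = lv.reconstruction_quality(model, ens.samples, [0, 2, 4, 8])
print("normalized correlation at 0/2/4/8 bases:", np.round(curve, 3))

# rank bases by label correlation, classify on the selected coefficients
lc = lv.LabeledCoefficients(model.coefficients, ens.labels)
sel = lv.select_bases(lc, 2)
print("basis ranking by |r|:", sel.ranking)
print("correlations       :", np.round(sel.correlations[sel.ranking], 3))
acc, _ = lv.loo_classify(model.coefficients[:, sel.selected], ens.labels,
                         classifier="svm")
print("LOO accuracy, top-2 selected bases, linear SVM:", acc)
```

Output:

```
bases extracted: 8
summed residual norm: [243.8, 191.1, 153.4, 115.7, 101.6, 90.0, 88.1, 87.9, 87.7]
normalized correlation at 0/2/4/8 bases: [0.975 0.99  0.996 0.997]
basis ranking by |r|: [5 1 7 3 0 2 4 6]
correlations       : [-0.956  0.255 -0.243  0.225  0.216  0.212 -0.048 -0.034]
LOO accuracy, top-2 selected bases, linear SVM: 1.0
```

Reading this: the residual trace drops monotonically as bases are
extracted (it cannot increase — each deflation removes the fitted
component along a unit direction), and the reconstruction correlation
climbs toward 1. Basis 5 is the fitted counterpart of the planted
class-linked basis: its coefficient column correlates at |r| = 0.956 with
the group labels while nuisance bases sit near zero, so the selection
ranks it first and the classifier separates the groups perfectly from two
features.

The same pipeline is available from the shell:

```sh
ltcvol synth --shape 16,16,8 --n 20 --seed 0 --out data.npz
ltcvol fit-ltc --input data.npz --max-bases 8 --out model.npz
ltcvol select --model model.npz --input data.npz --labels data.labels.csv \
              --k 2 --out selection.csv
ltcvol classify --input data.npz --labels data.labels.csv \
                --method ltc_selected --select-k 2 --max-bases 8 \
                --fold-mode pooled --out report.csv
```

Runs are deterministic given `--seed`, and model archives written from
identical invocations are bitwise identical.

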