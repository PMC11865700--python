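# coopernet

Cooperative penalized Cox regression for variable selection with competing
risks.

## The problem

In high-dimensional survival settings (gene expression, other omics) with
two competing event types, the standard approach fits one cause-specific
penalized Cox model per event, treating the competing event as censored.
Each model then selects variables on its own, ignoring that the two events
may share biology: a gene that drives both hazards has to clear the lasso
threshold twice, independently, and effects on a rare event are easily
shrunk to zero.

`coopernet` implements **CooPeR** (cooperative penalized regression): two
cause-specific feature-weighted Cox elastic nets that iteratively exchange
coefficient magnitudes as prior information. The model for cause k
minimizes

```
(1/n) · NLL(β) + λ Σⱼ wⱼ(θ) ( α|βⱼ| + (1−α)/2 βⱼ² ),
wⱼ(θ) = Σₗ exp(zₗθ) / ( p · exp(zⱼθ) ),
```

where `NLL` is the negative log Cox partial likelihood (Breslow convention
for ties), `z` is a vector of nonnegative relevance scores and `θ` a scalar
learned from the data (`θ = 0` recovers the plain elastic net; the weights
always satisfy `Σⱼ 1/wⱼ = p`). The cooperative algorithm:

1. Initialize both cause-specific models at their cross-validated plain
   elastic-net solutions (`lambda.min`).
2. Repeat until `‖βₖ⁽ʲ⁾ − βₖ⁽ʲ⁻¹⁾‖₂ < ε` for both causes or `mt_max_iter`
   rounds: refit cause 2 with `z = |β₁|`, then cause 1 with `z = |β₂|`,
   each by cross-validated feature-weighted elastic net.

Coefficients shrunk to zero in one model raise the penalty on the same
feature in the other model, so shared effects are amplified and noise is
suppressed in both models. Without shared effects the procedure behaves
like two ordinary Coxnet fits.

The package also ships the simulation designs used to study the method (a
high-dimensional block-correlated genomics design and a low-dimensional
four-scenario proof of concept) and a replicated variable-selection
benchmark (per-block PPV/FPR/TPR/F1).

## Worked example

Simulate one replicate of the high-dimensional design (n = 400, p = 5000;
blocks B1/B2 carry four effects each shared between the causes, B3.1/B3.2
carry cause-specific effects, the rest is noise) and fit CooPeR:

```sh
coopernet simulate --design highdim --n 400 --seed 7 --out demo.csv --truth demo_truth.json
# wrote demo.csv: n=400 p=5000 status counts {0: 115, 1: 132, 2: 153}

coopernet fit --input demo.csv --mt-max-iter 3 --alpha 1.0 --nfolds 10 --seed 7 --out demo_fit.json
# wrote demo_fit.json: shared selection ['B1_1', 'B1_2', 'B1_3', 'B1_4',
#   'B2_251', 'B2_252', 'B2_253', 'B2_254', 'B3.1_501', 'B3.1_504',
#   'B3.2_752', 'B3.2_754']
```

The shared-selection set (features nonzero in both cause-specific models)
recovers exactly the eight truly shared effects (`B1_1..4`, `B2_251..254`).
Inside `demo_fit.json`, the cooperative fits are much sparser than their
plain elastic-net initializations (cause 1: 25 vs 55 nonzero coefficients,
cause 2: 15 vs 71) with learned score weights `θ ≈ 5.9` — the fits lean on
each other's coefficients. The initial fits are the Coxnet baseline and
stay available via `coefficients_initial` / `use_initial_fit`.

The same functionality is available as a library:

```python
from coopernet import CooperConfig, PenaltyConfig, fit_cooper, read_survival_csv

data = read_survival_csv("demo.csv")          # columns: time, status, features...
fit = fit_cooper(data, CooperConfig(mt_max_iter=3,
                                    penalty=PenaltyConfig(alpha=1.0, nfolds=10),
                                    seed=7))
fit.fit_cause1.nonzero()                      # sparse cooperative coefficients
fit.initial_fit_cause1.nonzero()              # Coxnet baseline
```

`coopernet benchmark --replicates 10 --seed 0 --out results.csv` scores
CooPeR against its Coxnet initialization over replicated simulations and
writes per-replicate and aggregated (median/IQR) selection metrics.

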