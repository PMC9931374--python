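# ihas

Inference of **integrated hierarchical association structures** from
multi-omics cohorts: a tested re-implementation of a pipeline that ties
together probabilistic quantization of heterogeneous omics data,
exponential-family association models of gene expression, joint
biclustering of association modules and samples, pan-cancer aggregation of
the resulting structure, random-walk network diffusion, and alignment with
clinical phenotypes and survival — exercised end-to-end on synthetic
cohorts with planted ground truth.

## Who this is for

Computational biologists who want a working, inspectable implementation of
the hierarchical association machinery — from raw omics matrices to Sample
Groups, Gene Groups and Artery Networks — without needing access to a
consortium-scale dataset.  Every stage can be driven by the built-in
synthetic-data generator, which plants known effectors, modules, sample
groups, survival structure and network paths, so each inference step has a
measurable recovery target.

## The model

The expression state of a target gene, y in {-1, 0, +1} (down / unchanged
/ up), is tied to the states x_i of its effector alterations (CNV,
mutation, DNA methylation, microRNA, phosphoprotein, SNP) through an
exponential-family conditional law

```
p(y | x) = exp( sum_i  lambda_i f_i(x_i) y ) / Z(f(x)),     lambda_i >= 0,
```

where f_i is the effector's feature function (signed by the association
direction: x_i for additive effects, a non-silent indicator for mutations,
allele dosage for SNPs) and Z the trinary normalizer.  Continuous
measurements enter as *posterior probabilities* of the hidden states
(probabilistic quantization on within-feature CDF values), so fitting
maximizes the expected log-likelihood under those posteriors — a concave
problem solved with bound-constrained Newton / quasi-Newton steps.

Model building screens all (effector, target) pairs with an
FDR-calibrated log-likelihood-ratio threshold, ranks surviving candidates
by interaction-network distance then effector type, and accepts a
candidate only when the augmented model beats both the current model and
the candidate-alone model in chi-square *and* permutation nested tests.
Models are grouped into Association Modules (one effector + direction, 11
realizable type classes), modules and samples are jointly partitioned into
Super Modules and Sample Groups by recursive spectral sorting plus
multiscale boundary detection, and cross-cohort aggregation yields Super
Module Groups, Gene Groups, Meta Gene Groups, Recurrent Effectors and the
diffusion-weighted Artery Network.  Clinical and survival alignment uses
concentration coefficients with permutation baselines, per-gene Cox
coefficients, the p_diff distribution-deviation statistic and Kaplan-Meier
log-rank tests.

## Worked example

Recover three planted effectors (association strength lambda = 1.5,
alteration rate 0.25) from among five decoys at n = 500 samples:

```python
import numpy as np
from ihas import assoc, synthetic

exp = synthetic.planted_target_experiment(
    n_samples=500, n_true=3, n_decoys=5, lam=1.5, seed=0
)
effectors = [assoc.Effector(eid, "mutation", "+", p)
             for eid, p in exp.effector_probs.items()]
screened = []
for eff in effectors:
    res = assoc.pairwise_association(eff, "target", exp.target_probs)
    print(f"{eff.eid}: llr={res.llr:6.2f}  chi2_p={res.chi2_p:.2e}")
    if res.chi2_p <= 0.05:
        screened.append(
            (assoc.Effector(eff.eid, eff.ftype, res.direction, eff.probs), res.llr)
        )
ranking = assoc.prioritize_effectors("target", screened, None)
model = assoc.stepwise_build_model(
    "target", exp.target_probs, ranking,
    alpha=0.05, n_permutations=200, rng=np.random.default_rng(0),
)
print("selected:", [e.eid for e in model.effectors])
print("weights: ", np.round(model.lambdas, 3))
print("true:    ", exp.true_effectors)
```

prints

```
mut_0: llr= 18.99  chi2_p=1.31e-05
mut_1: llr= 20.23  chi2_p=6.88e-06
mut_2: llr= 14.40  chi2_p=1.48e-04
mut_3: llr=  0.82  chi2_p=3.65e-01
mut_4: llr=  0.25  chi2_p=6.20e-01
mut_5: llr=  0.05  chi2_p=8.32e-01
mut_6: llr=  1.30  chi2_p=2.55e-01
mut_7: llr=  0.22  chi2_p=6.43e-01
selected: ['mut_1', 'mut_0', 'mut_2']
weights:  [0.374 0.375 0.251]
true:     ['mut_0', 'mut_1', 'mut_2']
```

The three planted effectors stand far above the decoys in the pairwise
screen and are exactly the ones the stepwise loop accepts.  The fitted
weights are attenuated relative to the generating lambda = 1.5 because
both the target and the effectors are observed only through noisy
emissions and rank-based quantization posteriors; recovery of the *set*
of effectors, not of the raw weights, is the inference target.

A complete end-to-end run on a two-cohort synthetic study (simulate →
quantize → associate → supermodules → pancancer → artery →
clinical/survival → cross-cohort validation) is one command:

```bash
ihas demo --out demo_run --seed 1
```

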