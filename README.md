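# mixgpcm

Mixture generalized partial credit models for response-style analysis of
polytomous rating-scale data.

People do not all use a rating scale the same way: some spread their answers
across every category (*ordinary* response style, ORS), some gravitate to
the endpoints (*extreme*, ERS), some live inside a narrow band of preferred
categories (*range*, RRS). Such styles distort sum scores, reliability and
criterion correlations. `mixgpcm` is for survey methodologists and
psychometricians who want to detect and quantify these styles with a
restrictive mixed generalized partial credit model (rmGPCM) — a finite
mixture of adjacent-category IRT models

P<sub>vix</sub>(θ) = Σ<sub>g</sub> π<sub>g</sub> ·
exp[Σ<sub>s=0</sub><sup>x</sup> δ<sub>i</sub>(θ<sub>vg</sub> − τ<sub>isg</sub>)] /
Σ<sub>c=0</sub><sup>m</sup> exp[Σ<sub>s=0</sub><sup>c</sup> δ<sub>i</sub>(θ<sub>vg</sub> − τ<sub>isg</sub>)]

with class-specific thresholds τ<sub>isg</sub>, shared discriminations
δ<sub>i</sub> (δ<sub>1</sub> = 1), class-specific trait variances, and
mixing weights π<sub>g</sub>. Around the model the package provides the full
analysis pipeline of a rating-scale study: sample-size-adjusted BIC model
selection, parametric-bootstrap Pearson / Cressie–Read fit, disordered-
threshold diagnostics with heuristic style labels, careless-responder
screening, paired McNemar / odds-ratio comparisons of style membership,
Spearman criterion correlations with Fisher-z comparisons, McDonald's ω, and
a synthetic-data generator with planted styles for end-to-end validation.
See `docs/methods.md` for the model, estimation and design details.

## Worked example

Simulate a three-class (ORS/ERS/RRS) four-point-scale dataset, fit one to
three classes, select by saBIC, and inspect the winner:

```python
from mixgpcm import MixedGPCM, EstimationOptions, SyntheticDesign, simulate_responses
from mixgpcm.selection import FitStatistics, select_best_model
from mixgpcm.diagnostics import profile_classes

design = SyntheticDesign(n_persons=1200, n_categories=4, seed=3)
sim = simulate_responses(design)
opts = EstimationOptions(n_starts=3, burnin_iterations=30,
                         n_quadrature_nodes=21, max_em_iterations=400, seed=1)
stats, results = [], {}
for G in (1, 2, 3):
    res = MixedGPCM(sim.responses, n_classes=G).fit(opts)
    results[G] = res
    stats.append(FitStatistics(n_classes=G, ll=res.log_likelihood,
                               n_parameters=res.n_parameters, n_persons=1200))
best = stats[select_best_model(stats)].n_classes
res = results[best]
print(res.summary())
```

Output:

```
G=1: LL= -10389.3  N_par= 32  saBIC= 20903.8
G=2: LL= -10268.8  N_par= 58  saBIC= 20764.6
G=3: LL= -10216.7  N_par= 84  saBIC= 20762.2
selected: 3 classes

Mixed GPCM results
==================
classes: 3   items: 8   categories: 4
persons: 1200   parameters: 84
log-likelihood: -10216.71   converged: True (178 EM iterations)

       estimated_size  modal_share  mean_assignment_probability
class
1               0.484        0.463                        0.806
2               0.280        0.277                        0.770
3               0.236        0.260                        0.705

discriminations: [1.    1.105 0.875 0.879 0.949 0.652 1.368 0.817]
trait SDs:       [0.968 1.264 0.905]

class 1: ORS  (extreme coverage 0.18, disorder 0.0%)
class 2: ERS  (extreme coverage 0.85, disorder 20.8%)
class 3: RRS  (extreme coverage 0.18, disorder 29.2%)
model-based reliability: 0.699
```

Reading this: saBIC drops from the one-class to the three-class model and
the three-class solution wins (20762.2 < 20764.6 < 20903.8), recovering the
generating structure. The class sizes (48/28/24%) approximate the planted
55/26/19% at this moderate N; mean assignment probabilities around 0.7–0.8
say class membership is decided with reasonable confidence. The style
labels come with their numeric evidence: class 2's extreme categories are
modal over 85% of its central trait range (ERS), class 3 concentrates on
upper non-extreme categories with 29% disordered thresholds (RRS). The
model-based reliability (0.70) is the share of EAP-score variance that is
signal rather than posterior uncertainty.

The same pipeline is scriptable from the shell
(`mixgpcm simulate | fit | select | gof | diagnose | compare | omega |
run-study`); `mixgpcm run-study --config demo.yaml` writes a JSON report
with every table analog, stamped with version, config hash and seed.

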