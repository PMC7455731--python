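# ccsatlas

Unified collision cross-section (CCS) databases, machine-learning CCS
prediction, and multi-dimensional metabolite annotation for ion
mobility–mass spectrometry (IM–MS).

## The problem

The collision cross-section — the rotationally averaged area (Å²)
governing how fast an ion drifts through a buffer gas — is a
physicochemical identifier orthogonal to m/z, and IM–MS instruments
measure it routinely. Two obstacles keep CCS from being used at scale in
metabolite annotation: published experimental values disagree across
instruments (drift tube DTIM, traveling wave TWIM, trapped TIMS) and
labs, and most compounds have no measured value at all. `ccsatlas` is a
toolkit for analysts building CCS resources and annotation pipelines; it
provides:

* **Unification** — a five-step standardization of heterogeneous CCS
  records (quality check at 10 ppm, intra-dataset 0.5% consistency rule,
  power-law trend-line outlier removal at the 99% prediction interval,
  DTIM-priority averaging, confidence levels 1/2/3/Conflict).
* **Prediction** — an RBF-kernel support vector regression on selected
  molecular descriptors (LASSO-driven RFECV selection), tuned on a
  7 × 15 grid of C ∈ {0.001…0.5}/N_MD and γ ∈ {2¹…2¹⁵}, with the
  *representative structure similarity* (RSS) — the mean of the top five
  tanimoto coefficients against the training set — attached to every
  prediction as a reliability estimate (small ≤ 0.6 < medium ≤ 0.8 <
  large). Predicted values carry confidence level 4.
* **Annotation** — candidate retrieval at 25 ppm, a trapezoidal CCS
  match score (full score below Δ = 2%, zero beyond 4%, where
  Δ = |CCS_cand − CCS_exp|/CCS_exp × 100), a reverse dot-product MS/MS
  score over reference-library peaks, and the weighted fusion
  S = 0.3·S_ccs + 0.7·S_MS/MS with dense candidate ranking.
* **Simulation** — seeded synthetic multi-lab studies (real structures,
  power-law CCS ground truth, injected lab biases and outliers, toy
  spectra, decoy databases) so the whole stack is testable offline.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
from ccsatlas.simulate import SimulationConfig, simulate_library, simulate_records
from ccsatlas.unify import unify_pipeline
from ccsatlas.ccsmodel import CCSPredictor

cfg = SimulationConfig(n_compounds=60, seed=42)
compounds, truth = simulate_library(cfg)
records = simulate_records(truth, cfg)

unified, removals = unify_pipeline(records, compounds)
print(f"{len(records)} records -> {len(unified)} unified values; {len(removals)} removed")

train = unified[(unified.level != "Conflict") & (unified.polarity == "+")]
train = train.rename(columns={"unified_ccs": "ccs"})[["compound_id", "adduct", "ccs"]]
results = CCSPredictor(compounds, train, "+").fit(C=0.5, gamma=4.0)
print(results.summary())

rec = results.predict("Oc1ccc2oc(=O)ccc2c1", "[M+H]+", "6-hydroxycoumarin")
print(f"predicted CCS {rec.ccs:.1f} A^2, RSS {rec.rss:.4f} ({rec.rss_group}), level {rec.level}")
```

prints

```
3037 records -> 420 unified values; 45 removed
CCS prediction model (RBF support vector regression)
========================================================
polarity            +
training instances  240
descriptors (N_MD)  15
adducts             [M+H]+, [M+Na]+, [M+NH4]+, [M+H-H2O]+
C                   0.5
gamma               4
epsilon (std y)     0.01
training MRE        0.65 %
training ARE        1.35 %
training R^2        0.9934
fingerprint scheme  rdkit-path/d7/1024
predicted values are confidence level 4
predicted CCS 115.2 A^2, RSS 0.3639 (small), level 4
```

3037 simulated multi-lab records collapse into 420 consensus values
(45 faulty records caught on the way); the fitted positive-mode model
reproduces its training CCS to a 0.65% median relative error; and the
query prediction arrives with a *small* RSS — the structure sits far from
this (deliberately small) training set, so the predicted 115.2 Å² should
be trusted less than a large-RSS prediction would be.

The same workflow is scriptable from the shell:

```bash
ccs-atlas simulate --seed 42 --n-compounds 60 --outdir fixtures/
ccs-atlas unify --records fixtures/records.tsv --compounds fixtures/compounds.tsv \
                --out unified.tsv --report removals.tsv
ccs-atlas train --train train.tsv --compounds fixtures/compounds.tsv --tune --out model.bin
ccs-atlas predict --model model.bin --input queries.tsv --adducts "[M+H]+" --out pred.tsv
ccs-atlas annotate --features peaks.tsv --db candidates.tsv --mode pos \
                   --out annotations.tsv --stage-report stages.tsv
```

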