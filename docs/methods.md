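# Methods

`ccsatlas` implements the computational core of a unified collision
cross-section (CCS) atlas for ion mobility–mass spectrometry (IM–MS)
metabolomics: standardization of heterogeneous experimental CCS records,
machine-learning CCS prediction with a structure-similarity reliability
score, and multi-dimensional (m/z + CCS + MS/MS) metabolite annotation.
This note records the model assumptions, the tunable parameters and their
defaults, and the design choices made where the procedure was genuinely
open.

## Adducts and mass arithmetic

Adduct shifts are net ion shifts in Da with the electron mass folded in,
so `[M+H]+` is exactly one proton (1.00727646688 Da) and `[M+H]+` /
`[M-H]-` are sign-symmetric. The shipped whitelist holds nine positive
and six negative singly charged electrospray adducts; the seven flagged
`training` ones (`[M+H]+`, `[M+Na]+`, `[M+NH4]+`, `[M+H-H2O]+`,
`[M-H]-`, `[M+Na-2H]-`, `[M+HCOO]-`) are the set retained for model
training. The table is data (`data/adducts.tsv`) and can be replaced
wholesale via `load_adducts`. Mass errors are reported in ppm,
`|obs − theo| / theo × 1e6`.

## Record unification

Experimental CCS records from independent datasets, labs and instrument
families (drift tube DTIM, traveling wave TWIM, trapped TIMS) are
standardized in five steps:

1. **Quality check** — records lacking a parseable structure, carrying a
   non-whitelisted adduct, or (when a measured m/z is reported) deviating
   more than 10 ppm from the theoretical adduct m/z are removed.
2. **Intra-dataset consistency** — replicates of one ion within one
   dataset are averaged when their maximum difference is ≤ 0.5%, and all
   removed otherwise. "Maximum difference" is `(max − min)/mean × 100`
   throughout; the mean denominator is symmetric and matches the
   replicate-consistency use.
3. **Trend-line outlier removal** — per (chemical superclass, polarity)
   with ≥ 10 records, `CCS = a·(m/z)^b` is fitted by ordinary least
   squares on log–log axes and records outside the two-sided 99%
   prediction interval (`t`-based, `s·sqrt(1 + 1/n + (x−x̄)²/Sxx)`) are
   dropped. The x-axis is the theoretical ion m/z. A numerically perfect
   fit (residual variance < 1e-20 on the log scale) removes nothing.
   Grouping per (superclass, polarity) rather than per adduct is a
   configuration default; classes below the size floor are passed
   through untouched.
4. **Unified value** — per (compound, adduct): the mean of DTIM records
   when any exist, otherwise the mean of all platforms. Means are
   unweighted (no dataset-size weighting).
5. **Confidence levels** — an ordered cascade over
   (number of datasets, number of DTIM datasets, maximum difference):
   Level 1 requires ≥ 2 DTIM datasets within 1%; Level 2 requires ≥ 2
   datasets (any commercial instruments) within 3%; ≥ 2 datasets beyond
   3% is Conflict; a single dataset is Level 3. The maximum difference
   is computed over all platform records of the group, so the cascade is
   a total, deterministic function of one tuple; ≥ 2 DTIM datasets with
   a difference in (1%, 3%] fall through to Level 2. "Independent
   datasets" means distinct dataset identifiers, not distinct labs.
   Level 4 is reserved for predicted values.

Every input record ends in exactly one unified value's source list or
one removal-report row (record conservation), which the tests enforce.

## Molecular descriptors

Descriptors come from RDKit's 2-D catalogue (~210 descriptors; the
backend version is recorded on every matrix). Preprocessing drops
non-differential (zero-variance) columns, Z-scores the rest, and imputes
missing cells with K nearest neighbours (k = 5, Euclidean distance on the
available Z-scored columns; k is a conventional default, configurable).
Training means and standard deviations are stored so query compounds are
normalized identically.

Descriptor selection is recursive feature elimination with
cross-validation (RFECV) driven by LASSO: within one pass the descriptor
with the smallest |LASSO coefficient| is removed one at a time (the LASSO
penalty is re-chosen by inner 3-fold CV at every step), each subset size
is scored by 10-fold CV, and the winning subset is the *smallest* one
scoring within 5% of the best score. The parsimony rule matters:
CV scores of nested subsets are frequently near-tied, and without it
uninformative descriptors survive by chance. The CV score is the median
relative error (MRE) of the fold predictions — the selection criterion is
deliberately the same statistic the final model is judged by. Passes are
repeated over random subsamples of 50–90% of the training rows (five
fractions × 200 replications = 1000 by default); descriptors appearing in
more than 700 of 1000 winning subsets are selected, the threshold scaling
proportionally when fewer replications are run. A compact 15-descriptor
default panel (`DEFAULT_PANEL`: size, flexibility, surface and polarity
descriptors) is shipped for building a model without running the full
selection, and a published selection can be injected by name to bypass
RFECV entirely.

## SVR CCS prediction

One model per ionization polarity, exposed in the Model/Results style:
`CCSPredictor(compounds, ccs_values, polarity).fit(...)` returns a
`CCSPredictorResults` with the chosen hyperparameters, training
diagnostics, `summary()`, `predict()` and `evaluate()`.

* **Features** — Z-scored selected descriptors plus an adduct encoding:
  the adduct's mass shift in Da and a one-hot indicator. How one
  per-polarity model distinguishes adducts is not otherwise specified;
  per-adduct submodels are possible by filtering the training table.
  This encoding is the main reproduction risk relative to descriptor-only
  features.
* **Targets** — standardized internally (mean/sd of the training CCS) and
  back-transformed on prediction. Without target standardization the
  small grid C values (≤ 0.5/N_MD) could not fit targets living at
  ~100–300 Å².
* **Kernel** — RBF. The tuning grid is 7 C values
  (0.001, 0.005, 0.025, 0.05, 0.1, 0.25, 0.5)/N_MD × 15 gamma values
  2¹…2¹⁵ = 105 combinations, scored by repeated 10-fold CV MRE (ties
  broken toward smaller C, then smaller gamma; the full grid table is
  returned for audit). **Gamma is interpreted as the kernel width σ of
  K = exp(−‖u−v‖²/(2σ²))**, not as scikit-learn's inverse coefficient:
  on Z-scored descriptors the nearest-neighbour squared distances are of
  order 1–10, so inverse-coefficient gammas ≥ 2 would annihilate the
  kernel at every grid point, whereas under the width convention large
  gamma flattens the kernel and pushes the model toward linear
  regression — which is also the only convention under which high tuned
  gammas plausibly coexist with low prediction errors. The conversion
  (sklearn gamma = 1/(2σ²)) happens inside the SVR wrapper; reported
  gammas are widths.
* **ε-tube** — 0.01 in standardized-target units, chosen to sit at the
  scale of residual measurement noise in unified CCS values (~0.3% of a
  typical CCS ≈ 0.015 target sd); the backend's 0.1 default would add a
  tube wider than the error the model is asked to reach. SVR tolerance
  1e-3, shrinking on.
* **Metrics** — relative error per pair `|pred − exp|/exp × 100`; MRE is
  its median, ARE its mean, R² on raw CCS; the cumulative error curve
  (fraction of predictions at or below each threshold, 0.5% steps) is a
  valid CDF. Training MRE is the in-sample MRE of the final model.
* Predictions are flagged confidence level 4 and carry an RSS score.

## Representative structure similarity (RSS)

Fingerprints are path-based (RDKit, depth 7, 1024 bits; scheme recorded
in every result — published RSS values can move by a few hundredths
across schemes). Tanimoto similarity is `|A∩B| / (|A| + |B| − |A∩B|)`,
defined as 1 for two empty bitsets. RSS of a query is the mean of the
top five tanimoto coefficients against the training set (mean over the
available ones when the training set holds fewer than five). A query
identical to a training structure contributes TC = 1 — no self-exclusion,
matching the definition literally; `exclude_self=True` exists for
leave-one-out experiments. Reliability groups: small (RSS ≤ 0.6),
medium (0.6 < RSS ≤ 0.8), large (RSS > 0.8); boundaries map exactly as
stated. On the leave-one-superclass-out harness, excluded-class
predictions show higher errors and lower RSS, which is what licenses RSS
as a reliability estimate.

## Multi-dimensional annotation

* **m/z match** — candidates whose adduct m/z lies within 25 ppm;
  `[M+H]+` / `[M-H]-` by default.
* **CCS match** — relative error Δ = |CCS_cand − CCS_exp|/CCS_exp × 100;
  candidates beyond TOL_max (4%) are removed, the rest scored by the
  trapezoid: 1 below TOL_min (2%), linear decay to 0 at TOL_max.
  TOL_max = TOL_min degenerates to a step function, documented, no
  division error. Candidates with no CCS value at all are excluded when
  the CCS dimension is on.
* **MS/MS match** — reverse dot-product: each reference peak is paired
  with the closest experimental peak within 25 ppm (the precursor
  tolerance is mirrored), intensities are square-root transformed, and
  the squared cosine over the reference-peak vectors is returned;
  experimental-only peaks are ignored. Scores from third-party
  in-silico MS/MS tools can be ingested instead and are min–max rescaled
  to [0, 1] within each feature's candidate set before integration.
  When several spectra arrive per feature the highest-intensity one
  should be selected upstream; the annotation API takes one spectrum.
* **Integration** — S = 0.3·S_ccs + 0.7·S_MS/MS (weights validated to
  sum to 1 unless explicitly overridden). A feature without usable
  MS/MS falls back to S_ccs with the CCS weight renormalized to 1 and the
  result flagged. Candidates are densely ranked by integrated score,
  ties broken by |ppm error| then id; per-feature stage counts (m/z
  matched → after CCS → ranked) expose the candidate-reduction
  statistic.

## Synthetic studies

The simulator generates the study conditions the pipeline is tested
under. Real structures, synthetic CCS: descriptors and fingerprints need
valid chemistry, but truth values must be known, hence the hybrid. The
bundled list holds 102 curated small molecules across seven chemical
superclasses (masses 75–390 Da). Ground truth per superclass follows
`CCS = a·(m/z)^b` (a ≈ 7.6–9.8, b ≈ 0.50–0.54, giving ~120–320 Å² over
the simulated m/z range — the same functional form the trend-line filter
assumes) times a compound-level jitter (σ = 2%) representing structure
effects beyond mass.

Experimental records: six datasets (three DTIM, two TWIM, one TIMS across
four labs), per-dataset bias drawn with σ = 0.5%, coverage 0.8, one to
two replicates, measurement noise σ = 0.3% at the measurement level plus
σ = 0.1% replicate noise, and 2% outliers displaced ±25%. Outlier
displacement is shared by replicates of a measurement: a per-replicate
outlier would be caught by the 0.5% intra-dataset rule and never reach
the trend-line stage that the recovery statistics probe. With these
conditions the injected outliers inflate the per-class residual variance
enough that the 99% prediction interval covers the clean records
comfortably — recovery is ≈ 100% with zero false removals.

Spectra are toys: 5–20 reference peaks below the precursor, degraded
copies with 20% dropout, 10% intensity noise and up to two contaminant
peaks. The decoy candidate database spikes each true compound with 15
decoys within ±20 ppm in mass and ±15% in CCS, so the m/z filter alone
cannot separate them; with a 4% CCS gate roughly two-thirds to
three-quarters of decoys fall away, reproducing the direction of the
published candidate-reduction narrative.

What the simulator does **not** emulate: real fragmentation chemistry,
instrument-specific calibration drift, retention-time structure,
correlated descriptor noise, or the chemical breadth of a hundred-
thousand-compound database. Passing tests therefore demonstrate the
correctness and statistical behaviour of the procedures, not
field accuracy on real libraries.

## Problem sizes and numerical choices

The default test and acceptance runs use deliberately modest sizes chosen
as sensible desk-scale experiments: 60–102 compounds, ~4000 records for
the unification study, 500 CCS values (80/20 split) for the SVR study
with tuning at 1 CV repeat, RFECV at 4–20 replications per fraction with
the proportionally scaled threshold, ~200 features for the annotation
benchmark, and ~450 predictions for the extrapolation harness. Full-size
settings (100 CV repeats, 1000 RFECV replications) are plain parameters.
All stochastic steps take explicit seeds; identical configurations
reproduce identical outputs.

## Known limitations

* One CCS per ion: conformer multiplicity is out of scope.
* Singly charged adducts only; the charge division is stubbed for
  future multi-charge support.
* The descriptor catalogue differs from other cheminformatics backends;
  selected-descriptor identities are backend-dependent and the package
  makes no claim to reproduce any specific published descriptor list.
* The adduct encoding (shift + one-hot) is a design choice; exact
  reproduction of published per-polarity models may require per-adduct
  submodels.
* Unified values average platforms without recalibration models;
  cross-instrument recalibration is explicitly out of scope.
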