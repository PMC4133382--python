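# Methods

## Problem and model

Given a protein, the task is to decide for each tyrosine whether it can be
nitrated. The predictor is purely sequence-based and local: the only input
per site is the `(2ℓ+1)`-mer window centered on the tyrosine, over the
21-symbol alphabet of the 20 amino acids plus the padding residue `X`
(windows overhanging a terminus are padded rather than discarded, so every
tyrosine of every protein is scorable).

Each class (nitrated / non-nitrated) is summarized by a position-specific
dipeptide propensity matrix: for subsite `j` (the `j`-th of the `2ℓ`
overlapping adjacent residue pairs, left to right) and dipeptide `i` (row-
major over the numeric residue codes, A=1 … Y=20, X=21), entry `z(i,j)` is
the fraction of that class's training windows showing dipeptide `i` at
subsite `j`. Matrices are exact occurrence frequencies — each column of the
441×2ℓ table sums to 1 and an unseen dipeptide scores 0. `X` counts like
any residue; padded positions are informative (they encode proximity to a
terminus).

A window's feature vector toward a class is the `2ℓ` matrix lookups of its
own dipeptides. The similarity to a class is taken against the *ideal*
window of that class, whose every feature component sits at the upper limit
1; since components lie in [0,1], the inner product with the all-ones ideal
is simply the component sum `φ`, and any monotone alternative would reduce
to it up to a reparameterization of the threshold. The discriminant is
`Δ = φ⁺ − φ⁻ + ξ`, called positive iff `Δ ≥ 0`. The boundary case is
deliberately inclusive (a site exactly at the threshold is flagged for
inspection); this is a documented convention, not a derivable fact.

### The adjust parameter ξ

With ~7:1 negative:positive imbalance the raw score `φ⁺ − φ⁻` is not
centered where overall accuracy peaks. ξ is chosen by exact search: the
candidate thresholds are the midpoints between consecutive distinct raw
training scores plus guards beyond both extremes (these exhaust all
achievable confusion tables), and the candidate maximizing accuracy wins,
with ties broken by higher MCC and then by smaller |ξ|. Three policies are
exposed:

* `fixed(v)` — user-supplied;
* `shared` (default for evaluation) — ξ tuned once on the full dataset's
  raw scores, then held fixed while each sample is scored leave-one-out.
  This matches reporting a single ξ for a jackknife experiment; it leaks a
  small amount of threshold information and is the convention used for the
  headline numbers.
* `tuned` — re-tuned inside every fold (k-fold) or for every held-out
  sample on the remaining samples' leave-one-out scores (jackknife). The
  jackknife variant is leakage-free but quadratic in the dataset size and
  intended for small datasets.

## Evaluation

The jackknife is computed by *decrement*: matrices store integer counts, so
leaving a sample out subtracts 1 from each of its own-class (dipeptide,
subsite) cells and renormalizes by `n − 1`, while the opposite class is
untouched. Scores are computed as (integer count sum)/(sample count), so
the decremental path agrees bit-for-bit with full retraining — the test
suite asserts exact equality sample by sample.

k-fold folds are built by shuffling each class with a seeded generator and
dealing the shuffled positives followed by the shuffled negatives
round-robin into k folds (one continuous cycle). This keeps per-fold class
proportions within one sample of each other and makes `k = n` collapse
exactly to the leave-one-out jackknife, which the suite verifies. Counts
are pooled (micro-averaged) across folds, as in a single jackknife table.
Fold assignments are recorded in the report for reproducibility.

Sn, Sp, Acc and MCC are computed in both the TP/TN/FP/FN form and the
class-size form (`Sn = 1 − N⁺₋/N⁺`, etc.) and cross-checked to 1e−12 on
every call; an MCC whose denominator vanishes (a degenerate margin) is
reported as 0 with an explicit `mcc_defined=False` flag. ROC curves sweep
the decision threshold over every distinct observed raw score (equivalently
every achievable ξ) with guard points at (0,0) and (1,1); AUC is the
trapezoidal integral, which equals the tie-corrected Mann–Whitney statistic
normalized by `N⁺·N⁻` (asserted against scipy's implementation in tests).

The window-size sweep rebuilds the benchmark at each candidate ℓ from the
same proteins and annotations and reports the pooled out-of-fold AUC per ℓ.

## Synthetic data

The generator emulates the *shape* of a curated nitration benchmark: fixed
class sizes, Y-centered windows, flanks drawn i.i.d. from a background
distribution (uniform over the 20 amino acids by default; `X` never occurs,
because padding is a windowing artifact, not a residue), and a controllable
class contrast made of planted position-specific dipeptides. Plants are
applied left to right with overwrite, so overlapping plants are legal and
later ones win; plants touching the center must keep the `Y`.

`default_benchmark_motif` is the package's standard simulated condition: a
fixed profile of eight acidic/basic dipeptide plants at scattered subsites
with probabilities 0.15–0.35, reflecting the charged neighbourhoods that
favour tyrosine nitration at a moderate, non-separable effect size. It was
fixed once as a design choice. What the synthetic data does **not**
reproduce: residue autocorrelation within flanks, homologous redundancy
between windows from related proteins, per-protein composition biases, and
whatever real enrichment structure the curated benchmark carries. Passing
the synthetic suites therefore demonstrates correctness of the estimator,
discriminant and evaluation machinery — not field performance on real
proteins.

On this simulated condition the single-residue baseline can match or exceed
the dipeptide model, because plants injected independently per subsite
create strong marginal single-residue signal; the dipeptide encoder's
advantage is specific to genuinely coupled residue pairs, as in the real
benchmark.

## Numerical and interface choices

* Frequencies and scores are exact rationals evaluated in double precision;
  the only tolerance in the package is the 1e−12 metric cross-check.
* The dipeptide enumeration order (row-major over residue codes) is a
  convention; nothing downstream depends on more than its bijectivity.
* Model files are plain text: a key–value header (version, ℓ, encoder mode,
  ξ, class sample counts) followed by sparse `(dipeptide, subsite,
  frequency)` triplets per class. Frequencies are written with full `repr`
  precision and converted back to integer counts on load, so a save → load
  → save cycle is byte-identical.
* Coordinates facing users (site positions, benchmark tables, prediction
  reports) are 1-based; internal window offsets are 0-based with the center
  at ℓ.
* Duplicate training peptides are retained — propensities are occurrence
  frequencies, and deduplication would silently reweight the estimate.
* Non-standard FASTA letters (B, J, O, U, Z, `*`, `-`) are sanitized to `X`
  with a logged count rather than rejected, keeping the pipeline total over
  real-world inputs.

## Problem sizes

The default test and acceptance runs use the curated benchmark's shape
(1,044 / 7,669 windows at ℓ=9) for the end-to-end jackknife, 5,000 samples
for frequency-recovery checks, 1,000 per class for the signal-free AUC
control, and ≤50-sample datasets for the exact decrement-vs-retrain
equivalence; the decremental jackknife makes the largest of these take
fractions of a second.

## Known limitations

* The curated benchmark itself is not bundled (it is third-party
  supplementary material); the two tests that reproduce its published
  jackknife rates and composition require a user-supplied conversion at
  `data/s1_benchmark.tsv` and fail with a pointer otherwise.
* No smoothing means a test window containing a dipeptide never seen in a
  class contributes 0 for that subsite; with small training sets this makes
  scores coarse. An additive-smoothing knob was considered and rejected for
  the reproduction path, since the propensity definition is a raw frequency.
* Single-label, binary decisions only; no multi-site or multi-label
  calibration, no homology reduction, no physicochemical features.
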