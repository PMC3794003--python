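# Methods

## Model and procedure

`ggapsvm` classifies protein sequences into two classes (by convention
*acidic* vs *alkaline* enzymes, with alkaline the positive class) using
only primary-sequence information. The pipeline has four stages.

**1. Encoding.** For a gap `g ≥ 0`, a sequence of length `L` contains
`L − g − 1` ordered residue pairs `(R_i, R_{i+g+1})`. Tallying these over
the 400 ordered pairs of standard amino acids and dividing by `L − g − 1`
yields a composition vector: non-negative, summing to one. `g = 0` is the
ordinary adjacent dipeptide composition; larger gaps probe longer-range
residue correlations (e.g. positions bridged by secondary-structure
periodicity). The pair-to-column map is fixed: row-major over the
alphabetically sorted residues (AA, AC, …, YY), first residue major, and is
serialized into every model file so that feature indices can never drift
between training and prediction.

**2. Feature ranking.** Each of the 400 features is scored by the one-way
ANOVA F statistic,

    F(λ) = MSB(λ) / MSW(λ),
    MSB = SSB / (K − 1),  MSW = SSW / (M − K),
    SSB = Σ_i m_i (mean_i − grand_mean)²,
    SSW = Σ_i Σ_j (x_ij − mean_i)²,

with `K = 2` groups and `M` samples. Under no class difference F ≈ 1; for
`K = 2` it equals the squared pooled two-sample t statistic (a property the
tests exploit as an oracle). p-values are the upper tail of
`F(K − 1, M − K)`. Degenerate columns: `SSW = 0` with `SSB > 0` maps to
`+inf` (the feature separates the sample perfectly, ranks first);
all-identical columns map to 0. Ties in the descending-F ranking break by
ascending canonical pair index, making the ranking bit-reproducible.

**3. Incremental feature selection.** The nested subsets S₁ ⊂ … ⊂ S₄₀₀ in
rank order are each evaluated by leave-one-out (jackknife) accuracy of an
RBF-kernel C-SVC. Leave-one-out is used precisely because it yields a
unique, row-order-independent result for a given dataset. Scanning gaps
g = 0…10 gives 11 IFS curves (4,400 candidate subsets); the global peak
fixes `(g₀, t₀)`, with ties broken toward smaller g, then smaller t
(simpler models). Hyperparameters `(C, γ)` are searched on a powers-of-two
grid — C exponents +15…−5, γ exponents −5…−15, step 1, i.e. 21 × 11 = 231
points — scored by the same jackknife accuracy. Because the grid itself is
tuned on jackknife accuracy, the reported peak accuracy is optimistically
biased; this reproduces the classical protocol. Two scan modes exist:
`fast` (default) optimises the grid once per gap on the full 400-feature
matrix and reuses `(C, γ)` across subset sizes; `regrid` re-searches at
every subset size (hundreds of times slower, same interface). After
`(g₀, t₀)` is fixed, the grid search is re-run once on the selected subset
before the final fit.

**4. Final model and prediction.** The final SVC is trained on all samples
with Platt-style sigmoid calibration (scikit-learn's probability mode; its
internal 5-fold split is seeded and the seed stored in the model file), so
predictions emit `P(acidic)` and `P(alkaline)` summing to 1; the label is
the class with probability above 0.5. Model files carry a format version,
the feature subset, the dipeptide ordering and the calibration seed, and
refuse to load under a mismatched version.

## Evaluation metrics

With TP/FN counting alkaline samples and TN/FP acidic ones:
`Sn = TP/(TP+FN)`, `Sp = TN/(TN+FP)`, `Ac = (TP+TN)/M`, and CC is the
Matthews correlation coefficient, set to 0 when any denominator factor
vanishes. ROC curves sweep a threshold over the distinct jackknife decision
values (ties grouped); AUC is the trapezoidal area, identical to the
pairwise concordance probability with ties counted ½. Percentages are
rounded half-up to one decimal.

## Jackknife implementation

A full gap scan costs ~440,000 SVM fits, so the leave-one-out loop runs on
scikit-learn's low-level LibSVM binding and skips refits for held-out
samples that are not support vectors of the full-data model — removing a
non-support vector leaves the KKT solution, and hence the held-out
prediction, unchanged, so the shortcut is exact, not an approximation. A
`use_lowlevel=False` path through the public `SVC` API is kept and a test
asserts both paths produce identical confusion counts.

## Synthetic data generator

The generator emulates the single property the pipeline exploits:
class-discriminative g-gap dipeptide frequencies. Residues are drawn
i.i.d. from a background (uniform by default — cleaner nulls; a
Swiss-Prot-style natural-frequency preset exists). For the class a planted
pair favours, each anchor position is overwritten with a planted pair with
probability `P(e−1)/(400+P(e−1))` (P planted pairs, enrichment e), giving
planted pairs exactly e-fold emission odds over background pairs;
`e = 1` yields exchangeable classes. Defaults: 50 sequences per class,
lengths uniform on [100, 300] (matching the convention of discarding
chains under 100 residues — too short to carry stable dipeptide
statistics).

What the generator does *not* emulate: residue autocorrelation, domain
structure, phylogenetic relatedness between sequences, class-specific
isoelectric-point physicochemistry, or length/composition confounds of real
enzymes. Passing tests therefore demonstrate that the pipeline recovers
planted compositional signal and stays calibrated on exchangeable data —
not that any particular accuracy will be attained on real enzymes.

The test suite plants *mirrored* pairs (RL→acidic, LR→alkaline, DT→acidic,
TD→alkaline, plus KE→alkaline) so both classes receive nearly the same
single-residue enrichment and the discriminative signal is specific to the
planted gap. Unmirrored plantings leak into residue marginals, which every
gap sees, and wrong-gap accuracy then rises toward the planted-gap
accuracy.

## Null calibration and the balanced leave-one-out artifact

Dipeptide-composition vectors are compressed into a small ball (pairwise
squared distances of order 10⁻²). Every γ in the classical grid (max 2⁻⁵)
then leaves the RBF kernel nearly constant, the SVM degenerates to a
majority vote, and balanced leave-one-out makes the held-out sample's class
the training minority — the degenerate model votes *against* every held-out
label. On signal-free data this yields accuracy and AUC near 0, not 0.5,
regardless of grid search. Null-calibration checks therefore fix the
bandwidth by the median heuristic (γ = 1/median squared pairwise distance,
a standard data-scale choice) with C = 2⁵, under which signal-free data
scores at chance as a null check should. This artifact is a property of
the evaluation protocol on balanced data, not of the generator; with real
signal present the classical grid behaves normally, which is why the
selection pipeline itself keeps the classical search space.

## Numerical and design choices

- **Frequency denominator** `L − g − 1`: the unique normalisation making
  each encoded row a composition summing to 1.
- **Grid-step reading**: both exponent ranges step by 1 (factor 2), the
  standard LibSVM schedule; `gamma_exp_step` exposes a coarser step.
- **Grid search not nested in the jackknife** by default (the classical,
  optimistically biased protocol); per-fold re-search is available via the
  `regrid` scan mode at the corresponding cost.
- **No feature rescaling** before the SVM: frequencies already live in
  [0, 1] on a common scale.
- **Tie-breaks** everywhere favour the simpler model: smaller C, larger γ
  in grid search; smaller t, then smaller g in selection; ascending
  canonical pair index in rankings.
- **Duplicate ids** are rejected at dataset construction (ambiguous
  provenance is worse than strictness); lowercase residues are silently
  uppercased; `*`, `-` and non-standard letters (B, J, O, U, X, Z) are
  errors in strict mode, dropped with a warning otherwise.
- **Problem sizes in tests**: the planted-signal acceptance run uses 50
  sequences per class with a reduced 3 × 2 hyperparameter grid over the
  full gap 0–10 × t 1–400 scan; smoke tests cap the scan via `t_max`.
  These sizes keep the whole suite at a few minutes while exercising every
  stage at full feature dimensionality.

## Known limitations

- The jackknife-tuned grid search inflates the selected peak accuracy;
  treat reported IFS peaks as model-selection scores, not unbiased
  generalisation estimates (use held-out data or the `kfold` command for
  that).
- Feature selection is performed on the full dataset before the jackknife,
  as in the classical protocol, which adds further selection bias.
- The `fast` scan mode fixes `(C, γ)` per gap; curves can differ slightly
  from the exhaustive `regrid` interpretation.
- Binary classification only; sequences shorter than `g + 2` cannot be
  encoded at gap `g` and are reported per record at prediction time.
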