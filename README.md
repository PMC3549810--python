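# fealect

Feature-relevance scoring and selection from Lasso regularization paths over
data subsamples, for high-dimensional problems where the number of features
far exceeds the number of samples (gene-expression panels, flow-cytometry
cell-population features, mass-spectrometry peaks, and similar n ≪ d
settings).

A single Lasso fit at a cross-validated penalty is brittle when n is small:
features a domain expert knows to be informative get dropped, and the
selected set changes from run to run.  Intersection-style stabilizers
(Bolasso) are often too strict in the other direction and return an empty
set.  This package implements a softer, fully analytic alternative:

1. **Subsample.** Draw m random subsamples B of size ⌊γn⌋ *without*
   replacement (defaults γ = 3/4, m = 1000).
2. **Path, not point.** On each subsample run least-angle regression (LARS,
   no-drop variant) to get the nested active sets F₁ᴮ ⊂ F₂ᴮ ⊂ … ⊂ F_Kᴮ of
   the whole ℓ₁ regularization path, up to a cap K (default min(d, 60)).
3. **Score.** At path size k each of the k active features earns 1/k, so a
   feature entering at rank j earns H_{K_B} − H_{j−1} on that subsample
   (H is the harmonic number).  The total score S(f) averages these
   contributions over subsamples; ∑_f S(f) = mean(K_B) exactly.
4. **Threshold analytically.**  For a feature that is selected *iff* a fixed
   set U of r samples lands in the subsample, Pr(U ⊆ B) = C(n−r, b−r)/C(n, b)
   → γ^r, so the scores of such "over-fitting" features decay geometrically
   in r and form a straight band in the sorted log-score curve.  Fitting a
   continuous quadratic–linear–quadratic 3-segment model to the curve
   locates that band; everything above its upper knot is reported as
   informative.  No user-chosen cutoff is involved.

Bolasso and Bolasso-S baselines, a repeated-split AUC comparison protocol,
exact inclusion-probability combinatorics, and a seeded sparse-data
generator are included.

## Worked example

`examples/score_and_select.py` plants 5 predictive features among 200 with
60 samples and runs the full pipeline:

```
dataset: n=60, d=200, planted support = (63, 93, 121, 129, 137)
sum of scores = 37.1800 (= mean path length 37.1800)
3-segment fit: knots at curve ranks 10 and 178 of 197, threshold score 0.3902
selected 19 features; 5 of the 5 planted features are among them
top-5 by score: [63, 129, 121, 137, 93] (5/5 planted)
```

The first line after the dataset is the conservation identity (each
subsample's path of length K_B distributes exactly K_B score units).  The
3-segment fit places the irrelevant linear band between curve ranks 10 and
178; the 19 features above it include the whole planted support, which also
occupies the top five score ranks.

`examples/bolasso_comparison.py` compares selectors by mean held-out AUC
over 20 random 20-sample training splits of the same kind of data:

```
          mean_auc  repeats   sem
selector
bolasso      0.500       20 0.000
fealect      0.587       20 0.027
lars         0.578       20 0.023
```

Bolasso's intersection is empty here (AUC 0.5 from a constant model), while
restricting the classifier to the score-selected features edges out a single
cross-validated Lasso on all features — the small-n regime the method is
built for.  `examples/theory_checks.py` prints the inclusion-probability
convergence table and the log-score slope on the mock over-fit harness
(measured −0.290 against the theoretical log γ = −0.288).

## Command line

The same pipeline is scriptable:

```sh
fealect simulate --n 60 --d 200 --sparsity 5 --snr 8 --seed 7 --output data.csv
fealect score --input data.csv --label-col label --bootstraps 1000 --seed 1 --output scores.tsv
fealect select --scores scores.tsv --report report.json --curve curve.tsv
fealect bolasso --input data.csv --label-col label --output bolasso.json
fealect compare --input data.csv --label-col label --n-train 20 --output compare.tsv
fealect validate --suite all --seed 7
```

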